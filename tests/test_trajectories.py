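"""Spline trajectories, dense-grid z comparison, validation, meta-pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lifetraj.trajectories import (
    CubicSplineGAM,
    TrajectoryGrid,
    adjust_covariates,
    compare_grid,
    fit_group_trajectory,
    longitudinal_rate_check,
    meta_combine_ivw,
    validation_concordance,
)


class _ConstFit:
    """Stub group fit with constant mean and SE over a fixed support."""

    def __init__(self, mean, se, lo=8.0, hi=70.0):
        self.m, self.s, self.age_range = mean, se, (lo, hi)

    def predict(self, ages, covars=None):
        n = len(ages)
        return np.full(n, self.m), np.full(n, self.s)


class TestSplineGAM:
    def test_straight_line_reproduced(self, rng):
        age = rng.uniform(8, 70, 2000)
        y = 10 + 2 * age + rng.normal(0, 0.01, 2000)
        res = CubicSplineGAM(y, age, K=3).fit()
        m, se = res.predict(np.array([20.0, 50.0]))
        assert np.allclose(m, [50.0, 110.0], atol=0.01)
        assert np.all(se < 0.01)

    def test_k3_basis_has_three_spline_coefficients(self, rng):
        age = rng.uniform(8, 70, 500)
        gam = CubicSplineGAM(rng.normal(size=500), age, K=3)
        # intercept plus at most 3 spline coefficients
        assert gam.n_spline - 1 <= 3
        assert gam.X.shape[1] == gam.n_spline

    def test_rmse_below_sample_sd(self, rng):
        age = rng.uniform(8, 70, 3000)
        y = 3000 - 8 * age + 200 * np.exp(-(((age - 30) / 15) ** 2)) + rng.normal(0, 150, 3000)
        res = CubicSplineGAM(y, age).fit()
        pred, _ = res.predict(age)
        assert np.sqrt(np.mean((y - pred) ** 2)) < y.std()

    def test_degenerate_ages_rejected(self):
        with pytest.raises(ValueError):
            CubicSplineGAM(np.ones(10), np.full(10, 30.0))


class TestAdjustCovariates:
    def test_planted_sex_effect_removed(self, rng):
        n = 5000
        age = rng.uniform(8, 70, n)
        sex = rng.integers(0, 2, n)
        tab = pd.DataFrame(
            dict(age=age, sex=sex, handedness=0, group="HC",
                 roi=3000 - 8 * age + 100 * sex + rng.normal(0, 150, n))
        )
        out = adjust_covariates(tab, ["roi"], study_col=None)
        gap = out.loc[tab.sex == 1, "roi"].mean() - out.loc[tab.sex == 0, "roi"].mean()
        assert abs(gap) < 5.0

    def test_null_covariates_near_identity(self, rng):
        n = 3000
        age = rng.uniform(8, 70, n)
        tab = pd.DataFrame(
            dict(age=age, sex=rng.integers(0, 2, n), handedness=0, group="HC",
                 roi=3000 - 8 * age + rng.normal(0, 150, n))
        )
        out = adjust_covariates(tab, ["roi"], study_col=None)
        assert np.abs(out["roi"] - tab["roi"]).max() < 15.0

    def test_within_cell_order_preserved(self, rng):
        n = 400
        tab = pd.DataFrame(
            dict(age=rng.uniform(20, 60, n), sex=rng.integers(0, 2, n),
                 handedness=0, group="HC", roi=rng.normal(3000, 100, n))
        )
        out = adjust_covariates(tab, ["roi"], study_col=None)
        for s in (0, 1):
            m = tab.sex == s
            assert (
                np.argsort(out.loc[m, "roi"].to_numpy())
                == np.argsort(tab.loc[m, "roi"].to_numpy())
            ).all()


class TestCompareGrid:
    def test_default_grid_has_1241_ages(self):
        g = compare_grid(_ConstFit(1.0, 0.1), _ConstFit(1.0, 0.1), roi="r")
        assert len(g.grid) == 1241

    def test_identical_fits_yield_null(self):
        g = compare_grid(_ConstFit(2.0, 0.1), _ConstFit(2.0, 0.1))
        assert np.allclose(g.z, 0.0)
        assert not g.grid["sig"].any() and g.windows == []

    def test_hand_computed_z_and_p(self):
        """means (1.2, 1.0), SEs (0.05, 0.05) -> z = 2.8284, p = 0.004678."""
        g = compare_grid(_ConstFit(1.2, 0.05), _ConstFit(1.0, 0.05))
        assert g.z[0] == pytest.approx(2.8284, abs=1e-4)
        assert g.grid["p"].iloc[0] == pytest.approx(0.004678, abs=1e-6)

    def test_bh_adjusted_never_below_raw(self, rng):
        age = rng.uniform(8, 70, 2000)
        grp = np.array(["HC"] * 1000 + ["SUD"] * 1000)
        y = 3000 - 8 * age + rng.normal(0, 200, 2000)
        df = pd.DataFrame(dict(age=age, group=grp, roi=y))
        g = compare_grid(
            fit_group_trajectory(df, "SUD", "roi"), fit_group_trajectory(df, "HC", "roi")
        )
        assert (g.grid["p_adj"] >= g.grid["p"] - 1e-12).all()
        assert ((g.grid["p_adj"] < g.alpha) == g.grid["sig"]).all()

    def test_z_antisymmetric_under_group_swap(self, rng):
        age = rng.uniform(8, 70, 2000)
        grp = np.array(["HC"] * 1000 + ["SUD"] * 1000)
        y = 3000 - 8 * age - 100 * (grp == "SUD") + rng.normal(0, 200, 2000)
        df = pd.DataFrame(dict(age=age, group=grp, roi=y))
        fs = fit_group_trajectory(df, "SUD", "roi")
        fh = fit_group_trajectory(df, "HC", "roi")
        g1 = compare_grid(fs, fh)
        g2 = compare_grid(fh, fs)
        assert np.allclose(g1.z, -g2.z)

    def test_empty_support_errors(self):
        with pytest.raises(ValueError):
            compare_grid(_ConstFit(1, 0.1, 8, 20), _ConstFit(1, 0.1, 30, 70))


class TestLongitudinal:
    def test_faster_decline_in_cases_is_concordant(self):
        rng = np.random.default_rng(42)
        n = 800
        rows = []
        for i in range(n):
            grp = "SUD" if i < n // 2 else "HC"
            age = rng.uniform(10, 40)
            slope = -12.0 if grp == "SUD" else -4.0
            base = 3000 + slope * age + rng.normal(0, 60)
            rows.append(dict(participant_id=i, visit=1, age=age, sex=0, group=grp,
                             roi=base + rng.normal(0, 10)))
            rows.append(dict(participant_id=i, visit=2, age=age + 2, sex=0, group=grp,
                             roi=base + 2 * slope + rng.normal(0, 10)))
        rep = longitudinal_rate_check(pd.DataFrame(rows), ["roi"])
        assert rep.loc["roi", "group_coef"] < 0
        assert rep.loc["roi", "slope_diff"] < 0
        assert rep.loc["roi", "concordant"]

    def test_single_group_rejected(self):
        df = pd.DataFrame(
            dict(participant_id=[1, 1], visit=[1, 2], age=[10, 12.0], sex=[0, 0],
                 group=["HC", "HC"], roi=[1.0, 2.0])
        )
        with pytest.raises(ValueError):
            longitudinal_rate_check(df, ["roi"])


class TestConcordance:
    def _grid(self, z):
        ages = np.arange(8, 70.5, 0.5)
        g = pd.DataFrame(dict(age=ages, z=np.resize(z, len(ages))))
        return TrajectoryGrid(roi="r", grid=g)

    def test_identity_and_antitone(self, rng):
        z = rng.standard_normal(125)
        a = {"r": self._grid(z)}
        out, summary = validation_concordance(a, {"r": self._grid(z)})
        assert out.loc["r", "spearman_r"] == pytest.approx(1.0)
        out2, _ = validation_concordance(a, {"r": self._grid(-z)})
        assert out2.loc["r", "spearman_r"] == pytest.approx(-1.0)

    def test_seventeen_of_twentyfour_reports_71_percent(self, rng):
        a, b = {}, {}
        for i in range(24):
            z = rng.standard_normal(125)
            a[f"r{i}"] = self._grid(z)
            b[f"r{i}"] = self._grid(z if i < 17 else -z)
        _, summary = validation_concordance(a, b, threshold=0.25)
        assert summary["n_above"] == 17 and summary["percent"] == 71


class TestIVW:
    def test_closed_form_example(self):
        est, se = meta_combine_ivw([1.0, 3.0], [1.0, 1.0])
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(1 / np.sqrt(2))

    def test_single_input_identity(self):
        est, se = meta_combine_ivw([1.7], [0.3])
        assert est == pytest.approx(1.7) and se == pytest.approx(0.3)

    def test_infinite_se_gets_zero_weight(self):
        est, se = meta_combine_ivw([1.0, 99.0], [0.5, np.inf])
        assert est == pytest.approx(1.0) and se == pytest.approx(0.5)

    def test_vectorized_and_validation(self):
        est, se = meta_combine_ivw(np.ones((2, 4)), np.ones((2, 4)))
        assert est.shape == (4,)
        with pytest.raises(ValueError):
            meta_combine_ivw([1.0], [0.0])
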