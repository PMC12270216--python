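"""Behavioral contrasts, composites, brain-behavior correlation, pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lifetraj.behavior import (
    bh_adjust,
    brain_behavior_corr,
    cohens_d,
    downsample_balance,
    extract_composites,
    group_compare,
    interaction_trend,
    meta_pool_r,
)
from lifetraj.factor import tucker_congruence


class TestGroupCompare:
    def test_identical_samples_null(self):
        x = np.array([1.0, 2.0, 3.0] * 4)
        g = np.array(["a"] * 6 + ["b"] * 6)
        rec = group_compare(np.concatenate([x[:6], x[:6]]), g)
        assert rec.value == 0.0 and rec.p == pytest.approx(1.0)

    def test_hand_computed_d(self):
        """mean gap 1 with pooled SD 2 gives d = 0.5."""
        rng = np.random.default_rng(0)
        base = rng.normal(0, 2, 4000)
        base = (base - base.mean()) / base.std(ddof=1) * 2
        x = np.concatenate([base + 1.0, base])
        g = np.array(["a"] * 4000 + ["b"] * 4000)
        rec = group_compare(x, g)
        assert rec.value == pytest.approx(0.5, abs=1e-9)

    def test_chi2_contingency_oracle(self):
        """2x2 table (30,70 / 50,50): Pearson chi-square = 25/3 = 8.3333
        without continuity correction (frozen from scipy's oracle)."""
        g = np.repeat(["a", "b"], 100)
        v = np.concatenate([np.repeat([0, 1], [30, 70]), np.repeat([0, 1], [50, 50])])
        rec = group_compare(v, g, kind="categorical")
        assert rec.value == pytest.approx(8.3333, abs=1e-3)

    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_d_invariant_to_affine_and_sign_flips_on_swap(self, shift, scale):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 50), rng.normal(0.5, 1, 50)
        d = cohens_d(x, y)
        assert cohens_d(scale * x + shift, scale * y + shift) == pytest.approx(d, rel=1e-9)
        assert cohens_d(y, x) == pytest.approx(-d, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], ["a", "a"])


class TestDownsample:
    def test_balances_to_minority_size(self, rng):
        tab = pd.DataFrame(dict(group=["maj"] * 1000 + ["min"] * 84, x=0.0))
        out = downsample_balance(tab, seed=0)
        assert out["group"].value_counts().to_dict() == {"maj": 84, "min": 84}

    def test_balanced_input_unchanged_and_deterministic(self):
        tab = pd.DataFrame(dict(group=["a"] * 5 + ["b"] * 5, x=range(10)))
        out = downsample_balance(tab, seed=3)
        assert sorted(out["x"]) == list(range(10))
        tab2 = pd.DataFrame(dict(group=["a"] * 50 + ["b"] * 10, x=range(60)))
        o1 = downsample_balance(tab2, seed=7)
        o2 = downsample_balance(tab2, seed=7)
        pd.testing.assert_frame_equal(o1, o2)


class TestComposites:
    def test_planted_two_factor_recovery(self, rng):
        lam = np.vstack(
            [np.column_stack([np.full(4, 0.7), np.zeros(4)]),
             np.column_stack([np.zeros(4), np.full(4, 0.7)])]
        )
        f = rng.standard_normal((5000, 2))
        X = pd.DataFrame(f @ lam.T + rng.standard_normal((5000, 8)) * np.sqrt(0.51))
        X.columns = [f"i{j}" for j in range(8)]
        fm = extract_composites(X)
        assert fm.n_factors == 2
        assert tucker_congruence(lam, fm.loadings.to_numpy()) > 0.95

    def test_identity_correlation_retains_zero_factors(self, rng):
        # whiten so the sample correlation is exactly the identity
        X = rng.standard_normal((400, 5))
        X = X - X.mean(0)
        C = np.cov(X, rowvar=False)
        w, V = np.linalg.eigh(C)
        X = X @ V @ np.diag(w**-0.5) @ V.T
        fm = extract_composites(pd.DataFrame(X))
        assert fm.n_factors == 0

    def test_scores_uncorrelated_with_pure_noise_item(self, rng):
        lam = np.column_stack(
            [np.concatenate([np.full(4, 0.7), np.zeros(4)]),
             np.concatenate([np.zeros(4), np.full(4, 0.7)])]
        )
        f = rng.standard_normal((5000, 2))
        X = pd.DataFrame(f @ lam.T + rng.standard_normal((5000, 8)) * 0.7)
        noise = rng.standard_normal(5000)
        fm = extract_composites(X)
        for c in fm.scores.columns:
            assert abs(np.corrcoef(fm.scores[c], noise)[0, 1]) < 0.05


class TestBrainBehavior:
    def test_perfect_and_self_adjusted_correlation(self, rng):
        x = pd.Series(rng.standard_normal(500))
        cent = pd.DataFrame({"roiA": x.to_numpy(), "roiB": rng.standard_normal(500)})
        recs = brain_behavior_corr(x, cent)
        byroi = {r.measure: r for r in recs}
        assert byroi["roiA"].value == pytest.approx(1.0)
        # partial correlation with the confounder itself as target -> 0
        recs2 = brain_behavior_corr(x, cent[["roiA"]], adjust_for=x)
        assert abs(recs2[0].value) < 1e-8

    def test_target_correlation_recovered(self, rng):
        n = 5000
        z = rng.standard_normal(n)
        x = pd.Series(0.3 * z + np.sqrt(1 - 0.09) * rng.standard_normal(n))
        cent = pd.DataFrame({"roi": z})
        recs = brain_behavior_corr(x, cent)
        assert 0.25 <= recs[0].value <= 0.35

    def test_bh_monotone_in_rank(self, rng):
        x = pd.Series(rng.standard_normal(300))
        cent = pd.DataFrame(rng.standard_normal((300, 8)), columns=list("abcdefgh"))
        recs = brain_behavior_corr(x, cent)
        df = pd.DataFrame([r.as_dict() for r in recs]).sort_values("p")
        assert (df["p_adj"].to_numpy() >= df["p"].to_numpy() - 1e-12).all()
        assert (np.diff(df["p_adj"].to_numpy()) >= -1e-12).all()


class TestMetaPool:
    def test_closed_form_example(self):
        """r = (0.1, 0.3), n = (103, 103): pooled z = 0.20493 -> r = 0.2021."""
        r, p = meta_pool_r([0.1, 0.3], [103, 103])
        assert r == pytest.approx(0.2021, abs=2e-4)

    def test_equal_r_and_single_study_identity(self):
        r, _ = meta_pool_r([0.4, 0.4, 0.4], [50, 100, 20])
        assert r == pytest.approx(0.4)
        r1, _ = meta_pool_r([0.25], [60])
        assert r1 == pytest.approx(0.25)

    def test_pooled_between_min_and_max(self, rng):
        rs = rng.uniform(-0.5, 0.5, 5)
        ns = rng.integers(10, 200, 5)
        r, _ = meta_pool_r(rs, ns)
        assert rs.min() <= r <= rs.max()

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            meta_pool_r([1.0], [50])


class TestInteraction:
    def test_planted_slope_gap_recovered(self):
        rng = np.random.default_rng(5)
        n = 2000
        age = rng.uniform(10, 40, n)
        grp = np.where(rng.random(n) < 0.5, "SUD", "HC")
        score = 1.0 + 0.02 * age + 0.1 * age * (grp == "SUD") + rng.normal(0, 0.5, n)
        rec = interaction_trend(score, age, grp)
        assert 0.08 <= rec.value <= 0.12

    def test_parallel_trends_null(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            n = 500
            age = rng.uniform(10, 40, n)
            grp = np.where(rng.random(n) < 0.5, "SUD", "HC")
            score = 0.02 * age + 0.3 * (grp == "SUD") + rng.normal(0, 0.5, n)
            rec = interaction_trend(score, age, grp)
            hits += abs(rec.value / rec.se) < 2
        assert hits >= 18

    def test_constant_score_gives_zero_slopes(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(10, 40, 200)
        grp = np.array(["SUD", "HC"] * 100)
        rec = interaction_trend(np.full(200, 3.0), age, grp)
        assert abs(rec.value) < 1e-10


def test_bh_adjust_empty_is_noop():
    assert bh_adjust([]) == []
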