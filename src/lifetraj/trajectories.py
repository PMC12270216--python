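"""Group volumetric trajectories and their dense-grid comparison.

Covariate-adjusted volumes are modelled per group with a penalized cubic
regression spline in age (basis dimension K=3, smoothing parameter by a
REML criterion).  Group mean curves and their standard errors are
evaluated on a dense age grid (8-70y in 0.05y steps by default), compared
with a two-sided z test at every grid age, Benjamini-Hochberg adjusted
across the grid within each region, and summarized as contiguous
significant age windows plus a smoothed z curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CubicSplineGAM",
    "GAMResults",
    "TrajectoryGrid",
    "adjust_covariates",
    "fit_group_trajectory",
    "compare_grid",
    "longitudinal_rate_check",
    "validation_concordance",
    "meta_combine_ivw",
]


def _natural_spline_basis(x, knots):
    """Natural cubic spline basis (truncated-power construction).

    Columns: [x, d_1(x) - d_{K-1}(x), ..., d_{K-2}(x) - d_{K-1}(x)] with
    d_k(x) = ((x - t_k)_+^3 - (x - t_K)_+^3) / (t_K - t_k); linear beyond
    the boundary knots.  K knots give K-1 columns (intercept excluded).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    K = len(t)

    def d(k):
        return (
            np.clip(x - t[k], 0, None) ** 3 - np.clip(x - t[-1], 0, None) ** 3
        ) / (t[-1] - t[k])

    dK1 = d(K - 2)
    cols = [x] + [d(k) - dK1 for k in range(K - 2)]
    return np.column_stack(cols)


class CubicSplineGAM:
    """Penalized natural cubic regression spline y ~ s(age), K basis functions.

    K is the number of spline coefficients excluding the intercept (K=3
    default: knots at the min, median and max age give 2 curvature columns
    plus the linear column).  The curvature penalty integrates the squared
    second derivative, approximated on a fine grid; lambda is chosen by
    restricted maximum likelihood on a log-spaced grid.
    """

    def __init__(self, y, age, K: int = 3, extra_covars: np.ndarray | None = None):
        self.y = np.asarray(y, dtype=float)
        self.age = np.asarray(age, dtype=float)
        if np.ptp(self.age) == 0:
            raise ValueError("all ages equal: singular spline basis")
        self.K = K
        qs = np.linspace(0, 1, K)
        self.knots = np.unique(np.quantile(self.age, qs))
        if len(self.knots) < 3:
            self.knots = np.linspace(self.age.min(), self.age.max(), 3)
        self._mean, self._scale = self.age.mean(), max(self.age.std(), 1e-9)

        B = self._basis(self.age)
        self.X = np.column_stack([np.ones(len(self.y)), B])
        if extra_covars is not None:
            self.X = np.column_stack([self.X, np.asarray(extra_covars, float)])
        self.n_spline = B.shape[1] + 1  # incl. intercept
        self.S = self._penalty()

    def _basis(self, x):
        z = (np.asarray(x, float) - self._mean) / self._scale
        zk = (self.knots - self._mean) / self._scale
        return _natural_spline_basis(z, zk)

    def _penalty(self):
        # numerical \int f''^2 over the data range, in coefficient space
        grid = np.linspace(self.age.min(), self.age.max(), 200)
        Bg = self._basis(grid)
        h = grid[1] - grid[0]
        D2 = (Bg[2:] - 2 * Bg[1:-1] + Bg[:-2]) / h**2
        S_spl = D2.T @ D2 * h
        p = self.X.shape[1]
        S = np.zeros((p, p))
        S[1 : self.n_spline, 1 : self.n_spline] = S_spl
        return S

    def fit(self, lambdas=None) -> "GAMResults":
        if lambdas is None:
            lambdas = np.logspace(-8, 8, 33)
        y, X, S = self.y, self.X, self.S
        n, p = X.shape
        XtX, Xty = X.T @ X, X.T @ y
        s_eig = np.linalg.eigvalsh(S)
        s_pos = s_eig[s_eig > 1e-10 * max(s_eig.max(), 1e-300)]
        M = p - len(s_pos)  # penalty null-space dimension

        best = (np.inf, None, None)
        for lam in lambdas:
            A = XtX + lam * S
            try:
                beta = np.linalg.solve(A, Xty)
            except np.linalg.LinAlgError:
                continue
            rss = float(((y - X @ beta) ** 2).sum())
            pen = float(lam * beta @ S @ beta)
            sig2 = max((rss + pen) / max(n - M, 1), 1e-300)
            sign, logdet_A = np.linalg.slogdet(A)
            if sign <= 0:
                continue
            logdet_S = len(s_pos) * np.log(lam) + np.log(s_pos).sum()
            neg2_reml = (
                (n - M) * (np.log(2 * np.pi * sig2) + 1)
                + logdet_A
                - logdet_S
                - M * np.log(sig2)
            )
            if neg2_reml < best[0]:
                best = (neg2_reml, lam, beta)
        if best[1] is None:
            raise np.linalg.LinAlgError("REML grid search failed")
        _, lam, beta = best
        A = XtX + lam * S
        rss = float(((y - X @ beta) ** 2).sum())
        edf = float(np.trace(np.linalg.solve(A, XtX)))
        sig2 = rss / max(n - edf, 1.0)
        cov = sig2 * np.linalg.inv(A)  # Bayesian posterior covariance
        return GAMResults(model=self, beta=beta, cov=cov, lam=lam, sigma2=sig2, edf=edf)


@dataclass
class GAMResults:
    model: CubicSplineGAM
    beta: np.ndarray
    cov: np.ndarray
    lam: float
    sigma2: float
    edf: float

    @property
    def age_range(self):
        return float(self.model.age.min()), float(self.model.age.max())

    def _design(self, ages, covars=None):
        ages = np.asarray(ages, dtype=float)
        X = np.column_stack([np.ones(len(ages)), self.model._basis(ages)])
        p_extra = self.model.X.shape[1] - self.model.n_spline
        if p_extra:
            C = np.zeros((len(ages), p_extra)) if covars is None else np.asarray(covars)
            X = np.column_stack([X, C])
        return X

    def predict(self, ages, covars=None):
        """Mean curve and its SE at ``ages`` (reference covariates = 0)."""
        X = self._design(ages, covars)
        mean = X @ self.beta
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", X, self.cov, X), 0, None))
        return mean, se

    def slope(self, age, eps=0.25):
        m1, _ = self.predict([age - eps])
        m2, _ = self.predict([age + eps])
        return float((m2[0] - m1[0]) / (2 * eps))

    def summary(self) -> str:
        return (
            f"Penalized cubic spline GAM: K={self.model.K}, "
            f"edf={self.edf:.2f}, lambda={self.lam:.3g}, sigma2={self.sigma2:.4g}"
        )


def adjust_covariates(
    table: pd.DataFrame,
    rois: list[str],
    covars=("sex", "handedness"),
    study_col: str | None = "cohort",
    age_df: int = 6,
) -> pd.DataFrame:
    """Remove sex/handedness/study effects from volumes, keeping the age effect.

    An additive model (cubic spline of age + linear covariates) is fitted
    on the pooled case+control sample — group is deliberately excluded, so
    covariate effects are assumed independent of case status — and the
    centered covariate contributions are subtracted.
    """
    covars = list(covars)
    C = [
        table[c].to_numpy(float)
        for c in covars
        if c in table and np.ptp(table[c].to_numpy(float)) > 0
    ]
    if study_col and study_col in table and table[study_col].nunique() > 1:
        d = pd.get_dummies(table[study_col], drop_first=True)
        C.extend(d[c].to_numpy(float) for c in d.columns)
    if not C:
        return table.copy()
    C = np.column_stack(C)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariates")
    Cc = C - C.mean(axis=0)

    out = table.copy()
    for r in rois:
        gam = CubicSplineGAM(table[r].to_numpy(float), table["age"].to_numpy(float),
                             K=age_df, extra_covars=Cc)
        res = gam.fit()
        beta_cov = res.beta[gam.n_spline:]
        out[r] = table[r].to_numpy(float) - Cc @ beta_cov
    return out


def fit_group_trajectory(
    adjusted: pd.DataFrame, group: str, roi: str, K: int = 3, min_n: int = 50
) -> GAMResults:
    """Penalized cubic-spline mean trajectory for one group and region."""
    sub = adjusted[adjusted["group"] == group]
    if len(sub) < min_n:
        raise ValueError(f"need >= {min_n} scans in group {group!r}")
    if np.ptp(sub["age"].to_numpy()) < 5:
        raise ValueError("age span must exceed 5 years")
    return CubicSplineGAM(sub[roi].to_numpy(float), sub["age"].to_numpy(float), K=K).fit()


@dataclass
class TrajectoryGrid:
    """Dense-age comparison of the case and control mean curves."""

    roi: str
    grid: pd.DataFrame  # age, mean_sud, se_sud, mean_hc, se_hc, z, p, p_adj, sig, ...
    alpha: float = 0.05
    windows: list = field(default_factory=list)  # [(age_lo, age_hi), ...]

    @property
    def ages(self):
        return self.grid["age"].to_numpy()

    @property
    def z(self):
        return self.grid["z"].to_numpy()

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.grid
        for grp, color in [("sud", "crimson"), ("hc", "steelblue")]:
            ax.plot(g["age"], g[f"mean_{grp}"], color=color, label=grp.upper())
            ax.fill_between(
                g["age"],
                g[f"mean_{grp}"] - 1.96 * g[f"se_{grp}"],
                g[f"mean_{grp}"] + 1.96 * g[f"se_{grp}"],
                color=color,
                alpha=0.2,
            )
        for lo, hi in self.windows:
            ax.axvspan(lo, hi, color="gold", alpha=0.2)
        ax.set_xlabel("age (y)")
        ax.set_ylabel(f"{self.roi} adjusted volume (mm$^3$)")
        ax.legend()
        return ax


def compare_grid(
    fit_sud: GAMResults,
    fit_hc: GAMResults,
    roi: str = "",
    age_min: float = 8.0,
    age_max: float = 70.0,
    step: float = 0.05,
    alpha: float = 0.05,
    min_run: int = 10,
    smooth_K: int = 10,
) -> TrajectoryGrid:
    """z-test the two group curves on the dense age grid with BH adjustment.

    The grid is clipped to the common fitted age support.  Significant runs
    shorter than ``min_run`` consecutive grid ages are not reported as
    windows (isolated-point suppression).  A smoothed z curve is refitted
    with a cubic-spline GAM on the z sequence.
    """
    n_pts = int(round((age_max - age_min) / step)) + 1
    ages = age_min + step * np.arange(n_pts)
    lo = max(fit_sud.age_range[0], fit_hc.age_range[0], age_min)
    hi = min(fit_sud.age_range[1], fit_hc.age_range[1], age_max)
    ages = ages[(ages >= lo) & (ages <= hi)]
    if len(ages) == 0:
        raise ValueError("empty common age support")

    m_s, se_s = fit_sud.predict(ages)
    m_h, se_h = fit_hc.predict(ages)
    denom = np.sqrt(se_s**2 + se_h**2)
    z = (m_s - m_h) / denom
    p = 2 * stats.norm.sf(np.abs(z))
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    sig = p_adj < alpha

    z_smooth = (
        CubicSplineGAM(z, ages, K=smooth_K).fit().predict(ages)[0]
        if len(ages) > smooth_K
        else z.copy()
    )
    grid = pd.DataFrame(
        dict(
            age=ages, mean_sud=m_s, se_sud=se_s, mean_hc=m_h, se_hc=se_h,
            z=z, p=p, p_adj=p_adj, sig=sig, z_smooth=z_smooth,
            log10p=np.log10(np.clip(p, 1e-300, None)),
        )
    )
    windows = []
    run_start = None
    for i, s in enumerate(np.append(sig, False)):
        if s and run_start is None:
            run_start = i
        elif not s and run_start is not None:
            if i - run_start >= min_run:
                windows.append((float(ages[run_start]), float(ages[i - 1])))
            run_start = None
    return TrajectoryGrid(roi=roi, grid=grid, alpha=alpha, windows=windows)


def longitudinal_rate_check(
    long_table: pd.DataFrame, rois: list[str], case_label: str = "SUD"
) -> pd.DataFrame:
    """Concordance between longitudinal change rates and the fitted curves.

    Per region, the follow-up-minus-baseline volume change is regressed on
    group + baseline age + sex; the group coefficient's sign is compared
    with the cross-sectional spline slope difference (case minus control)
    at the participants' mean baseline age.
    """
    import statsmodels.api as sm

    counts = long_table.groupby("participant_id")["visit"].nunique()
    pids = counts[counts >= 2].index
    if len(pids) == 0:
        raise ValueError("no participants with >= 2 visits")
    sub = long_table[long_table["participant_id"].isin(pids)].sort_values("visit")
    base = sub.groupby("participant_id").first()
    follow = sub.groupby("participant_id").last()
    if base["group"].nunique() < 2:
        raise ValueError("longitudinal sample contains a single group")

    grp = (base["group"] == case_label).astype(float).to_numpy()
    X = sm.add_constant(
        np.column_stack([grp, base["age"].to_numpy(float), base["sex"].to_numpy(float)])
    )
    mean_age = float(base["age"].mean())
    rows = []
    for r in rois:
        dy = follow[r].to_numpy(float) - base[r].to_numpy(float)
        fit = sm.OLS(dy, X).fit()
        coef, pval = fit.params[1], fit.pvalues[1]
        try:
            f_s = fit_group_trajectory(base.reset_index(), case_label, r, min_n=10)
            f_h = fit_group_trajectory(base.reset_index(), "HC", r, min_n=10)
            slope_diff = f_s.slope(mean_age) - f_h.slope(mean_age)
        except ValueError:
            slope_diff = np.nan
        rows.append(
            dict(
                roi=r, group_coef=coef, group_p=pval, slope_diff=slope_diff,
                concordant=bool(np.sign(coef) == np.sign(slope_diff))
                if np.isfinite(slope_diff) else None,
            )
        )
    return pd.DataFrame(rows).set_index("roi")


def validation_concordance(
    grids_a: dict, grids_b: dict, threshold: float = 0.25
) -> tuple[pd.DataFrame, dict]:
    """Spearman correlation of z curves between two sets of trajectory grids.

    Grids are resampled (linearly in age) onto the overlapping support.
    Summary reports the count and rounded percentage of regions at or above
    ``threshold``.
    """
    from .pipeline import fraction_report

    rows = {}
    for roi in grids_a:
        if roi not in grids_b:
            continue
        a, b = grids_a[roi], grids_b[roi]
        lo = max(a.ages.min(), b.ages.min())
        hi = min(a.ages.max(), b.ages.max())
        common = a.ages[(a.ages >= lo) & (a.ages <= hi)]
        if len(common) < 3:
            raise ValueError(f"fewer than 3 common ages for {roi}")
        za = np.interp(common, a.ages, a.z)
        zb = np.interp(common, b.ages, b.z)
        rows[roi] = stats.spearmanr(za, zb).statistic
    out = pd.DataFrame({"spearman_r": pd.Series(rows)})
    k = int((out["spearman_r"] >= threshold).sum())
    summary = dict(n_above=k, n_total=len(out), percent=fraction_report(k, len(out)))
    return out, summary


def meta_combine_ivw(estimates, ses):
    """Inverse-variance weighted combination along axis 0.

    Infinite SEs get zero weight; all SEs must be positive.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValueError("estimates and ses must have matching shapes")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    scalar = est.ndim == 1
    if scalar:
        est, se = est[:, None], se[:, None]
    w = 1.0 / se**2
    w = np.where(np.isinf(se), 0.0, w)
    wsum = w.sum(axis=0)
    if np.any(wsum == 0):
        raise ValueError("all weights zero at some position")
    comb = np.where(np.isinf(se), 0.0, w * est).sum(axis=0) / wsum
    comb_se = 1.0 / np.sqrt(wsum)
    if scalar:
        return float(comb[0]), float(comb_se[0])
    return comb, comb_se
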