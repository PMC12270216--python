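"""Group comparisons of behavioral measures and brain-behavior correlation.

Case-control contrasts of neurobehavioral measures (Cohen's d with a
two-sided t-test for continuous measures, Pearson chi-square for
categorical ones, Benjamini-Hochberg adjusted within study), optional
down-sampling of the majority class, factor-analytic composite scores,
per-region brain-behavior (partial) correlations, Fisher-z pooling of
correlations across studies, and an age-by-group interaction model for
time-varying behavioral differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .factor import FactorModel, principal_axis_factor

__all__ = [
    "EffectRecord",
    "group_compare",
    "bh_adjust",
    "downsample_balance",
    "extract_composites",
    "brain_behavior_corr",
    "meta_pool_r",
    "interaction_trend",
]


@dataclass
class EffectRecord:
    measure: str
    study: str
    stat: str  # "d" | "chi2" | "r" | "beta"
    value: float
    se: float
    p: float
    p_adj: float = np.nan

    def as_dict(self):
        return dict(
            measure=self.measure, study=self.study, stat=self.stat,
            value=self.value, se=self.se, p=self.p, p_adj=self.p_adj,
        )


def bh_adjust(records: list[EffectRecord]) -> list[EffectRecord]:
    """Benjamini-Hochberg adjust p-values in place across the given records."""
    if not records:
        return records
    _, p_adj, _, _ = multipletests([r.p for r in records], method="fdr_bh")
    for r, pa in zip(records, p_adj):
        r.p_adj = float(pa)
    return records


def cohens_d(x, y, pooled: bool = True) -> float:
    """Classic pooled-SD Cohen's d (x minus y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    if pooled:
        sp = np.sqrt(
            ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        )
    else:
        sp = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def group_compare(
    values, groups, kind: str = "continuous", measure: str = "", study: str = "",
    welch: bool = False,
) -> EffectRecord:
    """Two-group contrast of one measure.

    Continuous: Cohen's d (pooled SD) with a two-sided t-test (pooled by
    default, Welch behind the flag).  Categorical: Pearson chi-square on
    the contingency table, no continuity correction.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need two groups")
    a, b = values[groups == labels[0]], values[groups == labels[1]]
    if kind == "continuous":
        a = a.astype(float)[~np.isnan(a.astype(float))]
        b = b.astype(float)[~np.isnan(b.astype(float))]
        if min(len(a), len(b)) < 2:
            raise ValueError("need >= 2 observations per group")
        d = cohens_d(a, b, pooled=not welch)
        t = stats.ttest_ind(a, b, equal_var=not welch)
        if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and np.allclose(
            a.mean(), b.mean()
        ):
            t = type(t)(0.0, 1.0)  # identical degenerate samples
        se = np.sqrt(1 / len(a) + 1 / len(b) + d**2 / (2 * (len(a) + len(b))))
        return EffectRecord(measure, study, "d", d, float(se), float(t.pvalue))
    elif kind == "categorical":
        tab = pd.crosstab(groups, values)
        if (tab.to_numpy() < 1).any():
            raise ValueError("all contingency cells must be >= 1")
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        return EffectRecord(measure, study, "chi2", float(chi2), np.nan, float(p))
    raise ValueError(f"unknown kind {kind!r}")


def downsample_balance(
    table: pd.DataFrame, group_col: str = "group", seed=None
) -> pd.DataFrame:
    """Sample the majority group without replacement down to the minority size."""
    rng = np.random.default_rng(seed)
    counts = table[group_col].value_counts()
    if counts.min() == 0 or len(counts) < 2:
        raise ValueError("both groups must be non-empty")
    n_min = int(counts.min())
    parts = []
    for g, grp in table.groupby(group_col, sort=True):
        if len(grp) > n_min:
            idx = rng.choice(grp.index, size=n_min, replace=False)
            parts.append(table.loc[np.sort(idx)])
        else:
            parts.append(grp)
    return pd.concat(parts)


def extract_composites(items: pd.DataFrame) -> FactorModel:
    """Factor composite scores from a pre-scored item table.

    Principal-axis factoring on the item correlation matrix, retention by
    the Kaiser rule (eigenvalues > 1), varimax rotation, regression-method
    factor scores.  Non-item columns ('cohort', 'group', ids) are ignored.
    """
    drop = [c for c in ("participant_id", "cohort", "group") if c in items.columns]
    clean = items.drop(columns=drop).dropna(axis=0, how="any")
    return principal_axis_factor(clean, n_factors="kaiser", rotation="varimax")


def _partial_corr(x, y, z):
    """Pearson correlation of x and y after removing linear z from both."""
    Z = np.column_stack([np.ones(len(x)), np.asarray(z, float)])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return rx, ry


def brain_behavior_corr(
    factor_scores: pd.Series,
    centiles: pd.DataFrame,
    adjust_for: pd.Series | None = None,
    study: str = "",
) -> list[EffectRecord]:
    """Per-region (partial) Pearson correlation of a factor with centiles.

    Rows must be aligned on the same participants.  BH adjustment is
    applied across regions; two-tailed t-based p-values.
    """
    x = factor_scores.to_numpy(float)
    if x.std() == 0:
        raise ValueError("zero-variance factor score")
    n = len(x)
    k_adj = 0
    records = []
    for roi in centiles.columns:
        y = centiles[roi].to_numpy(float)
        if y.std() == 0:
            raise ValueError(f"zero-variance centiles for {roi}")
        xi, yi = x, y
        if adjust_for is not None:
            xi, yi = _partial_corr(x, y, adjust_for.to_numpy(float))
            k_adj = 1
        if min(xi.std(), yi.std()) < 1e-10 * max(x.std(), y.std()):
            r = 0.0  # target collinear with the adjustment variable
        else:
            r = float(np.corrcoef(xi, yi)[0, 1])
        dof = n - 2 - k_adj
        with np.errstate(divide="ignore"):
            t = r * np.sqrt(dof / max(1e-300, 1 - r**2))
        p = float(2 * stats.t.sf(np.abs(t), dof))
        se = float(np.sqrt((1 - r**2) / max(dof, 1)))
        records.append(EffectRecord(roi, study, "r", r, se, p))
    return bh_adjust(records)


def meta_pool_r(rs, ns):
    """Fisher-z inverse-variance pooled correlation and its p-value."""
    rs = np.asarray(rs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if np.any(np.abs(rs) >= 1):
        raise ValueError("|r| must be < 1")
    if np.any(ns < 4):
        raise ValueError("need n >= 4 per study")
    z = np.arctanh(rs)
    w = ns - 3
    z_pool = float((w * z).sum() / w.sum())
    se = 1.0 / np.sqrt(w.sum())
    p = float(2 * stats.norm.sf(abs(z_pool) / se))
    return float(np.tanh(z_pool)), p


def interaction_trend(
    score, age, group, sex=None, handedness=None, case_label="SUD",
    measure: str = "", study: str = "",
) -> EffectRecord:
    """Age-by-group interaction in a linear model of a behavioral score.

    score ~ age + group + age x group (+ sex + handedness); the interaction
    coefficient's SE comes from the coefficient covariance under the
    normal-theory assumption.
    """
    import statsmodels.api as sm

    g = (np.asarray(group) == case_label).astype(float)
    age = np.asarray(age, dtype=float)
    for gv in (0.0, 1.0):
        if np.ptp(age[g == gv]) < 5:
            raise ValueError("each group must span >= 5 years of age")
    cols = [age, g, age * g]
    names = ["age", "group", "age:group"]
    for nm, v in [("sex", sex), ("handedness", handedness)]:
        if v is not None:
            cols.append(np.asarray(v, dtype=float))
            names.append(nm)
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design")
    fit = sm.OLS(np.asarray(score, float), X).fit()
    i = 1 + names.index("age:group")
    return EffectRecord(
        measure, study, "beta",
        float(fit.params[i]), float(fit.bse[i]), float(fit.pvalues[i]),
    )
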