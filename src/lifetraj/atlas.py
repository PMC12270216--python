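"""Cognitive-atlas factor maps and their lifespan association with z-patterns.

A term-by-region meta-analytic matrix is factor-decomposed (regions as
observations, terms as variables; varimax rotation; factors explaining
more than 1% of variance retained; terms retained per factor when their
loading exceeds 0.2 and sits in the top half of that factor's loadings).
Each factor's region-level map is then regressed against the case-control
differential z-statistic at 0.5-year age steps, with permutation p-values
from region-label permutation (or user-supplied null maps, e.g.
precomputed spin nulls) and BH adjustment across ages within factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .factor import principal_axis_factor

__all__ = ["AtlasFactorSet", "AssociationTrack", "atlas_factorize", "lifespan_association"]


@dataclass
class AtlasFactorSet:
    loadings: pd.DataFrame  # terms x factors (varimax-rotated)
    explained_variance: np.ndarray  # fraction per retained factor
    retained_terms: pd.DataFrame  # bool terms x factors
    roi_maps: pd.DataFrame  # ROIs x factors
    map_method: str = "scores"

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


def atlas_factorize(
    term_matrix: pd.DataFrame,
    min_explained: float = 0.01,
    loading_threshold: float = 0.2,
    percentile: float = 50.0,
    map_method: str = "scores",
) -> AtlasFactorSet:
    """Varimax factor decomposition of a term-by-region matrix.

    Regions are the observations, terms the variables.  ``map_method``:
    'scores' (regression factor scores per region, default) or 'weighted'
    (retained-loading-weighted sums of term maps).
    """
    if term_matrix.shape[0] < 2 or term_matrix.shape[1] < 10:
        raise ValueError("need >= 2 terms and >= 10 regions")
    data = term_matrix.T  # regions x terms
    p = data.shape[1]

    # provisional factor count from the correlation spectrum
    Z = (data - data.mean()) / data.std(ddof=1)
    eig = np.sort(np.linalg.eigvalsh(np.corrcoef(Z.to_numpy(), rowvar=False)))[::-1]
    k0 = max(1, int(np.sum(eig / p > min_explained)))
    k0 = min(k0, data.shape[0] - 2, p - 1)
    fm = principal_axis_factor(data, n_factors=k0, rotation="varimax", allow_small_n=True)

    keep = fm.explained_variance > min_explained
    if not keep.all():
        fm = principal_axis_factor(data, n_factors=int(keep.sum()), rotation="varimax",
                                   allow_small_n=True)
    L = fm.loadings

    retained = pd.DataFrame(False, index=L.index, columns=L.columns)
    for c in L.columns:
        cut = np.percentile(L[c], percentile)
        retained[c] = (L[c] > loading_threshold) & (L[c] >= cut)

    if map_method == "scores":
        maps = fm.scores.copy()
        maps.index = term_matrix.columns
    elif map_method == "weighted":
        W = L.where(retained, 0.0)
        norm = W.abs().sum(axis=0).replace(0, 1.0)
        maps = pd.DataFrame(
            term_matrix.T.to_numpy() @ (W / norm).to_numpy(),
            index=term_matrix.columns,
            columns=L.columns,
        )
    else:
        raise ValueError(f"unknown map_method {map_method!r}")
    return AtlasFactorSet(
        loadings=L,
        explained_variance=fm.explained_variance,
        retained_terms=retained,
        roi_maps=maps,
        map_method=map_method,
    )


@dataclass
class AssociationTrack:
    factor: str
    track: pd.DataFrame  # age, r2, p, p_adj, sig_corrected, sig_nominal
    n_perm: int = 1000

    @property
    def min_p(self) -> float:
        return 1.0 / (self.n_perm + 1)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.track
        ax.plot(t["age"], t["r2"], label=self.factor)
        sig = t[t["sig_corrected"]]
        ax.scatter(sig["age"], sig["r2"], marker="^", zorder=3)
        ax.set_xlabel("age (y)")
        ax.set_ylabel("$R^2$")
        ax.legend()
        return ax


def lifespan_association(
    factor_maps: pd.DataFrame,
    z_by_age: pd.DataFrame,
    n_perm: int = 1000,
    null_mode: str = "label",
    null_maps: dict | None = None,
    alpha: float = 0.05,
    seed=None,
) -> dict[str, AssociationTrack]:
    """Per-age univariate association of each factor map with the z-pattern.

    ``factor_maps``: regions x factors; ``z_by_age``: regions x ages
    (columns are ages, 0.5y steps over 8-70y in the full analysis).  For
    each (factor, age) the explained variance R^2 of the simple regression
    of the z-pattern on the map is computed; permutation p-values use
    region-label permutation (the same permutation applied across all ages
    of a null draw) or user-supplied null maps keyed by factor, p = (1 +
    #{null R^2 >= observed}) / (n_perm + 1).  BH adjustment runs across
    ages within factor.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    if set(factor_maps.index) != set(z_by_age.index):
        raise ValueError("factor maps and z table have mismatched region sets")
    Zmat = z_by_age.loc[factor_maps.index].to_numpy(float)  # regions x ages
    Zc = Zmat - Zmat.mean(axis=0)
    z_ss = (Zc**2).sum(axis=0)
    rng = np.random.default_rng(seed)
    n_roi = len(factor_maps)

    def r2_for(map_vec):
        m = map_vec - map_vec.mean()
        denom = (m**2).sum() * z_ss
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = (m @ Zc) ** 2 / denom
        return np.nan_to_num(r2)

    out = {}
    for f in factor_maps.columns:
        vec = factor_maps[f].to_numpy(float)
        obs = r2_for(vec)
        if null_mode == "supplied":
            if null_maps is None or f not in null_maps:
                raise ValueError(f"no supplied null maps for factor {f!r}")
            nulls = np.asarray(null_maps[f], dtype=float)
        elif null_mode == "label":
            nulls = np.array([vec[rng.permutation(n_roi)] for _ in range(n_perm)])
        else:
            raise ValueError(f"unknown null_mode {null_mode!r}")
        null_r2 = np.array([r2_for(nv) for nv in nulls])  # n_perm x ages
        p = (1.0 + (null_r2 >= obs).sum(axis=0)) / (len(nulls) + 1.0)
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        out[f] = AssociationTrack(
            factor=str(f),
            track=pd.DataFrame(
                dict(
                    age=np.asarray(z_by_age.columns, dtype=float),
                    r2=obs, p=p, p_adj=p_adj,
                    sig_corrected=p_adj < alpha, sig_nominal=p < alpha,
                )
            ),
            n_perm=len(nulls),
        )
    return out
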