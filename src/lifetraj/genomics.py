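"""Case definition, association scan, wGMV score, conjFDR and PGS pruning.

The genomic arm of the analysis: longitudinal case status (case iff
flagged on more than half of visits); a per-SNP score-test association
scan on 0/1/2 genotypes; the weighted grey-matter-volume score wGMV =
sum_r w_r * centile_r with weights taken from the per-region case-control
z statistics; conditional FDR of one trait's p-values given enrichment in
a second (empirical conditional CDF with 2-D monotone enforcement) and the
conjunctional FDR as the maximum of the two conditionals; greedy
distance-based locus clumping; and LD-pruned cross-trait polygenic-score
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "define_cases",
    "assoc_scan",
    "compute_wgmv",
    "cond_fdr",
    "conj_fdr",
    "clump_loci",
    "ld_prune",
    "prs_correlation",
    "read_gwas_table",
    "write_gwas_table",
]


def define_cases(visit_flags: pd.DataFrame | pd.Series) -> pd.Series:
    """Binary case label: case iff flagged on more than half of the visits.

    ``visit_flags`` is a Series of 0/1 (or bool) flags indexed by
    participant id (one row per visit), or a DataFrame with columns
    'participant_id' and 'sud'.
    """
    if isinstance(visit_flags, pd.DataFrame):
        flags = visit_flags.set_index("participant_id")["sud"]
    else:
        flags = visit_flags
    if len(flags) == 0:
        raise ValueError("empty visit record")
    grp = flags.astype(float).groupby(level=0)
    n = grp.count()
    if (n == 0).any():
        raise ValueError("participant with empty visit record")
    return (grp.sum() / n > 0.5).rename("case")


def _residualize(M, X):
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def assoc_scan(
    genotypes: np.ndarray,
    phenotype,
    covariates: np.ndarray | None = None,
    trait: str = "quantitative",
) -> pd.DataFrame:
    """Per-SNP score test of the genotype term given covariates.

    Quantitative traits use the linear-model score test on
    covariate-residualized genotypes; binary traits use the logistic score
    test at the null (covariates-only) fit.  Missing genotypes are
    mean-imputed per SNP; monomorphic SNPs are skipped with a warning and
    reported as NaN.
    """
    import warnings

    G = np.asarray(genotypes, dtype=float).copy()
    y = np.asarray(phenotype, dtype=float)
    n, m = G.shape
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    if n <= X.shape[1] + 2:
        raise ValueError("too few individuals for the covariate model")

    # mean-impute missing genotype calls per SNP
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = col_mean[idx[1]]
    mono = G.std(axis=0) == 0
    if mono.any():
        warnings.warn(f"skipping {int(mono.sum())} monomorphic SNPs")

    z = np.full(m, np.nan)
    if trait == "quantitative":
        r = _residualize(y, X)
        Gt = _residualize(G[:, ~mono], X)
        sig2 = (r @ r) / (n - X.shape[1])
        num = Gt.T @ r
        den = np.sqrt(sig2 * (Gt**2).sum(axis=0))
        z[~mono] = num / den
    elif trait == "binary":
        import statsmodels.api as sm

        null = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        p_hat = null.fittedvalues
        w = p_hat * (1 - p_hat)
        Gs = G[:, ~mono]
        U = Gs.T @ (y - p_hat)
        WX = X * w[:, None]
        XtWX_inv = np.linalg.inv(X.T @ WX)
        GtWX = Gs.T @ WX
        V = (Gs**2 * w[:, None]).sum(axis=0) - np.einsum(
            "ij,jk,ik->i", GtWX, XtWX_inv, GtWX
        )
        z[~mono] = U / np.sqrt(V)
    else:
        raise ValueError(f"unknown trait kind {trait!r}")
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(dict(z=z, p=p))


@dataclass
class WgmvScore:
    scores: pd.Series  # participant -> wGMV
    weights: pd.Series  # ROI -> weight (case-control z)

    def to_frame(self) -> pd.DataFrame:
        return self.scores.rename("wgmv").to_frame()


def compute_wgmv(centile_table: pd.DataFrame, roi_weights: pd.Series) -> WgmvScore:
    """wGMV = sum_r w_r * centile_r per participant; linear in centiles."""
    missing = [r for r in roi_weights.index if r not in centile_table.columns]
    if missing:
        raise ValueError(f"centile table lacks weighted ROIs: {missing}")
    w = roi_weights.astype(float)
    s = centile_table[w.index].to_numpy(float) @ w.to_numpy()
    return WgmvScore(scores=pd.Series(s, index=centile_table.index), weights=w)


class _Fenwick:
    """Binary indexed tree supporting point update and prefix query."""

    def __init__(self, n, op="sum"):
        self.n = n
        self.op = op
        init = 0.0 if op == "sum" else -np.inf
        self.t = np.full(n + 1, init)

    def update(self, i, v):
        i += 1
        while i <= self.n:
            self.t[i] = self.t[i] + v if self.op == "sum" else max(self.t[i], v)
            i += i & (-i)

    def query(self, i):
        i += 1
        acc = 0.0 if self.op == "sum" else -np.inf
        while i > 0:
            acc = acc + self.t[i] if self.op == "sum" else max(acc, self.t[i])
            i -= i & (-i)
        return acc


def _p2_groups(p2_order, p2):
    """Yield runs of indices (in p2-ascending order) sharing the same p2."""
    start = 0
    m = len(p2_order)
    while start < m:
        stop = start
        while stop + 1 < m and p2[p2_order[stop + 1]] == p2[p2_order[start]]:
            stop += 1
        yield p2_order[start : stop + 1]
        start = stop + 1


def cond_fdr(p_primary, p_secondary, monotone: bool = True) -> np.ndarray:
    """Conditional FDR of the primary p-values given the secondary trait.

    For SNP i the conditional empirical CDF is
        F(p1_i | p2 <= p2_i) = #{j: p1_j <= p1_i and p2_j <= p2_i}
                               / #{j: p2_j <= p2_i}
    and condFDR_i = min(1, p1_i / F).  With ``monotone=True`` the raw value
    is replaced by the running maximum over {j: p1_j <= p1_i and
    p2_j >= p2_i}: condFDR is forced non-decreasing along increasing p1,
    and a tighter conditioning threshold can never report more signal than
    any looser stratum did at the same p1.  Without this step the per-SNP
    empirical CDF is anticonservative for isolated doubly-extreme SNPs,
    whose conditioning strata contain only a handful of variants.

    Implemented with an O(n log n) sweep; equals the brute-force
    double-loop evaluation of the definitions exactly.
    """
    p1 = np.asarray(p_primary, dtype=float)
    p2 = np.asarray(p_secondary, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError("p-value vectors must be 1-D and equal length")
    if len(p1) < 100:
        raise ValueError("need >= 100 SNPs")
    if np.any((p1 <= 0) | (p1 > 1)) or np.any((p2 <= 0) | (p2 > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p1)
    sorted_p1 = np.sort(p1)
    rank1 = np.searchsorted(sorted_p1, p1, side="right") - 1  # 0-based, ties merged
    order2 = np.argsort(p2, kind="stable")

    raw = np.empty(n)
    bit = _Fenwick(n, op="sum")
    inserted = 0
    for grp in _p2_groups(order2, p2):
        for i in grp:
            bit.update(rank1[i], 1.0)
        inserted += len(grp)
        for i in grp:
            count = bit.query(rank1[i])
            assert count >= 1, "conditioning stratum cannot be empty"
            raw[i] = min(1.0, p1[i] * inserted / count)
    if not monotone:
        return raw

    # sweep p2 descending so the tree holds every j with p2_j >= p2_i
    out = np.empty(n)
    mbit = _Fenwick(n, op="max")
    for grp in _p2_groups(order2[::-1], p2):
        for i in grp:
            mbit.update(rank1[i], raw[i])
        for i in grp:
            out[i] = mbit.query(rank1[i])
    return out


def conj_fdr(gwas: pd.DataFrame, alpha: float = 0.05, monotone: bool = True) -> pd.DataFrame:
    """Conjunctional FDR: the maximum of the two conditional FDRs.

    Expects columns P1 and P2; returns a copy with condFDR_1_2 (trait 1
    conditioned on trait 2), condFDR_2_1, conjFDR and a boolean
    significance column at ``alpha``.
    """
    for c in ("P1", "P2"):
        if c not in gwas.columns:
            raise ValueError(f"missing column {c}")
    out = gwas.copy()
    out["condFDR_1_2"] = cond_fdr(gwas["P1"], gwas["P2"], monotone=monotone)
    out["condFDR_2_1"] = cond_fdr(gwas["P2"], gwas["P1"], monotone=monotone)
    out["conjFDR"] = np.maximum(out["condFDR_1_2"], out["condFDR_2_1"])
    out["significant"] = out["conjFDR"] < alpha
    return out


def clump_loci(snps: pd.DataFrame, window_bp: int = 250_000) -> pd.DataFrame:
    """Greedy distance clumping of significant SNPs into loci.

    SNPs are processed in ascending conjFDR order; a SNP joins an existing
    locus when it sits on the same chromosome within ``window_bp`` of that
    locus's index SNP, else it seeds a new locus.  Returns a copy with
    'locus' ids and an 'is_index' flag.
    """
    out = snps.copy()
    out["locus"] = -1
    out["is_index"] = False
    loci = []  # (chrom, pos of index snp)
    sort_col = "conjFDR" if "conjFDR" in out.columns else "P1"
    for i in out.sort_values(sort_col).index:
        chrom, pos = out.at[i, "CHR"], out.at[i, "POS"]
        for lid, (lc, lp) in enumerate(loci):
            if lc == chrom and abs(pos - lp) <= window_bp:
                out.at[i, "locus"] = lid
                break
        else:
            out.at[i, "locus"] = len(loci)
            out.at[i, "is_index"] = True
            loci.append((chrom, pos))
    return out


AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def align_alleles(summary: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Match summary SNPs to genotype metadata on id + alleles.

    Flips effect signs for swapped alleles and drops strand-ambiguous
    (A/T, C/G) variants when allele columns are present on both sides;
    otherwise matches on SNP id alone.
    """
    if not {"A1", "A2"}.issubset(summary.columns) or not {"A1", "A2"}.issubset(
        meta.columns
    ):
        return summary[summary["SNP"].isin(meta["SNP"])].copy()
    merged = summary.merge(meta[["SNP", "A1", "A2"]], on="SNP", suffixes=("", "_geno"))
    amb = merged.apply(lambda r: (r["A1"], r["A2"]) in AMBIGUOUS, axis=1)
    merged = merged[~amb].copy()
    same = (merged["A1"] == merged["A1_geno"]) & (merged["A2"] == merged["A2_geno"])
    swap = (merged["A1"] == merged["A2_geno"]) & (merged["A2"] == merged["A1_geno"])
    merged = merged[same | swap].copy()
    flip = swap[same | swap]
    for c in ("BETA", "Z", "Z1"):
        if c in merged.columns:
            merged.loc[flip, c] = -merged.loc[flip, c]
    return merged.drop(columns=["A1_geno", "A2_geno"])


def ld_prune(
    genotypes: np.ndarray,
    meta: pd.DataFrame,
    pvals: np.ndarray,
    window_bp: int = 50_000,
    step: int = 5,
    r2_threshold: float = 0.1,
) -> np.ndarray:
    """PLINK-style sliding-window LD pruning; returns a keep mask.

    Within each window of ``window_bp`` the SNP with the larger p-value of
    any pair with r^2 above the threshold is removed; the window then
    advances by ``step`` variants.
    """
    G = np.asarray(genotypes, dtype=float)
    m = G.shape[1]
    keep = np.ones(m, dtype=bool)
    pos = meta["POS"].to_numpy()
    chrom = meta["CHR"].to_numpy()
    Gc = G - G.mean(axis=0)
    norms = np.sqrt((Gc**2).sum(axis=0))
    norms[norms == 0] = np.inf

    start = 0
    while start < m:
        end = start
        while (
            end + 1 < m
            and chrom[end + 1] == chrom[start]
            and pos[end + 1] - pos[start] <= window_bp
        ):
            end += 1
        idx = [j for j in range(start, end + 1) if keep[j]]
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if not (keep[i] and keep[j]):
                    continue
                r = (Gc[:, i] @ Gc[:, j]) / (norms[i] * norms[j])
                if r**2 > r2_threshold:
                    drop = i if pvals[i] > pvals[j] else j
                    keep[drop] = False
        start += step
    return keep


def prs_correlation(
    train_summary: pd.DataFrame,
    test_genotypes: np.ndarray,
    test_meta: pd.DataFrame,
    test_phenotype,
    covariates: np.ndarray | None = None,
    window_bp: int = 50_000,
    step: int = 5,
    r2_threshold: float = 0.1,
    bias_correction: float | None = None,
):
    """Polygenic score on the test sample after LD pruning, and its
    (partial) correlation with the phenotype.

    ``train_summary`` needs SNP + an effect column (BETA, else Z); the
    pruning keeps the smaller-p member of correlated pairs.  An optional
    multiplicative ``bias_correction`` factor is applied to the
    correlation estimate (pluggable, for externally derived corrections).
    Returns (pgs array, corrected r, p-value, keep mask over test SNPs).
    """
    summary = align_alleles(train_summary, test_meta)
    eff_col = "BETA" if "BETA" in summary.columns else "Z"
    pcol = "P" if "P" in summary.columns else "P1"
    snp_to_eff = dict(zip(summary["SNP"], summary[eff_col].astype(float)))
    snp_to_p = dict(zip(summary["SNP"], summary[pcol].astype(float)))

    in_train = test_meta["SNP"].isin(snp_to_eff).to_numpy()
    if not in_train.any():
        raise ValueError("no overlapping SNP ids")
    G = np.asarray(test_genotypes, dtype=float)[:, in_train]
    meta = test_meta.loc[in_train].reset_index(drop=True)
    pvals = meta["SNP"].map(snp_to_p).to_numpy(float)
    keep = ld_prune(G, meta, pvals, window_bp, step, r2_threshold)
    if not keep.any():
        raise ValueError("no SNPs survive pruning")
    betas = meta["SNP"].map(snp_to_eff).to_numpy(float)[keep]
    pgs = G[:, keep] @ betas

    y = np.asarray(test_phenotype, dtype=float)
    x = pgs.copy()
    if covariates is not None:
        X = np.column_stack([np.ones(len(y)), np.asarray(covariates, float)])
        x = _residualize(x, X)
        y = _residualize(y, X)
    r = float(np.corrcoef(x, y)[0, 1])
    if bias_correction is not None:
        r *= bias_correction
    dof = len(y) - 2 - (0 if covariates is None else np.atleast_2d(covariates).shape[1])
    t = r * np.sqrt(dof / max(1e-300, 1 - r**2))
    p = float(2 * stats.t.sf(abs(t), dof))
    full_keep = np.zeros(len(test_meta), dtype=bool)
    full_keep[np.where(in_train)[0][keep]] = True
    return pgs, r, p, full_keep


def write_gwas_table(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


def read_gwas_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
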