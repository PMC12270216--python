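"""Synthetic lifespan cohort, behavior, GWAS and atlas generators.

Everything the analysis consumes can be generated here with known ground
truth: four age-staggered cohorts with site/scanner batch effects and a
planted case-control volume-difference curve per region; behavioral items
loading on latent factors correlated with regional centiles; two GWAS
traits with a planted fraction of shared causal variants in AR(1)-style LD
blocks; and term-by-region cognitive atlas matrices with known loadings.

Group-difference curves follow the shapes reported for substance-use
case-control contrasts: an inverted U over age for cortical regions and a
monotone decay over age for subcortical regions, both expressed in units of
the within-age volume SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .dists import gg_ppf, gg_cdf, gg_mean, gg_var

__all__ = [
    "RoiTruth",
    "CohortSpec",
    "BehaviorTruth",
    "GwasTruth",
    "TruthSpec",
    "CohortTruth",
    "generate_cohorts",
    "generate_behavior",
    "generate_gwas",
    "generate_genotypes",
    "simulate_phenotype",
    "generate_atlas",
]

#: the 24 addiction-circuit regions (Desikan-Killiany / ASEG naming)
DEFAULT_ROIS = [
    (f"{h}_{name}", kind)
    for name, kind in [
        ("accumbens", "subcortical"),
        ("caudate", "subcortical"),
        ("putamen", "subcortical"),
        ("amygdala", "subcortical"),
        ("hippocampus", "subcortical"),
        ("insula", "cortical"),
        ("frontalpole", "cortical"),
        ("medialorbitofrontal", "cortical"),
        ("lateralorbitofrontal", "cortical"),
        ("superiorfrontal", "cortical"),
        ("rostralanteriorcingulate", "cortical"),
        ("caudalanteriorcingulate", "cortical"),
    ]
    for h in ("L", "R")
]


@dataclass
class RoiTruth:
    """Ground-truth generative model for one region's volume."""

    name: str
    kind: str = "cortical"  # cortical -> inverted-U delta; subcortical -> decay
    # median-volume curve on the log scale: log mu = b0 + b1*sqrt(t) + b2*t,
    # t = age / 10
    b0: float = 8.0
    b1: float = 0.5
    b2: float = -0.25
    sigma: float = 0.15
    nu: float = 0.7
    # group-difference curve parameters (units of within-age SD)
    delta_amp: float = 0.3
    delta_peak: float = 45.0
    delta_width: float = 12.0
    delta_tau: float = 20.0

    def mu(self, age):
        t = np.asarray(age, dtype=float) / 10.0
        return np.exp(self.b0 + self.b1 * np.sqrt(t) + self.b2 * t)

    def delta(self, age):
        """Case-minus-control shift at ``age`` in within-age SD units."""
        age = np.asarray(age, dtype=float)
        if self.delta_amp == 0:
            return np.zeros_like(age)
        if self.kind == "subcortical":
            return -self.delta_amp * np.exp(-(age - 8.0) / self.delta_tau)
        return -self.delta_amp * np.exp(
            -0.5 * ((age - self.delta_peak) / self.delta_width) ** 2
        )

    def sd(self, age):
        return np.sqrt(gg_var(self.mu(age), self.sigma, self.nu))


@dataclass
class CohortSpec:
    name: str
    age_min: float
    age_max: float
    n_sites: int = 2
    sud_fraction: float = 0.25
    visit_policy: str = "baseline-only"  # or "sampled"
    longitudinal_fraction: float = 0.0
    followup_years: float = 2.0


def _default_cohorts():
    return [
        CohortSpec("adolescent", 9, 13, n_sites=3, longitudinal_fraction=0.3),
        CohortSpec("youth", 14, 23, n_sites=2, visit_policy="sampled"),
        CohortSpec("young_adult", 22, 37, n_sites=2),
        CohortSpec("aging", 45, 73, n_sites=2),
    ]


@dataclass
class BehaviorTruth:
    """Latent two-factor structure behind the behavioral item battery."""

    loadings: np.ndarray = field(
        default_factory=lambda: np.vstack(
            [
                np.column_stack([np.full(4, 0.7), np.zeros(4)]),
                np.column_stack([np.zeros(4), np.full(4, 0.7)]),
            ]
        )
    )
    #: factor index -> (roi index, target factor-centile correlation)
    centile_targets: dict = field(default_factory=lambda: {0: (0, 0.3)})
    item_names: list | None = None

    def uniqueness(self):
        return 1.0 - np.sum(self.loadings**2, axis=1)


@dataclass
class GwasTruth:
    n_snps: int = 20_000
    n_chrom: int = 4
    causal_frac: float = 0.01
    shared_frac: float = 0.002
    effect_sd: float = 4.0
    shared_effect: float = 6.0
    ld_block_size: int = 5
    ld_r: float = 0.8
    maf_range: tuple = (0.05, 0.5)


@dataclass
class TruthSpec:
    """Full ground truth for one synthetic study.

    The defaults encode the study conditions the analysis targets: four
    cohorts spanning roughly 9-73y, >=2 sites per cohort with
    location-scale scanner effects, additive sex/handedness effects,
    positively skewed generalized-gamma volume noise, and the
    cortical/subcortical group-difference shapes.
    """

    rois: list = field(
        default_factory=lambda: [RoiTruth(name, kind) for name, kind in DEFAULT_ROIS]
    )
    cohorts: list = field(default_factory=_default_cohorts)
    site_shift_sd: float = 40.0  # mm^3
    site_scale_sd: float = 0.07  # log-scale SD of the multiplicative factor
    sex_effect: float = 150.0  # mm^3 added for sex == 1 (male)
    hand_effect: float = 25.0  # mm^3 added for handedness == 1 (left)
    behavior: BehaviorTruth = field(default_factory=BehaviorTruth)
    gwas: GwasTruth = field(default_factory=GwasTruth)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("ROI list must be non-empty")
        if not (0.0 <= self.gwas.shared_frac <= 1.0):
            raise ValueError("shared-causal fraction must lie in [0, 1]")
        if self.gwas.shared_frac > self.gwas.causal_frac:
            raise ValueError("shared fraction cannot exceed causal fraction")
        lam = self.behavior.loadings
        if lam.ndim != 2 or lam.shape[1] < 2:
            raise ValueError("behavioral loadings need >= 2 factors")
        if np.any(np.all(lam == 0, axis=0)):
            raise ValueError("behavioral loadings contain an all-zero factor column")
        for t in self.centile_corrs().values():
            if not abs(t) < 1:
                raise ValueError("|factor-centile correlation| must be < 1")

    def centile_corrs(self):
        return {k: v[1] for k, v in self.behavior.centile_targets.items()}

    @property
    def roi_names(self):
        return [r.name for r in self.rois]

    def to_json(self) -> str:
        d = asdict(self)
        d["behavior"]["loadings"] = self.behavior.loadings.tolist()
        return json.dumps(d, indent=2, default=str)


@dataclass
class CohortTruth:
    """Ground truth attached to one generated cohort table."""

    spec: TruthSpec
    true_centiles: pd.DataFrame  # same index as the table, one column per ROI


def generate_cohorts(
    spec: TruthSpec, n_per_cohort: int, seed=None
) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate the pooled multi-cohort scan table.

    One row per scan.  Healthy-control volumes are drawn from the baseline
    generalized-gamma model; case volumes are additionally shifted by
    delta_r(age) times the within-age SD.  Site effects are location-scale
    on the residual around the covariate-conditional mean, i.e. exactly the
    model ComBat assumes.  A configurable fraction of the first cohort
    receives a second visit ``followup_years`` later, re-using the
    participant's latent quantile so that within-person volumes are
    strongly correlated across visits.
    """
    if n_per_cohort < 50:
        raise ValueError("need n_per_cohort >= 50")
    if not spec.rois:
        raise ValueError("empty ROI list")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    rows, cent_rows = [], []
    pid = 0
    for coh in spec.cohorts:
        site_names = [f"{coh.name}_site{k}" for k in range(coh.n_sites)]
        shifts = rng.normal(0.0, spec.site_shift_sd, size=coh.n_sites)
        scales = np.exp(rng.normal(0.0, spec.site_scale_sd, size=coh.n_sites))
        ages = rng.uniform(coh.age_min, coh.age_max, size=n_per_cohort)
        sexes = rng.integers(0, 2, size=n_per_cohort)
        hands = (rng.random(n_per_cohort) < 0.1).astype(int)
        sites = rng.integers(0, coh.n_sites, size=n_per_cohort)
        groups = np.where(rng.random(n_per_cohort) < coh.sud_fraction, "SUD", "HC")
        u = rng.random((n_per_cohort, len(spec.rois)))
        followup = (
            rng.random(n_per_cohort) < coh.longitudinal_fraction
            if coh.longitudinal_fraction > 0
            else np.zeros(n_per_cohort, dtype=bool)
        )

        for i in range(n_per_cohort):
            visits = [(1, ages[i])]
            if followup[i]:
                visits.append((2, ages[i] + coh.followup_years))
            for visit, age in visits:
                vols, cents = {}, {}
                for j, roi in enumerate(spec.rois):
                    mu = roi.mu(age)
                    y0 = gg_ppf(u[i, j], mu, roi.sigma, roi.nu)
                    m = gg_mean(mu, roi.sigma, roi.nu)
                    shift = 0.0
                    if groups[i] == "SUD":
                        shift = roi.delta(age) * roi.sd(age)
                    cond_mean = (
                        m
                        + shift
                        + spec.sex_effect * sexes[i]
                        + spec.hand_effect * hands[i]
                    )
                    resid = y0 - m
                    y = cond_mean + shifts[sites[i]] + scales[sites[i]] * resid
                    vols[roi.name] = max(y, 1.0)
                    cents[roi.name] = gg_cdf(
                        max(y0 + shift, 1e-6), mu, roi.sigma, roi.nu
                    )
                rows.append(
                    dict(
                        participant_id=f"P{pid:06d}",
                        cohort=coh.name,
                        site=site_names[sites[i]],
                        visit=visit,
                        age=age,
                        sex=int(sexes[i]),
                        handedness=int(hands[i]),
                        group=groups[i],
                        **vols,
                    )
                )
                cent_rows.append(cents)
            pid += 1

    table = pd.DataFrame(rows)
    centiles = pd.DataFrame(cent_rows, index=table.index).astype(float)
    return table, CohortTruth(spec=spec, true_centiles=centiles)


def generate_behavior(
    cohorts: pd.DataFrame,
    spec: TruthSpec,
    centiles: pd.DataFrame | None = None,
    seed=None,
    cohort_items: dict | None = None,
) -> pd.DataFrame:
    """Item scores = loadings @ latent factors + uniqueness noise.

    Latent factors are built to hit the target factor-centile correlations:
    factor = r * probit(centile of the target ROI) + sqrt(1 - r^2) * noise.
    ``cohort_items`` maps cohort name -> list of item names to keep
    (different instruments per study); unlisted cohorts keep all items.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    lam = spec.behavior.loadings
    n_items, n_fac = lam.shape
    if n_fac < 2 or n_items < 3 * n_fac:
        raise ValueError("need >= 2 factors with >= 3 items each")
    if np.any(np.all(lam == 0, axis=0)):
        raise ValueError("all-zero loading column")

    base = cohorts.drop_duplicates("participant_id")
    base_idx = base.index
    base = base.set_index("participant_id")
    n = len(base)
    factors = rng.standard_normal((n, n_fac))
    if centiles is not None:
        cent_base = centiles.loc[base_idx]
        for k, (roi_idx, r) in spec.behavior.centile_targets.items():
            c = np.clip(cent_base.iloc[:, roi_idx].to_numpy(float), 1e-9, 1 - 1e-9)
            z = norm.ppf(c)
            z = (z - z.mean()) / z.std()
            factors[:, k] = r * z + np.sqrt(1 - r**2) * rng.standard_normal(n)

    psi = np.sqrt(np.clip(spec.behavior.uniqueness(), 1e-6, None))
    items = factors @ lam.T + rng.standard_normal((n, n_items)) * psi
    names = spec.behavior.item_names or [f"item{j:02d}" for j in range(n_items)]
    out = pd.DataFrame(items, index=base.index, columns=names)
    out.insert(0, "cohort", base["cohort"])
    out.insert(1, "group", base["group"])
    if cohort_items:
        for coh, keep in cohort_items.items():
            drop = [c for c in names if c not in keep]
            out.loc[out["cohort"] == coh, drop] = np.nan
    return out.reset_index()


def _snp_positions(rng, n_snps, n_chrom):
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=n_snps))
    pos = np.empty(n_snps, dtype=int)
    for c in range(1, n_chrom + 1):
        m = chrom == c
        pos[m] = np.cumsum(rng.integers(2_000, 8_000, size=m.sum())) + 10_000
    return chrom, pos


def generate_gwas(spec: TruthSpec, seed=None) -> tuple[pd.DataFrame, dict]:
    """Two traits' per-SNP z-scores with planted (shared) causal variants.

    Null SNPs are standard normal; causal SNPs receive a mean shift of
    random sign.  Shared-causal SNPs shift both traits (concordant sign,
    magnitude ``shared_effect``); trait-specific causal SNPs shift one
    trait by N(0, effect_sd) draws.  Returns the summary table and a truth
    dict with the causal index sets.
    """
    g = spec.gwas
    if g.n_snps < 1000:
        raise ValueError("need >= 1000 SNPs")
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    n = g.n_snps
    chrom, pos = _snp_positions(rng, n, g.n_chrom)

    n_causal = int(round(g.causal_frac * n))
    n_shared = int(round(g.shared_frac * n))
    causal = rng.choice(n, size=n_causal, replace=False)
    shared = causal[:n_shared]
    only1 = causal[n_shared : n_shared + (n_causal - n_shared) // 2]
    only2 = causal[n_shared + (n_causal - n_shared) // 2 :]

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    sign = rng.choice([-1.0, 1.0], size=n_shared)
    z1[shared] += sign * g.shared_effect
    z2[shared] += sign * g.shared_effect
    z1[only1] += rng.normal(0.0, g.effect_sd, size=len(only1))
    z2[only2] += rng.normal(0.0, g.effect_sd, size=len(only2))

    from scipy.stats import norm

    tab = pd.DataFrame(
        dict(
            SNP=[f"rs{i:07d}" for i in range(n)],
            CHR=chrom,
            POS=pos,
            Z1=z1,
            P1=np.clip(2 * norm.sf(np.abs(z1)), 1e-300, 1.0),
            Z2=z2,
            P2=np.clip(2 * norm.sf(np.abs(z2)), 1e-300, 1.0),
        )
    )
    truth = dict(shared=np.sort(shared), only1=np.sort(only1), only2=np.sort(only2))
    return tab, truth


def generate_genotypes(
    n_individuals: int,
    n_snps: int,
    ld_block_size: int = 5,
    ld_r: float = 0.8,
    maf_range=(0.05, 0.5),
    n_chrom: int = 4,
    seed=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """0/1/2 genotypes in LD blocks via an allele-copying Markov chain.

    Within a block, haplotype allele j+1 copies allele j with probability
    ``ld_r`` (else a fresh Bernoulli draw at that SNP's allele frequency),
    so adjacent-SNP genotype correlation is ld_r and decays geometrically
    with distance.  Blocks and chromosomes are independent.
    """
    rng = np.random.default_rng(seed)
    chrom, pos = _snp_positions(rng, n_snps, n_chrom)
    maf = rng.uniform(*maf_range, size=n_snps)
    block = np.arange(n_snps) // ld_block_size

    haps = np.empty((2, n_individuals, n_snps), dtype=np.int8)
    for h in range(2):
        fresh = rng.random((n_individuals, n_snps)) < maf
        copy = rng.random((n_individuals, n_snps)) < ld_r
        hap = fresh.copy()
        for j in range(1, n_snps):
            if block[j] == block[j - 1] and chrom[j] == chrom[j - 1]:
                hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
        haps[h] = hap
    geno = haps[0].astype(np.int16) + haps[1]
    meta = pd.DataFrame(
        dict(SNP=[f"rs{i:07d}" for i in range(n_snps)], CHR=chrom, POS=pos, MAF=maf)
    )
    return geno.astype(float), meta


def simulate_phenotype(genotypes, betas, h2: float = 0.2, seed=None):
    """Quantitative phenotype g @ beta rescaled to heritability h2 + noise."""
    rng = np.random.default_rng(seed)
    g = np.asarray(genotypes, dtype=float)
    gv = g @ np.asarray(betas, dtype=float)
    if gv.std() > 0:
        gv = gv / gv.std() * np.sqrt(h2)
    return gv + rng.standard_normal(len(gv)) * np.sqrt(1 - h2)


def generate_atlas(
    n_terms: int, n_rois: int, n_factors: int, noise_sd: float = 0.1, seed=None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Term-by-ROI matrix = loadings @ ROI factor scores + noise.

    Returns the matrix (rows = cognitive terms, columns = ROI names) and
    the true term loadings for recovery tests.
    """
    if n_factors >= min(n_terms, n_rois) or min(n_terms, n_rois, n_factors) < 1:
        raise ValueError("need 1 <= n_factors < min(n_terms, n_rois)")
    rng = np.random.default_rng(seed)
    # block-structured loadings: each factor owns a contiguous run of terms
    lam = np.zeros((n_terms, n_factors))
    bounds = np.linspace(0, n_terms, n_factors + 1).astype(int)
    for k in range(n_factors):
        lam[bounds[k] : bounds[k + 1], k] = rng.uniform(0.6, 0.9, bounds[k + 1] - bounds[k])
    scores = rng.standard_normal((n_factors, n_rois))
    mat = lam @ scores + rng.standard_normal((n_terms, n_rois)) * noise_sd
    df = pd.DataFrame(
        mat,
        index=[f"term{i:03d}" for i in range(n_terms)],
        columns=[f"roi{j:02d}" for j in range(n_rois)],
    )
    return df, lam
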