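"""End-to-end orchestration of the synthetic lifespan analysis.

Runs prep -> normative -> trajectories -> behavior -> atlas -> genomics on
configured (by default synthetic) inputs, writes every stage's outputs as
TSV/JSON with a provenance log, and provides the small report helpers
(conversion rates, whole-number fractions) used in summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_EVEN
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import prep, synth
from .behavior import extract_composites, brain_behavior_corr, group_compare
from .atlas import atlas_factorize, lifespan_association
from .genomics import compute_wgmv, conj_fdr, clump_loci
from .normative import FPSpec, fit_normative
from .trajectories import adjust_covariates, fit_group_trajectory, compare_grid

log = logging.getLogger("lifetraj")

__all__ = ["RunConfig", "run_pipeline", "conversion_rate", "fraction_report", "relabel_mild_sud"]


def conversion_rate(n_converted: int, n_baseline: int) -> float:
    """Percentage of baseline controls converting to cases, 2 decimals
    (banker's rounding)."""
    if n_baseline <= 0:
        raise ValueError("zero baseline denominator")
    if not 0 <= n_converted <= n_baseline:
        raise ValueError("converted count outside [0, baseline]")
    pct = Decimal(100 * n_converted) / Decimal(n_baseline)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def fraction_report(k: int, n: int) -> int:
    """Whole-number percentage, half-even rounded."""
    if n <= 0:
        raise ValueError("zero denominator")
    if not 0 <= k <= n:
        raise ValueError("numerator outside [0, n]")
    pct = Decimal(100 * k) / Decimal(n)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_EVEN))


def relabel_mild_sud(table: pd.DataFrame, adult_cohorts) -> pd.DataFrame:
    """Sensitivity relabeling: adult healthy controls become mild cases."""
    out = table.copy()
    m = out["cohort"].isin(adult_cohorts) & (out["group"] == "HC")
    out.loc[m, "group"] = "SUD"
    return out


@dataclass
class RunConfig:
    """Serializable configuration for one pipeline run."""

    out_dir: str = "lifetraj_run"
    n_per_cohort: int = 2000
    n_rois: int | None = 12  # None -> all 24 regions
    qc_iqr: float = 4.0
    age_min: float = 8.0
    age_max: float = 70.0
    step: float = 0.05
    alpha: float = 0.05
    atlas_terms: int = 40
    atlas_factors: int = 3
    seed: int = 0
    mild_sud_sensitivity: bool = False
    adult_cohorts: tuple = ("young_adult", "aging")
    mu_candidates: tuple = ((0.5, 1.0), (1.0,))

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["adult_cohorts"] = tuple(d.get("adult_cohorts", ()))
        d["mu_candidates"] = tuple(tuple(m) for m in d.get("mu_candidates", ()))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, **kw):
    df.to_csv(path, sep="\t", **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on a synthetic study; return the artifact bundle.

    Deterministic given ``config.seed``; every output file is stamped with
    the config hash in the provenance log.
    """
    rng_seed = config.seed
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config": config}

    def stage(name):
        log.info("stage: %s", name)

    # -- synth + prep -------------------------------------------------------
    stage("synthdata")
    spec = synth.TruthSpec(seed=rng_seed)
    if config.n_rois is not None:
        spec.rois = spec.rois[: config.n_rois]
    table, truth = synth.generate_cohorts(spec, config.n_per_cohort, seed=rng_seed)
    rois = spec.roi_names
    if config.mild_sud_sensitivity:
        table = relabel_mild_sud(table, config.adult_cohorts)

    stage("prep")
    table, qc = prep.qc_filter(table, rois, iqr_mult=config.qc_iqr)
    truth_cent = truth.true_centiles.loc[table.index]
    cross = prep.select_cross_sectional(table, sampled_cohorts=["youth"], seed=rng_seed)
    cross = prep.combat_per_cohort(cross, rois=rois)
    artifacts["qc"] = qc
    artifacts["table"] = cross
    _write(cross, out / "cohort_adjusted.tsv", index=False)
    (out / "qc_report.json").write_text(json.dumps(qc.to_dict(), indent=2))

    # -- normative ----------------------------------------------------------
    stage("normative")
    hc = cross[cross["group"] == "HC"]
    candidates = [FPSpec(m) for m in config.mu_candidates]
    fits, cent_cols = {}, {}
    for r in rois:
        fit = fit_normative(hc, r, candidate_specs=candidates, random_effect=False,
                            seed=rng_seed)
        fits[r] = fit
        cent_cols[r] = fit.predict_centile(
            cross[r].to_numpy(), cross["age"].to_numpy(),
            sex=cross["sex"].to_numpy(), handedness=cross["handedness"].to_numpy(),
            extrapolation_margin=5.0,
        )
    centiles = pd.DataFrame(cent_cols, index=cross.index)
    artifacts["normative"] = fits
    artifacts["centiles"] = centiles
    cent_out = centiles.copy()
    cent_out.insert(0, "participant_id", cross["participant_id"])
    _write(cent_out, out / "centiles.tsv", index=False)
    (out / "normative_fits.json").write_text(
        json.dumps({r: json.loads(f.to_json()) for r, f in fits.items()}, indent=2)
    )

    # -- trajectories -------------------------------------------------------
    stage("trajectories")
    adjusted = adjust_covariates(cross, rois)
    grids = {}
    for r in rois:
        f_sud = fit_group_trajectory(adjusted, "SUD", r)
        f_hc = fit_group_trajectory(adjusted, "HC", r)
        grids[r] = compare_grid(
            f_sud, f_hc, roi=r,
            age_min=config.age_min, age_max=config.age_max,
            step=config.step, alpha=config.alpha,
        )
    artifacts["grids"] = grids
    grid_all = pd.concat(
        [g.grid.assign(roi=r) for r, g in grids.items()], ignore_index=True
    )
    _write(grid_all, out / "trajectory_grid.tsv", index=False)
    (out / "significant_windows.json").write_text(
        json.dumps({r: g.windows for r, g in grids.items()}, indent=2)
    )

    # -- behavior -----------------------------------------------------------
    stage("behavior")
    items = synth.generate_behavior(table, spec, centiles=truth_cent, seed=rng_seed + 1)
    fm = extract_composites(items)
    artifacts["behavior_factors"] = fm
    effects = []
    if fm.n_factors >= 1 and fm.scores is not None and len(fm.scores):
        scores = fm.scores.copy()
        scores.index = items.dropna(axis=0, how="any")["participant_id"].to_numpy()
        common = cross.set_index("participant_id").index.intersection(scores.index)
        cent_by_pid = centiles.set_axis(cross["participant_id"].to_numpy(), axis=0)
        effects = brain_behavior_corr(
            scores.loc[common, fm.scores.columns[0]], cent_by_pid.loc[common],
            study="synthetic",
        )
    artifacts["brain_behavior"] = effects
    if effects:
        _write(pd.DataFrame([e.as_dict() for e in effects]),
               out / "brain_behavior.tsv", index=False)

    # -- atlas --------------------------------------------------------------
    stage("atlas")
    term_mat, true_load = synth.generate_atlas(
        config.atlas_terms, len(rois), config.atlas_factors, seed=rng_seed + 2
    )
    term_mat.columns = rois
    afs = atlas_factorize(term_mat) if len(rois) >= 10 else None
    artifacts["atlas_factors"] = afs
    if afs is not None:
        half_ages = np.arange(config.age_min, config.age_max + 1e-9, 0.5)
        z_by_age = pd.DataFrame(
            {a: [np.interp(a, grids[r].ages, grids[r].z) for r in rois]
             for a in half_ages},
            index=rois,
        )
        tracks = lifespan_association(
            afs.roi_maps, z_by_age, n_perm=500, seed=rng_seed + 3
        )
        artifacts["atlas_tracks"] = tracks
        _write(
            pd.concat([t.track.assign(factor=f) for f, t in tracks.items()],
                      ignore_index=True),
            out / "atlas_tracks.tsv", index=False,
        )

    # -- genomics -----------------------------------------------------------
    stage("genomics")
    z_mean = pd.Series({r: float(np.mean(grids[r].z)) for r in rois})
    wgmv = compute_wgmv(centiles, z_mean)
    gwas, gwas_truth = synth.generate_gwas(spec, seed=rng_seed + 4)
    gwas = conj_fdr(gwas, alpha=config.alpha)
    sig = gwas[gwas["significant"]]
    loci = clump_loci(sig) if len(sig) else sig.assign(locus=[], is_index=[])
    artifacts["wgmv"] = wgmv
    artifacts["gwas"] = gwas
    artifacts["loci"] = loci
    artifacts["gwas_truth"] = gwas_truth
    artifacts["wgmv_effect"] = group_compare(
        wgmv.scores.to_numpy(), cross["group"].to_numpy(),
        measure="wgmv", study="synthetic",
    )
    _write(gwas, out / "gwas_conjfdr.tsv", index=False)
    if len(loci):
        _write(loci, out / "shared_loci.tsv", index=False)

    # -- provenance ---------------------------------------------------------
    prov = dict(
        config_hash=config.config_hash(),
        seed=config.seed,
        n_scans=int(len(table)),
        n_cross_sectional=int(len(cross)),
        n_significant_snps=int(len(sig)),
    )
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    (out / "config.json").write_text(config.to_json())
    artifacts["provenance"] = prov
    return artifacts
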