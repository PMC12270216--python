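"""Generalized-gamma GAMLSS normative models with fractional-polynomial age.

The normative model regresses the three generalized-gamma parameters of a
region's volume distribution on covariates, in the growth-chart style:

    log mu    = b0 + FP(age; p_mu) + b_sex*sex + b_hand*handedness (+ u_study)
    log sigma = c0 + FP(age; p_sigma)
    nu        = constant

where FP(age; p) is a fractional polynomial of rescaled age with powers
from {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (power 0 means log age; a repeated
power multiplies in another log-age factor), and u_study is an optional
Gaussian study random intercept on log mu, fitted by penalized joint
likelihood with its variance tau^2 profiled on an outer grid against a
Laplace-approximate marginal likelihood.  Model complexity (number of FP
terms, random effect in or out) is chosen by BIC.  Fitted healthy-control
models convert an individual's volume into an age- and sex-specific
centile via the generalized-gamma CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from scipy import optimize, special

from .dists import gg_cdf, gg_ppf, gg_logpdf

__all__ = [
    "FPSpec",
    "fp_basis",
    "GeneralizedGammaGAMLSS",
    "GAMLSSResults",
    "fit_normative",
    "default_candidates",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPSpec:
    """Fractional-polynomial powers for the mu and sigma predictors."""

    mu_powers: tuple = (1.0,)
    sigma_powers: tuple = ()

    def __post_init__(self):
        if not (1 <= len(self.mu_powers) <= 3):
            raise ValueError("mu takes 1-3 fractional-polynomial terms")
        if len(self.sigma_powers) > 2:
            raise ValueError("sigma takes at most 2 fractional-polynomial terms")
        for p in tuple(self.mu_powers) + tuple(self.sigma_powers):
            if p not in FP_POWERS:
                raise ValueError(f"power {p} not in the fractional-polynomial set")

    def label(self) -> str:
        return f"mu{list(self.mu_powers)}|sigma{list(self.sigma_powers)}"


def fp_basis(t, powers) -> np.ndarray:
    """Fractional-polynomial design columns for positive rescaled age ``t``.

    Repeated powers get an extra log(t) factor per repetition, per the
    standard Royston-Altman construction.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("rescaled age must be positive before powering")
    cols, seen = [], {}
    for p in powers:
        k = seen.get(p, 0)
        base = np.log(t) if p == 0.0 else t**p
        cols.append(base * np.log(t) ** k)
        seen[p] = k + 1
    return np.column_stack(cols) if cols else np.empty((len(t), 0))


def _rescale_age(age, offset):
    return (np.asarray(age, dtype=float) - offset + 1.0) / 10.0


class GeneralizedGammaGAMLSS:
    """Normative generalized-gamma model for one region's volumes.

    Parameters
    ----------
    volume : array, strictly positive volumes (mm^3)
    age : array, years
    sex, handedness : optional 0/1 covariate arrays (enter the mu predictor)
    study : optional study labels; enables the random-intercept candidate
    spec : FPSpec with the fractional-polynomial powers
    random_effect : include a Gaussian study intercept on log mu
    """

    def __init__(
        self,
        volume,
        age,
        sex=None,
        handedness=None,
        study=None,
        spec: FPSpec = FPSpec(),
        random_effect: bool = False,
        age_offset: float | None = None,
    ):
        self.y = np.asarray(volume, dtype=float)
        if np.any(self.y <= 0):
            raise ValueError("negative or zero volumes present")
        self.age = np.asarray(age, dtype=float)
        self.spec = spec
        self.age_offset = float(self.age.min()) if age_offset is None else age_offset
        t = _rescale_age(self.age, self.age_offset)
        n = len(self.y)

        cov_cols, cov_names = [], []
        for nm, v in [("sex", sex), ("handedness", handedness)]:
            if v is not None and np.ptp(np.asarray(v, dtype=float)) > 0:
                cov_cols.append(np.asarray(v, dtype=float))
                cov_names.append(nm)
        self.Xmu = np.column_stack(
            [np.ones(n), fp_basis(t, spec.mu_powers)] + cov_cols
        )
        self.mu_names = (
            ["const"]
            + [f"fp({p})" for p in spec.mu_powers]
            + cov_names
        )
        self.Xsig = np.column_stack([np.ones(n), fp_basis(t, spec.sigma_powers)])
        self.sig_names = ["s_const"] + [f"s_fp({p})" for p in spec.sigma_powers]

        if study is not None:
            study = np.asarray(study)
            self.studies = list(pd.unique(study))
            self.study_idx = np.array([self.studies.index(s) for s in study])
        else:
            self.studies, self.study_idx = [], None
        self.random_effect = bool(random_effect) and len(self.studies) > 1

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, roi: str, spec=FPSpec(), **kw):
        return cls(
            df[roi].to_numpy(),
            df["age"].to_numpy(),
            sex=df["sex"].to_numpy() if "sex" in df else None,
            handedness=df["handedness"].to_numpy() if "handedness" in df else None,
            study=df["cohort"].to_numpy() if "cohort" in df else None,
            spec=spec,
            **kw,
        )

    # -- likelihood ---------------------------------------------------------

    def _unpack(self, params):
        pm, ps = self.Xmu.shape[1], self.Xsig.shape[1]
        bmu = params[:pm]
        bsig = params[pm : pm + ps]
        nu = params[pm + ps]
        u = params[pm + ps + 1 :]
        return bmu, bsig, nu, u

    def _predictors(self, params):
        bmu, bsig, nu, u = self._unpack(params)
        eta = self.Xmu @ bmu
        if len(u) and self.study_idx is not None:
            eta = eta + u[self.study_idx]
        s = self.Xsig @ bsig
        return eta, s, nu

    def _nll(self, params, tau2):
        eta, s, nu = self._predictors(params)
        if abs(nu) < 1e-3:
            return 1e10
        sig = np.exp(np.clip(s, -10, 5))
        ll = gg_logpdf(self.y, np.exp(np.clip(eta, -20, 30)), sig, nu).sum()
        _, _, _, u = self._unpack(params)
        pen = (u**2).sum() / (2 * tau2) if len(u) else 0.0
        val = -(ll - pen)
        return val if np.isfinite(val) else 1e10

    def _grad(self, params, tau2):
        bmu, bsig, nu, u = self._unpack(params)
        eta, s, nu_ = self._predictors(params)
        sig = np.exp(np.clip(s, -10, 5))
        theta = 1.0 / (sig**2 * nu**2)
        w = np.log(self.y) - eta
        logz = np.clip(nu * w, -600, 600)
        z = np.exp(logz)
        dig = special.digamma(theta)
        # per-observation derivatives of the log-likelihood
        dl_deta = theta * nu * (z - 1.0)
        core = np.log(theta) + 1.0 + logz - z - dig
        dl_ds = -2.0 * theta * core
        dl_dnu = 1.0 / nu - (2.0 * theta / nu) * core + theta * w * (1.0 - z)

        g_mu = self.Xmu.T @ dl_deta
        g_sig = self.Xsig.T @ dl_ds
        g_nu = np.array([dl_dnu.sum()])
        pieces = [g_mu, g_sig, g_nu]
        if len(u):
            g_u = np.bincount(self.study_idx, weights=dl_deta, minlength=len(u))
            g_u = g_u - u / tau2
            pieces.append(g_u)
        g = np.concatenate(pieces)
        return -np.where(np.isfinite(g), g, 0.0)

    def _init_params(self, rng=None):
        ly = np.log(self.y)
        bmu, *_ = np.linalg.lstsq(self.Xmu, ly, rcond=None)
        resid_sd = float(np.std(ly - self.Xmu @ bmu))
        bsig = np.zeros(self.Xsig.shape[1])
        bsig[0] = np.log(max(resid_sd, 1e-3))
        base = np.concatenate([bmu, bsig, [1.0]])
        if self.random_effect:
            base = np.concatenate([base, np.zeros(len(self.studies))])
        return base

    def _optimize(self, tau2, n_starts=3, seed=0, gtol=1e-6, maxiter=500):
        rng = np.random.default_rng(seed)
        x0 = self._init_params()
        best = None
        starts = [x0]
        for k in range(n_starts - 1):
            pert = x0.copy()
            pert += rng.normal(0, 0.05, size=len(x0))
            pert[self.Xmu.shape[1] + self.Xsig.shape[1]] = [0.5, 2.0][k % 2]
            starts.append(pert)
        for st in starts:
            res = optimize.minimize(
                self._nll,
                st,
                args=(tau2,),
                jac=self._grad,
                method="L-BFGS-B",
                options=dict(maxiter=maxiter, gtol=gtol),
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    def _laplace_marginal(self, params, tau2):
        """Penalized loglik plus the Laplace correction for the intercepts."""
        nll = self._nll(params, tau2)
        eta, s, nu = self._predictors(params)
        sig = np.exp(np.clip(s, -10, 5))
        theta = 1.0 / (sig**2 * nu**2)
        z = np.exp(np.clip(nu * (np.log(self.y) - eta), -600, 600))
        h = np.bincount(
            self.study_idx, weights=theta * nu**2 * z, minlength=len(self.studies)
        )
        corr = -0.5 * np.sum(np.log1p(tau2 * h))
        return -nll + corr

    def fit(
        self,
        tau2_grid=None,
        n_starts: int = 3,
        seed: int = 0,
        gtol: float = 1e-6,
        maxiter: int = 500,
    ) -> "GAMLSSResults":
        n = len(self.y)
        if not self.random_effect:
            res = self._optimize(np.inf, n_starts, seed, gtol, maxiter)
            loglik = -self._nll(res.x, np.inf)
            tau2 = 0.0
            params = res.x
            converged = bool(res.success)
        else:
            if tau2_grid is None:
                ref = np.var(np.log(self.y))
                tau2_grid = ref * np.array([1e-4, 1e-3, 0.01, 0.05, 0.1, 0.3, 1.0])
            best_m, best = -np.inf, None
            for tau2 in tau2_grid:
                res = self._optimize(tau2, n_starts, seed, gtol, maxiter)
                m = self._laplace_marginal(res.x, tau2)
                if m > best_m:
                    best_m, best, best_tau2 = m, res, tau2
            res, tau2 = best, best_tau2
            loglik = best_m
            params = res.x
            converged = bool(res.success)

        k = self.Xmu.shape[1] + self.Xsig.shape[1] + 1 + (1 if self.random_effect else 0)
        bic = -2.0 * loglik + k * np.log(n)
        return GAMLSSResults(
            model=self,
            params=params,
            tau2=float(tau2),
            loglik=float(loglik),
            bic=float(bic),
            k_params=k,
            converged=converged,
        )


@dataclass
class GAMLSSResults:
    """Fitted normative model: coefficients, BIC, centile machinery."""

    model: GeneralizedGammaGAMLSS
    params: np.ndarray
    tau2: float
    loglik: float
    bic: float
    k_params: int
    converged: bool
    _bse: np.ndarray | None = field(default=None, repr=False)

    # -- parameter access ---------------------------------------------------

    @property
    def param_names(self):
        names = self.model.mu_names + self.model.sig_names + ["nu"]
        if self.model.random_effect:
            names += [f"u[{s}]" for s in self.model.studies]
        return names

    def _fixed_slice(self):
        return slice(0, self.model.Xmu.shape[1] + self.model.Xsig.shape[1] + 1)

    @property
    def bse(self) -> np.ndarray:
        """SEs of the fixed parameters from the observed information."""
        if self._bse is None:
            sl = self._fixed_slice()
            x = self.params.copy()
            tau2 = self.tau2 if self.tau2 > 0 else np.inf

            def g(v):
                xx = x.copy()
                xx[sl] = v
                return self.model._grad(xx, tau2)[sl]

            p = sl.stop
            H = np.empty((p, p))
            h = 1e-5 * np.maximum(1.0, np.abs(x[sl]))
            for j in range(p):
                e = np.zeros(p)
                e[j] = h[j]
                H[:, j] = (g(x[sl] + e) - g(x[sl] - e)) / (2 * h[j])
            H = 0.5 * (H + H.T)
            cov = np.linalg.pinv(H)
            self._bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        return self._bse

    # -- prediction ---------------------------------------------------------

    def _param_curves(self, age, sex=0, handedness=0, study=None):
        age = np.asarray(age, dtype=float)
        t = _rescale_age(age, self.model.age_offset)
        bmu, bsig, nu, u = self.model._unpack(self.params)
        X = [np.ones(len(t)), fp_basis(t, self.model.spec.mu_powers)]
        for nm, v in [("sex", sex), ("handedness", handedness)]:
            if nm in self.model.mu_names:
                X.append(np.broadcast_to(np.asarray(v, float), t.shape))
        eta = np.column_stack(X) @ bmu
        if study is not None and study in self.model.studies and len(u):
            eta = eta + u[self.model.studies.index(study)]
        s = np.column_stack(
            [np.ones(len(t)), fp_basis(t, self.model.spec.sigma_powers)]
        ) @ bsig
        return np.exp(eta), np.exp(s), nu

    def _check_support(self, age, margin):
        age = np.asarray(age, dtype=float)
        lo, hi = self.model.age.min() - margin, self.model.age.max() + margin
        if np.any((age < lo) | (age > hi)):
            raise ValueError(
                f"age outside fitted support [{lo:.1f}, {hi:.1f}] "
                "(widen extrapolation_margin to override)"
            )

    def predict_centile(
        self, volume, age, sex=0, handedness=0, study=None, extrapolation_margin=2.0
    ):
        """Centile of ``volume`` under the fitted normative distribution.

        An unknown study gets the population-level prediction (random
        intercept 0).  Output is clamped to (1e-12, 1 - 1e-12).
        """
        self._check_support(age, extrapolation_margin)
        mu, sig, nu = self._param_curves(age, sex, handedness, study)
        c = gg_cdf(np.asarray(volume, dtype=float), mu, sig, nu)
        return np.clip(c, 1e-12, 1 - 1e-12)

    def centile_curves(
        self, ages, quantiles=(5, 25, 50, 75, 95), sex=0, handedness=0, study=None
    ) -> pd.DataFrame:
        """Inverse-CDF normative curves per quantile; non-crossing by
        monotonicity of the quantile function."""
        q = np.asarray(quantiles, dtype=float)
        if np.any((q <= 0) | (q >= 100)):
            raise ValueError("quantiles must lie in (0, 100)")
        mu, sig, nu = self._param_curves(ages, sex, handedness, study)
        out = {f"q{qq:g}": gg_ppf(qq / 100.0, mu, sig, nu) for qq in q}
        return pd.DataFrame(out, index=pd.Index(np.asarray(ages, float), name="age"))

    def plot_centiles(self, ages=None, ax=None, **kw):
        import matplotlib.pyplot as plt

        if ages is None:
            ages = np.linspace(self.model.age.min(), self.model.age.max(), 200)
        curves = self.centile_curves(ages, **kw)
        if ax is None:
            _, ax = plt.subplots()
        for col in curves:
            ax.plot(curves.index, curves[col], label=col)
        ax.set_xlabel("age (y)")
        ax.set_ylabel("volume (mm$^3$)")
        ax.legend()
        return ax

    def summary(self) -> str:
        sl = self._fixed_slice()
        bse = self.bse
        lines = [
            "Generalized-gamma GAMLSS normative fit",
            f"  spec: {self.model.spec.label()}   n = {len(self.model.y)}",
            f"  loglik = {self.loglik:.2f}   BIC = {self.bic:.2f}   "
            f"tau2 = {self.tau2:.4g}   converged = {self.converged}",
            f"  {'param':<16}{'coef':>12}{'se':>12}",
        ]
        for nm, v, se in zip(self.param_names[: sl.stop], self.params[sl], bse):
            lines.append(f"  {nm:<16}{v:>12.4f}{se:>12.4f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            dict(
                mu_powers=list(self.model.spec.mu_powers),
                sigma_powers=list(self.model.spec.sigma_powers),
                age_offset=self.model.age_offset,
                param_names=self.param_names,
                params=self.params.tolist(),
                tau2=self.tau2,
                loglik=self.loglik,
                bic=self.bic,
            ),
            indent=2,
        )


def default_candidates(max_mu_terms: int = 3, sigma_age: bool = False):
    """A compact candidate grid mirroring growth-chart practice."""
    mu_sets = [(1.0,), (0.5,), (0.0,), (0.5, 1.0), (1.0, 2.0), (0.5, 1.0, 2.0)]
    mu_sets = [m for m in mu_sets if len(m) <= max_mu_terms]
    sig_sets = [()] + ([(1.0,)] if sigma_age else [])
    return [FPSpec(m, s) for m in mu_sets for s in sig_sets]


def fit_normative(
    hc_table: pd.DataFrame,
    roi: str,
    candidate_specs=None,
    random_effect="auto",
    min_n: int = 200,
    **fit_kw,
) -> GAMLSSResults:
    """Fit all candidate specs on healthy-control scans, return the min-BIC fit.

    ``random_effect='auto'`` tries each spec with and without the study
    random intercept when >= 2 studies are present; non-converged
    candidates are dropped with a warning.
    """
    import warnings

    if len(hc_table) < min_n:
        raise ValueError(f"need >= {min_n} healthy-control scans")
    candidate_specs = candidate_specs or default_candidates()
    n_studies = hc_table["cohort"].nunique() if "cohort" in hc_table else 1
    re_opts = [False]
    if random_effect is True or (random_effect == "auto" and n_studies > 1):
        re_opts = [False, True] if random_effect == "auto" else [True]
    if random_effect is True and n_studies < 2:
        re_opts = [False]

    best = None
    for spec in candidate_specs:
        for re in re_opts:
            model = GeneralizedGammaGAMLSS.from_dataframe(
                hc_table, roi, spec=spec, random_effect=re
            )
            try:
                res = model.fit(**fit_kw)
            except (np.linalg.LinAlgError, ValueError) as err:
                warnings.warn(f"candidate {spec.label()} (re={re}) failed: {err}")
                continue
            if not res.converged:
                warnings.warn(f"candidate {spec.label()} (re={re}) did not converge")
                continue
            if best is None or res.bic < best.bic:
                best = res
    if best is None:
        raise RuntimeError("all candidate normative models failed to converge")
    return best
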