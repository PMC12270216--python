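"""Principal-axis factor analysis with varimax rotation and regression scores.

Used both for behavioral composite scores (retention by the Kaiser
eigenvalue-greater-than-one rule) and for cognitive-atlas decomposition
(retention by explained-variance fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FactorModel", "principal_axis_factor", "varimax", "tucker_congruence"]


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser, unnormalized)."""
    L = np.asarray(loadings, dtype=float).copy()
    n, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR**3 - LR @ np.diag(np.sum(LR**2, axis=0)) / n)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return L @ R


def _smooth_corr(R: np.ndarray) -> np.ndarray:
    """Nudge a near-PSD correlation matrix onto the PSD cone."""
    w, V = np.linalg.eigh(R)
    if w.min() > 1e-10:
        return R
    w = np.clip(w, 1e-8, None)
    Rs = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(Rs))
    return Rs / np.outer(d, d)


@dataclass
class FactorModel:
    loadings: pd.DataFrame  # items x factors, varimax-rotated
    eigenvalues: np.ndarray  # of the (reduced) correlation matrix
    explained_variance: np.ndarray  # fraction per retained factor
    rotation: str
    scores: pd.DataFrame | None = None  # participants x factors

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)

    def summary(self) -> str:
        lines = [
            f"Factor model ({self.rotation}): {self.n_factors} factors, "
            f"{self.loadings.shape[0]} items",
            "  explained variance: "
            + ", ".join(f"{v:.1%}" for v in self.explained_variance),
        ]
        return "\n".join(lines)


def principal_axis_factor(
    data: pd.DataFrame,
    n_factors: int | str = "kaiser",
    rotation: str = "varimax",
    scores: str = "regression",
    max_iter: int = 100,
    tol: float = 1e-6,
    allow_small_n: bool = False,
) -> FactorModel:
    """Iterated principal-axis factoring on the item correlation matrix.

    ``n_factors='kaiser'`` retains #{eigenvalues of R > 1} factors (zero is
    possible and returned as an empty model).  Factor scores use the
    regression (Thurstone) method on standardized items.
    ``allow_small_n`` permits fewer observations than variables (the
    singular correlation matrix is smoothed first), as needed when regions
    are the observations of a term-map decomposition.
    """
    X = data.to_numpy(dtype=float)
    n, p = X.shape
    if p < 3:
        raise ValueError("need at least 3 items")
    if n <= p and not allow_small_n:
        raise ValueError("need more observations than items")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance item")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    R = _smooth_corr(R)
    eig_R = np.sort(np.linalg.eigvalsh(R))[::-1]

    if n_factors == "kaiser":
        k = int(np.sum(eig_R > 1.0 + 1e-10))
    else:
        k = int(n_factors)
    cols = [f"factor{j+1}" for j in range(k)]
    if k == 0:
        return FactorModel(
            loadings=pd.DataFrame(index=data.columns, columns=[], dtype=float),
            eigenvalues=eig_R,
            explained_variance=np.array([]),
            rotation=rotation,
            scores=pd.DataFrame(index=data.index, columns=[], dtype=float),
        )

    # iterate communalities: start from squared multiple correlations
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, V = np.linalg.eigh(Rr)
        idx = np.argsort(w)[::-1][:k]
        L = V[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
        h2_new = np.clip((L**2).sum(axis=1), 0, 0.999)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new

    if rotation == "varimax" and k > 1:
        L = varimax(L)
    # fix column signs (largest loading positive) and order by variance
    order = np.argsort(-(L**2).sum(axis=0))
    L = L[:, order]
    L *= np.sign(L[np.abs(L).argmax(axis=0), np.arange(k)])

    explained = (L**2).sum(axis=0) / p
    load_df = pd.DataFrame(L, index=data.columns, columns=cols)

    score_df = None
    if scores == "regression":
        W = np.linalg.lstsq(R, L, rcond=None)[0]  # R^- Lambda
        score_df = pd.DataFrame(Z @ W, index=data.index, columns=cols)
    return FactorModel(
        loadings=load_df,
        eigenvalues=eig_R,
        explained_variance=explained,
        rotation=rotation if k > 1 else "none",
        scores=score_df,
    )


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> float:
    """Mean best-match Tucker congruence between two loading matrices.

    Columns of B are greedily matched to columns of A by absolute
    congruence; returns the mean of the matched |phi| values.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    ka, kb = A.shape[1], B.shape[1]
    phi = np.zeros((ka, kb))
    for i in range(ka):
        for j in range(kb):
            denom = np.linalg.norm(A[:, i]) * np.linalg.norm(B[:, j])
            phi[i, j] = np.abs(A[:, i] @ B[:, j]) / denom if denom > 0 else 0.0
    used, vals = set(), []
    for i in np.argsort(-phi.max(axis=1)):
        j = int(np.argmax([phi[i, j] if j not in used else -1 for j in range(kb)]))
        used.add(j)
        vals.append(phi[i, j])
        if len(used) == kb:
            break
    return float(np.mean(vals))
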