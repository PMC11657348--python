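"""Penalized precision-matrix estimation and BIC tuning of the shared
regularization parameter.

The tuning parameter is shared across the two conditions: a model is fitted
per condition at each candidate and the two BIC scores are summed; the
candidate minimizing the sum wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solver import GlassoNotConverged, pglasso
from .preprocess import Experiment

__all__ = [
    "PenaltySpec",
    "TuningResult",
    "GlassoFit",
    "sample_covariance",
    "glasso_fit",
    "bic_score",
    "lambda_grid_asymptotic",
    "tune_lambda",
    "GlassoNotConverged",
]

TUNING_MODES = ("exhaustive", "asymptotic_c", "user_supplied")


@dataclass
class PenaltySpec:
    """Uniform penalty ``lam`` or an edge-specific matrix; the diagonal is
    always unpenalized.  ``epsilon`` is the stabilizer of the
    selection-probability weighting."""

    lam: float = 0.0
    penalty_matrix: np.ndarray | None = None
    epsilon: float = 1e-4

    def materialize(self, m: int) -> np.ndarray:
        if self.penalty_matrix is not None:
            P = np.asarray(self.penalty_matrix, dtype=float)
            if P.shape != (m, m):
                raise ValueError("penalty matrix shape mismatch")
            if not np.allclose(P, P.T):
                raise ValueError("penalty matrix must be symmetric")
            if not np.all(np.isfinite(P)) or np.any(P < 0):
                raise ValueError("penalty entries must be finite and nonnegative")
            return P
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        return np.full((m, m), float(self.lam))


@dataclass
class GlassoFit:
    theta: np.ndarray
    converged: bool
    n_iter: int

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices_from(self.theta, k=1)
        return int(np.count_nonzero(self.theta[iu]))


@dataclass
class TuningResult:
    lambdas: np.ndarray
    bic: dict[str, np.ndarray]  # per condition, aligned with lambdas
    bic_total: np.ndarray
    optimal_lambda: float
    method: str
    c_values: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {"lambda": self.lambdas}
        if self.c_values is not None:
            data["c"] = self.c_values
        for lvl, scores in self.bic.items():
            data[f"bic_{lvl}"] = scores
        data["bic_total"] = self.bic_total
        return pd.DataFrame(data)


def sample_covariance(block: np.ndarray) -> np.ndarray:
    """S = (1/n_k) X X' for an m x n_k standardized block (features as rows).

    With population-sd standardization the diagonal of S is exactly 1.
    """
    block = np.asarray(block, dtype=float)
    m, n_k = block.shape
    if n_k < 2:
        raise ValueError("need at least 2 samples")
    return block @ block.T / n_k


def glasso_fit(
    S: np.ndarray,
    penalty: PenaltySpec | float,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GlassoFit:
    """Graphical lasso: maximize logdet(T) - tr(ST) - sum_{i!=j} rho_ij|t_ij|.

    Raises :class:`GlassoNotConverged` (carrying the last change) when block
    coordinate descent fails to reach tolerance.
    """
    if not isinstance(penalty, PenaltySpec):
        penalty = PenaltySpec(lam=float(penalty))
    S = np.asarray(S, dtype=float)
    rho = penalty.materialize(S.shape[0])
    theta, converged, n_iter, _ = pglasso(S, rho, tol=tol, max_iter=max_iter)
    return GlassoFit(theta=theta, converged=converged, n_iter=n_iter)


def bic_score(theta: np.ndarray, S: np.ndarray, n_k: int) -> float:
    """BIC = n_k (tr(S T) - logdet T) + log(n_k) * df with df the number of
    nonzero upper-off-diagonal entries.  Only comparable across fits sharing
    (S, n_k)."""
    theta = np.asarray(theta, dtype=float)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    try:
        np.linalg.cholesky(theta)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix must be positive definite") from exc
    iu = np.triu_indices_from(theta, k=1)
    df = int(np.count_nonzero(theta[iu]))
    return float(n_k * (np.trace(S @ theta) - logdet) + math.log(n_k) * df)


def lambda_grid_asymptotic(m: int, n: int) -> list[tuple[float, float]]:
    """(c, lambda) pairs with lambda = c sqrt(ln m / n) for
    c in {0.01, 0.03, ..., 0.29}."""
    if m < 2 or n < 2:
        raise ValueError("need m >= 2 and n >= 2")
    base = math.sqrt(math.log(m) / n)
    cs = [round(0.01 + 0.02 * k, 10) for k in range(15)]
    return [(c, c * base) for c in cs]


def _bic_curve(
    Ss: dict[str, np.ndarray],
    n_ks: dict[str, int],
    lambdas: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    bic = {lvl: np.empty(len(lambdas)) for lvl in Ss}
    for i, lam in enumerate(lambdas):
        for lvl, S in Ss.items():
            fit = glasso_fit(S, PenaltySpec(lam=float(lam)), tol=tol, max_iter=max_iter)
            bic[lvl][i] = bic_score(fit.theta, S, n_ks[lvl])
    total = np.sum([bic[lvl] for lvl in Ss], axis=0)
    return bic, total


def tune_lambda(
    exp: Experiment,
    mode: str = "exhaustive",
    user_grid: np.ndarray | list[float] | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> TuningResult:
    """Select the shared lambda minimizing the summed per-condition BIC.

    exhaustive: 20-point logarithmic grid on [0.01 lam_max, lam_max]
    (lam_max = max off-diagonal |S| over both conditions), then a 20-point
    uniform refinement around the coarse argmin.  asymptotic_c: the
    15-candidate grid of :func:`lambda_grid_asymptotic` with n = total
    samples.  user_supplied: the given grid verbatim.
    """
    if mode not in TUNING_MODES:
        raise ValueError(f"mode must be one of {TUNING_MODES}")
    Ss = {lvl: sample_covariance(exp.X_std[lvl]) for lvl in exp.condition_levels}
    n_ks = exp.sample_counts()

    c_values = None
    if mode == "user_supplied":
        if user_grid is None or len(user_grid) == 0:
            raise ValueError("user_supplied mode requires a nonempty grid")
        lambdas = np.asarray(sorted(float(x) for x in user_grid))
        bic, total = _bic_curve(Ss, n_ks, lambdas, tol, max_iter)
    elif mode == "asymptotic_c":
        pairs = lambda_grid_asymptotic(exp.m, exp.n)
        c_values = np.array([c for c, _ in pairs])
        lambdas = np.array([lam for _, lam in pairs])
        bic, total = _bic_curve(Ss, n_ks, lambdas, tol, max_iter)
    else:
        off = max(
            np.abs(S - np.diag(np.diag(S))).max() for S in Ss.values()
        )
        lam_max = max(off, 1e-8)
        coarse = np.geomspace(0.01 * lam_max, lam_max, 20)
        bic_c, total_c = _bic_curve(Ss, n_ks, coarse, tol, max_iter)
        k = int(np.argmin(total_c))
        lo = coarse[max(k - 1, 0)]
        hi = coarse[min(k + 1, len(coarse) - 1)]
        fine = np.linspace(lo, hi, 20)
        bic_f, total_f = _bic_curve(Ss, n_ks, fine, tol, max_iter)
        lambdas = np.concatenate([coarse, fine])
        order = np.argsort(lambdas)
        lambdas = lambdas[order]
        bic = {
            lvl: np.concatenate([bic_c[lvl], bic_f[lvl]])[order] for lvl in Ss
        }
        total = np.concatenate([total_c, total_f])[order]

    best = int(np.argmin(total))
    return TuningResult(
        lambdas=lambdas,
        bic=bic,
        bic_total=total,
        optimal_lambda=float(lambdas[best]),
        method=mode,
        c_values=c_values,
    )
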