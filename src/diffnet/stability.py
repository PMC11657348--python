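"""Resampling-based edge selection probabilities and the weighted penalty
matrix used for the final network fit.

Each replicate draws half of each condition's samples without replacement
(optionally balanced to the smaller group), restandardizes the drawn block,
fits a uniform-penalty graphical lasso per condition and records the edge
support.  Selection probabilities are the per-condition mean support.

Determinism contract: replicate b uses an RNG substream derived from
(seed, b), so results are bit-identical for a fixed seed regardless of the
worker count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from ._solver import GlassoNotConverged
from .estimation import PenaltySpec, glasso_fit, sample_covariance
from .preprocess import Experiment, _standardize_rows


@dataclass
class SelectionResult:
    probabilities: dict[str, np.ndarray]  # per-condition m x m symmetric P
    B: int
    subsample: bool
    replicate_sizes: dict[str, int]
    seed: int
    lam: float
    failed: dict[str, int] = field(default_factory=dict)
    feature_ids: list[str] | None = None


def _replicate_supports(
    blocks: dict[str, np.ndarray],
    sizes: dict[str, int],
    lam: float,
    seed: int,
    b: int,
    tol: float,
    max_iter: int,
) -> dict[str, np.ndarray | None]:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
    out: dict[str, np.ndarray | None] = {}
    for lvl, block in blocks.items():  # insertion order = declared level order
        n_k = block.shape[1]
        idx = rng.choice(n_k, size=sizes[lvl], replace=False)
        sub = block[:, idx]
        try:
            S = sample_covariance(_standardize_rows(sub))
            fit = glasso_fit(S, PenaltySpec(lam=lam), tol=tol, max_iter=max_iter)
            out[lvl] = fit.theta != 0
        except (GlassoNotConverged, ValueError, np.linalg.LinAlgError):
            out[lvl] = None
    return out


def stability_selection(
    exp: Experiment,
    lam: float,
    B: int = 1000,
    subsample: bool = False,
    seed: int = 0,
    workers: int = 1,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> SelectionResult:
    """Selection probability P_ij = (# replicates selecting edge ij) / B per
    condition, with failed replicates excluded from the denominator."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if lam <= 0:
        raise ValueError("lambda must be > 0")

    counts = exp.sample_counts()
    if subsample:
        half = min(counts.values()) // 2
        sizes = {lvl: half for lvl in exp.condition_levels}
    else:
        sizes = {lvl: counts[lvl] // 2 for lvl in exp.condition_levels}
    for lvl, s in sizes.items():
        if s < 2:
            raise ValueError(
                f"condition {lvl!r}: replicate sample size {s} < 2 "
                f"(n_k={counts[lvl]}, subsample={subsample})"
            )

    blocks = {lvl: exp.log_block(lvl) for lvl in exp.condition_levels}
    results = Parallel(n_jobs=workers)(
        delayed(_replicate_supports)(blocks, sizes, float(lam), int(seed), b, tol, max_iter)
        for b in range(B)
    )

    m = exp.m
    probs, failed = {}, {}
    off = ~np.eye(m, dtype=bool)
    for lvl in exp.condition_levels:
        acc = np.zeros((m, m))
        n_fail = 0
        for rep in results:
            sup = rep[lvl]
            if sup is None:
                n_fail += 1
            else:
                acc += sup
        denom = B - n_fail
        if denom == 0:
            raise RuntimeError(f"all {B} replicates failed for condition {lvl!r}")
        P = acc / denom
        P[~off] = 0.0
        probs[lvl] = 0.5 * (P + P.T)
        failed[lvl] = n_fail
        if n_fail:
            warnings.warn(
                f"{n_fail}/{B} replicates failed for condition {lvl!r} and were "
                "excluded from the selection-probability denominator"
            )
    return SelectionResult(
        probabilities=probs,
        B=B,
        subsample=subsample,
        replicate_sizes=sizes,
        seed=int(seed),
        lam=float(lam),
        failed=failed,
        feature_ids=list(exp.feature_ids),
    )


def edge_penalty_matrix(lam: float, P: np.ndarray, epsilon: float = 1e-4) -> np.ndarray:
    """Selection-probability-weighted penalties rho_ij = lam / (epsilon + p_ij).

    Edges never selected get rho = lam/epsilon (effectively forbidden);
    always-selected edges are penalized at ~lam.  The diagonal is zeroed
    (unpenalized).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("selection probabilities must be in [0, 1]")
    rho = lam / (epsilon + P)
    np.fill_diagonal(rho, 0.0)
    return rho
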