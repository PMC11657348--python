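"""Network-based differential enrichment test for metabolic modules.

Each sample vector is modeled as N(Lambda_k beta_k, sigma_g^2 Lambda_k
Lambda_k' + sigma_0^2 I) where Lambda_k Lambda_k' equals the inverse of the
condition's precision matrix.  Variance components are fitted by REML
jointly over both conditions; each module's mean contrast between conditions
is studentized with the model-based variance and referred to a t
distribution with Satterthwaite degrees of freedom.  BH-FDR is applied
across tested modules.

The data view used here is the log matrix standardized per feature across
*all* samples pooled: per-condition standardization (used for network
estimation) removes the very group mean differences the test targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .networks import ConsensusResult, GroupNetworks
from .preprocess import Experiment


class EnrichmentError(RuntimeError):
    pass


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_i = min_{j: p_(j) >= p_(i)} p_(j) M / j,
    capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    M = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * M / np.arange(1, M + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(M)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def refit_support(S: np.ndarray, support: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Support-constrained Gaussian MLE of the precision matrix: zero penalty
    on the given edges, a prohibitive penalty elsewhere.

    L1-shrunken precision estimates systematically understate covariance;
    refitting the selected support without shrinkage restores the scale the
    mixed model needs.
    """
    from ._solver import pglasso

    S = np.asarray(S, dtype=float)
    m = S.shape[0]
    off = np.abs(S - np.diag(np.diag(S)))
    big = 10.0 * max(off.max(), 1.0)
    rho = np.where(support, 0.0, big)
    np.fill_diagonal(rho, 0.0)
    theta, *_ = pglasso(S, rho, tol=tol, max_iter=1000)
    return theta


def influence_matrix(theta: np.ndarray) -> np.ndarray:
    """Triangular factor Lambda with Lambda Lambda' = inv(theta), via the
    Cholesky factorization of the covariance."""
    theta = np.asarray(theta, dtype=float)
    try:
        c, low = linalg.cho_factor(theta, lower=True)
    except linalg.LinAlgError as exc:
        raise EnrichmentError("precision matrix is not positive definite") from exc
    sigma = linalg.cho_solve((c, low), np.eye(theta.shape[0]))
    sigma = 0.5 * (sigma + sigma.T)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - sigma PD by construction
        raise EnrichmentError("implied covariance is not positive definite") from exc


@dataclass
class MixedModelFit:
    beta: dict[str, np.ndarray]
    sigma_g2: float
    sigma_02: float
    converged: bool
    # cached spectral pieces for variance evaluation
    eigvals: dict[str, np.ndarray] = field(default_factory=dict)
    eigvecs: dict[str, np.ndarray] = field(default_factory=dict)
    n_k: dict[str, int] = field(default_factory=dict)
    means: dict[str, np.ndarray] = field(default_factory=dict)

    def covariance(self, level: str) -> np.ndarray:
        U, d = self.eigvecs[level], self.eigvals[level]
        return (U * (self.sigma_g2 * d + self.sigma_02)) @ U.T


def fit_mixed_model(
    exp: Experiment,
    lambdas: dict[str, np.ndarray],
    tol: float = 1e-8,
) -> MixedModelFit:
    """REML fit of (sigma_g^2, sigma_0^2), profiled jointly over both
    conditions, with beta_k = Lambda_k^{-1} (condition mean)."""
    Y = exp.pooled_standardized()
    eigvals, eigvecs, scatter_diag, n_k, means, beta = {}, {}, {}, {}, {}, {}
    for lvl in exp.condition_levels:
        lam = np.asarray(lambdas[lvl], dtype=float)
        sigma = lam @ lam.T
        d, U = np.linalg.eigh(sigma)
        d = np.clip(d, 0.0, None)
        block = Y[:, exp.condition_mask(lvl)]
        xbar = block.mean(axis=1)
        centered = block - xbar[:, None]
        M = U.T @ centered
        eigvals[lvl], eigvecs[lvl] = d, U
        scatter_diag[lvl] = (M**2).sum(axis=1)
        n_k[lvl] = block.shape[1]
        means[lvl] = xbar
        beta[lvl] = linalg.solve_triangular(lam, xbar, lower=True)

    def neg2_reml(params: np.ndarray) -> tuple[float, np.ndarray]:
        sg2, s02 = params
        val = 0.0
        grad = np.zeros(2)
        for lvl in exp.condition_levels:
            v = sg2 * eigvals[lvl] + s02
            if np.any(v <= 1e-300):
                return np.inf, grad
            d, w = eigvals[lvl], scatter_diag[lvl]
            val += (n_k[lvl] - 1) * np.log(v).sum() + (w / v).sum()
            grad[0] += ((n_k[lvl] - 1) * d / v - w * d / v**2).sum()
            grad[1] += ((n_k[lvl] - 1) / v - w / v**2).sum()
        return val, grad

    total_var = sum(
        scatter_diag[lvl].sum() / ((n_k[lvl] - 1) * exp.m)
        for lvl in exp.condition_levels
    ) / len(exp.condition_levels)
    mean_d = np.mean([eigvals[lvl].mean() for lvl in exp.condition_levels])
    x0 = np.array([0.5 * total_var / max(mean_d, 1e-12), 0.5 * total_var])
    res = optimize.minimize(
        neg2_reml,
        x0,
        jac=True,
        method="L-BFGS-B",
        # strictly positive floor: at exactly (0, 0) the objective is +inf,
        # which aborts the projected line search
        bounds=[(1e-12, None), (1e-12, None)],
        options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
    )
    if not res.success and res.status != 2:  # status 2: precision loss at optimum
        raise EnrichmentError(f"REML did not converge: {res.message}")
    sg2, s02 = (float(max(v, 0.0)) for v in res.x)
    if sg2 < 1e-12 and s02 < 1e-12:
        raise EnrichmentError("degenerate variance estimate: both components are zero")
    return MixedModelFit(
        beta=beta,
        sigma_g2=sg2,
        sigma_02=s02,
        converged=bool(res.success or res.status == 2),
        eigvals=eigvals,
        eigvecs=eigvecs,
        n_k=n_k,
        means=means,
    )


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    fit: MixedModelFit | None
    min_size: int

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        tested = self.table[self.table["status"] == "tested"]
        return tested[tested["q"] < fdr]


def netgsa_test(
    exp: Experiment,
    net: GroupNetworks,
    modules: ConsensusResult | dict[int, list[str]],
    min_size: int = 5,
    fit: MixedModelFit | None = None,
    refit: bool = True,
) -> EnrichmentResult:
    """Module-level differential enrichment.

    For each module S with at least ``min_size`` members, the statistic is
    the case-minus-control contrast of the module mean divided by its
    model-based standard error; two-sided p from a t distribution with
    Welch-Satterthwaite degrees of freedom.  Modules below ``min_size`` are
    reported with status "too_small".  A precomputed ``fit`` may be supplied
    (e.g. to hold variance components fixed).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    module_map = modules.modules() if isinstance(modules, ConsensusResult) else modules

    if fit is None:
        thetas = dict(net.theta)
        if refit:
            Y = exp.pooled_standardized()
            for lvl in exp.condition_levels:
                block = Y[:, exp.condition_mask(lvl)]
                centered = block - block.mean(axis=1, keepdims=True)
                S = centered @ centered.T / centered.shape[1]
                support = net.theta[lvl] != 0
                try:
                    thetas[lvl] = refit_support(S, support)
                except Exception:  # fall back to the penalized estimate
                    thetas[lvl] = net.theta[lvl]
        lambdas = {lvl: influence_matrix(thetas[lvl]) for lvl in exp.condition_levels}
        fit = fit_mixed_model(exp, lambdas)

    idx = {f: i for i, f in enumerate(exp.feature_ids)}
    ctrl, case = exp.control, exp.case
    cov = {lvl: fit.covariance(lvl) for lvl in exp.condition_levels}

    edge_idx = list(
        zip(net.edge_table["source"].map(idx), net.edge_table["target"].map(idx))
    )

    rows = []
    for mod_id in sorted(module_map):
        members = module_map[mod_id]
        mem_idx = [idx[f] for f in members]
        n_edges = sum(1 for i, j in edge_idx if i in set(mem_idx) and j in set(mem_idx))
        if len(members) < min_size:
            rows.append(
                dict(
                    module=mod_id, n_nodes=len(members), n_edges=n_edges,
                    statistic=np.nan, df=np.nan, p=np.nan, q=np.nan,
                    status="too_small", members=";".join(sorted(members)),
                )
            )
            continue
        b = np.zeros(exp.m)
        b[mem_idx] = 1.0 / len(members)
        contrast = float(b @ (fit.means[case] - fit.means[ctrl]))
        v = {lvl: float(b @ cov[lvl] @ b) / fit.n_k[lvl] for lvl in (ctrl, case)}
        se = np.sqrt(v[ctrl] + v[case])
        if se == 0:
            t_stat, df, p = 0.0, float(fit.n_k[ctrl] + fit.n_k[case] - 2), 1.0
        else:
            t_stat = contrast / se
            num = (v[ctrl] + v[case]) ** 2
            den = v[ctrl] ** 2 / (fit.n_k[ctrl] - 1) + v[case] ** 2 / (fit.n_k[case] - 1)
            df = num / den if den > 0 else float(fit.n_k[ctrl] + fit.n_k[case] - 2)
            p = float(2 * stats.t.sf(abs(t_stat), df))
        rows.append(
            dict(
                module=mod_id, n_nodes=len(members), n_edges=n_edges,
                statistic=t_stat, df=df, p=p, q=np.nan,
                status="tested", members=";".join(sorted(members)),
            )
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "module", "n_nodes", "n_edges", "statistic", "df", "p", "q",
            "status", "members",
        ],
    )
    tested = table["status"] == "tested"
    if tested.any():
        table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    else:
        import warnings

        warnings.warn(f"no module reaches min_size={min_size}; nothing tested")
    return EnrichmentResult(table=table, fit=fit, min_size=min_size)
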