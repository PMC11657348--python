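"""Final per-condition network construction, partial correlations, edge
classification, presentational filtering, and consensus clustering of the
union network into modules."""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

from .estimation import PenaltySpec, _bic_curve, glasso_fit, sample_covariance
from .preprocess import Experiment
from .stability import SelectionResult, edge_penalty_matrix

NETWORK_MODES = ("stability_weighted", "bic_per_group", "approx")

EDGE_COLUMNS = ["source", "target", "pcor_control", "pcor_case", "edge_class"]


@dataclass
class GroupNetworks:
    feature_ids: list[str]
    condition_levels: tuple[str, str]
    theta: dict[str, np.ndarray]
    pcor: dict[str, np.ndarray]
    edge_table: pd.DataFrame
    mode: str
    params: dict = field(default_factory=dict)
    filtered: bool = False

    @property
    def control(self) -> str:
        return self.condition_levels[0]

    @property
    def case(self) -> str:
        return self.condition_levels[1]

    def edge_counts(self) -> dict[str, int]:
        cls = self.edge_table["edge_class"]
        return {
            "total": len(self.edge_table),
            "shared": int((cls == "shared").sum()),
            "control_only": int((cls == "control_only").sum()),
            "case_only": int((cls == "case_only").sum()),
        }


@dataclass
class ConsensusResult:
    membership: dict[str, int | None]  # None = unassigned (isolated node)
    per_method: dict[str, dict[str, int]]
    comembership: np.ndarray  # over clustered_features
    clustered_features: list[str]
    tau: float
    iterations: int

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for feat, mod in self.membership.items():
            if mod is not None:
                out.setdefault(mod, []).append(feat)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.membership),
                "module": [
                    "" if v is None else v for v in self.membership.values()
                ],
            }
        )


def partial_correlations(theta: np.ndarray) -> np.ndarray:
    """r_ij = -theta_ij / sqrt(theta_ii theta_jj), unit diagonal."""
    d = np.sqrt(np.diag(theta))
    R = -theta / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def lambda_approx(m: int, n_k: int) -> float:
    """Closed-form regularization lambda_k = sqrt(ln m / n_k), per condition."""
    if m < 2 or n_k < 2:
        raise ValueError("need m >= 2 and n_k >= 2")
    return math.sqrt(math.log(m) / n_k)


def _edge_table(
    feature_ids: list[str],
    pcor: dict[str, np.ndarray],
    levels: tuple[str, str],
) -> pd.DataFrame:
    ctrl, case = levels
    Rc, Ra = pcor[ctrl], pcor[case]
    rows = []
    m = len(feature_ids)
    for i in range(m):
        for j in range(i + 1, m):
            pc, pa = Rc[i, j], Ra[i, j]
            if pc == 0 and pa == 0:
                continue
            if pc != 0 and pa != 0:
                cls = "shared"
            elif pc != 0:
                cls = "control_only"
            else:
                cls = "case_only"
            a, b = sorted((feature_ids[i], feature_ids[j]))
            rows.append((a, b, pc, pa, cls))
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return df.sort_values(["source", "target"], ignore_index=True)


def from_precisions(
    thetas: dict[str, np.ndarray],
    feature_ids: list[str],
    condition_levels: tuple[str, str] | None = None,
    mode: str = "external",
    params: dict | None = None,
) -> GroupNetworks:
    """Assemble a :class:`GroupNetworks` from given per-condition precision
    matrices (e.g. simulation truth or externally estimated models)."""
    if condition_levels is None:
        condition_levels = tuple(thetas)
    pcor = {lvl: partial_correlations(np.asarray(thetas[lvl], float)) for lvl in thetas}
    # zero out pcor where theta is exactly zero (guards -0.0 artifacts)
    for lvl in thetas:
        off = ~np.eye(len(feature_ids), dtype=bool)
        pcor[lvl][off & (np.asarray(thetas[lvl]) == 0)] = 0.0
    return GroupNetworks(
        feature_ids=list(feature_ids),
        condition_levels=tuple(condition_levels),
        theta={lvl: np.asarray(thetas[lvl], float) for lvl in thetas},
        pcor=pcor,
        edge_table=_edge_table(list(feature_ids), pcor, tuple(condition_levels)),
        mode=mode,
        params=params or {},
    )


def get_networks(
    exp: Experiment,
    mode: str = "stability_weighted",
    selection: SelectionResult | None = None,
    lam: float | None = None,
    epsilon: float = 1e-4,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GroupNetworks:
    """Estimate the final per-condition networks.

    stability_weighted: glasso with selection-probability-weighted penalties
    (requires ``selection`` and ``lam``).  bic_per_group: lambda tuned
    independently per condition by BIC (intended for > 500 samples/group).
    approx: closed-form lambda_k per condition (intended for 50-500
    samples/group).
    """
    if mode not in NETWORK_MODES:
        raise ValueError(f"mode must be one of {NETWORK_MODES}")
    counts = exp.sample_counts()
    Ss = {lvl: sample_covariance(exp.X_std[lvl]) for lvl in exp.condition_levels}
    params: dict = {"epsilon": epsilon}

    if mode == "stability_weighted":
        if selection is None or lam is None:
            raise ValueError("stability_weighted mode requires a SelectionResult and lambda")
        thetas = {}
        for lvl in exp.condition_levels:
            rho = edge_penalty_matrix(lam, selection.probabilities[lvl], epsilon)
            fit = glasso_fit(
                Ss[lvl], PenaltySpec(penalty_matrix=rho), tol=tol, max_iter=max_iter
            )
            thetas[lvl] = fit.theta
        params["lambda"] = float(lam)
    elif mode == "bic_per_group":
        low = [lvl for lvl, c in counts.items() if c < 500]
        if low:
            warnings.warn(
                f"bic_per_group is intended for >500 samples per group; {low} have fewer"
            )
        thetas, lam_k = {}, {}
        for lvl in exp.condition_levels:
            S = Ss[lvl]
            off = np.abs(S - np.diag(np.diag(S))).max()
            lam_max = max(off, 1e-8)
            coarse = np.geomspace(0.01 * lam_max, lam_max, 20)
            _, total = _bic_curve({lvl: S}, {lvl: counts[lvl]}, coarse, tol, max_iter)
            k = int(np.argmin(total))
            fine = np.linspace(coarse[max(k - 1, 0)], coarse[min(k + 1, 19)], 20)
            _, total_f = _bic_curve({lvl: S}, {lvl: counts[lvl]}, fine, tol, max_iter)
            lam_k[lvl] = float(fine[int(np.argmin(total_f))])
            thetas[lvl] = glasso_fit(S, lam_k[lvl], tol=tol, max_iter=max_iter).theta
        params["lambda_per_group"] = lam_k
    else:  # approx
        out_of_range = [lvl for lvl, c in counts.items() if not (50 <= c <= 500)]
        if out_of_range:
            warnings.warn(
                f"approx mode is intended for 50-500 samples per group; {out_of_range} "
                "fall outside that range"
            )
        lam_k = {lvl: lambda_approx(exp.m, counts[lvl]) for lvl in exp.condition_levels}
        thetas = {
            lvl: glasso_fit(Ss[lvl], lam_k[lvl], tol=tol, max_iter=max_iter).theta
            for lvl in exp.condition_levels
        }
        params["lambda_per_group"] = lam_k

    net = from_precisions(thetas, exp.feature_ids, exp.condition_levels, mode, params)
    return net


def filter_networks(
    net: GroupNetworks,
    pcor_threshold: float | None = None,
    top_percent: float | None = None,
) -> GroupNetworks:
    """Drop weak edges by absolute partial-correlation threshold or by
    keeping the strongest ``top_percent`` of current edges.

    Edge strength is max over conditions of |pcor|; ties at the threshold
    are retained.  Filtering is presentational: precision matrices are left
    untouched, only the edge table and partial-correlation matrices change.
    """
    if (pcor_threshold is None) == (top_percent is None):
        raise ValueError("supply exactly one of pcor_threshold / top_percent")
    if pcor_threshold is not None and not (0 < pcor_threshold < 1):
        raise ValueError("pcor_threshold must be in (0, 1)")
    if top_percent is not None and not (0 < top_percent <= 100):
        raise ValueError("top_percent must be in (0, 100]")

    table = net.edge_table
    strength = np.maximum(
        table["pcor_control"].abs().to_numpy(), table["pcor_case"].abs().to_numpy()
    )
    if pcor_threshold is not None:
        thr = pcor_threshold
    elif len(table) == 0:
        thr = 0.0
    else:
        thr = float(np.percentile(strength, 100 - top_percent))
    keep = strength >= thr

    pcor = {lvl: net.pcor[lvl].copy() for lvl in net.pcor}
    idx = {f: i for i, f in enumerate(net.feature_ids)}
    for _, row in table[~keep].iterrows():
        i, j = idx[row["source"]], idx[row["target"]]
        for lvl in pcor:
            pcor[lvl][i, j] = 0.0
            pcor[lvl][j, i] = 0.0
    return GroupNetworks(
        feature_ids=list(net.feature_ids),
        condition_levels=net.condition_levels,
        theta=net.theta,
        pcor=pcor,
        edge_table=table[keep].reset_index(drop=True),
        mode=net.mode,
        params={
            **net.params,
            "filter": {"pcor_threshold": pcor_threshold, "top_percent": top_percent},
        },
        filtered=True,
    )


def _default_methods() -> dict[str, callable]:
    return {
        "edge_betweenness": lambda g: g.community_edge_betweenness().as_clustering().membership,
        "fast_greedy": lambda g: g.community_fastgreedy().as_clustering().membership,
        "infomap": lambda g: g.community_infomap().membership,
        "label_propagation": lambda g: g.community_label_propagation().membership,
        "louvain": lambda g: g.community_multilevel().membership,
        "walktrap": lambda g: g.community_walktrap().as_clustering().membership,
        "leading_eigenvector": lambda g: g.community_leading_eigenvector().membership,
    }


def _partition_sets(labels: np.ndarray) -> frozenset:
    groups: dict[int, set[int]] = {}
    for node, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(node)
    return frozenset(frozenset(s) for s in groups.values())


def consensus_cluster(
    net: GroupNetworks,
    tau: float = 0.5,
    seed: int = 0,
    max_iterations: int = 20,
    methods: dict | None = None,
) -> ConsensusResult:
    """Consensus community detection on the unweighted union graph.

    Seven community-detection algorithms vote; node pairs co-clustered by at
    least a fraction ``tau`` of them *and* adjacent in the union graph form
    the consensus graph, whose connected components are re-clustered until
    membership stabilizes (at most ``max_iterations`` rounds).  Isolated
    nodes of the union graph are left unassigned.
    """
    if not (0.5 <= tau <= 1):
        raise ValueError("tau must be in [0.5, 1]")
    methods = methods or _default_methods()

    table = net.edge_table
    if len(table) == 0:
        raise ValueError("no edges to cluster: the union graph is empty")

    active = sorted({*table["source"], *table["target"]}, key=net.feature_ids.index)
    pos = {f: i for i, f in enumerate(active)}
    union_edges = [(pos[s], pos[t]) for s, t in zip(table["source"], table["target"])]
    n = len(active)

    def run_methods(edges: list[tuple[int, int]]) -> tuple[dict[str, np.ndarray], np.ndarray]:
        g = ig.Graph(n=n, edges=edges, directed=False)
        memberships: dict[str, np.ndarray] = {}
        C = np.zeros((n, n))
        for k, (name, fn) in enumerate(sorted(methods.items())):
            random.seed(1000003 * seed + k)  # igraph draws from Python's random module
            try:
                lab = np.asarray(fn(g), dtype=int)
            except ig.InternalError:  # pragma: no cover - method-specific failure
                warnings.warn(f"clustering method {name!r} failed and was skipped")
                continue
            memberships[name] = lab
            C += lab[:, None] == lab[None, :]
        if not memberships:
            raise RuntimeError("all clustering methods failed")
        C /= len(memberships)
        return memberships, C

    working = list(union_edges)
    prev_partition = None
    memberships, C = {}, np.eye(n)
    labels = np.arange(n)
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        if working:
            memberships, C = run_methods(working)
        else:
            memberships, C = {}, np.eye(n)
        keep = [
            (i, j) for i, j in union_edges if C[i, j] >= tau - 1e-12
        ]
        g_cons = ig.Graph(n=n, edges=keep, directed=False)
        labels = np.asarray(g_cons.connected_components().membership, dtype=int)
        partition = _partition_sets(labels)
        if partition == prev_partition:
            break
        prev_partition = partition
        working = keep

    # module ids ordered by size (desc), then by smallest member index
    groups: dict[int, list[int]] = {}
    for node, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(node)
    ordered = sorted(groups.values(), key=lambda ns: (-len(ns), min(ns)))
    module_of: dict[int, int] = {}
    for mod_id, nodes in enumerate(ordered, start=1):
        for node in nodes:
            module_of[node] = mod_id

    membership: dict[str, int | None] = {
        f: (module_of[pos[f]] if f in pos else None) for f in net.feature_ids
    }
    per_method = {
        name: {active[i]: int(lab[i]) for i in range(n)}
        for name, lab in memberships.items()
    }
    return ConsensusResult(
        membership=membership,
        per_method=per_method,
        comembership=C,
        clustered_features=active,
        tau=tau,
        iterations=iterations,
    )
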