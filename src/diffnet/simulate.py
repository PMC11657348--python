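"""Fixture generator: two-condition multivariate-normal data with known
sparse, partially shared precision matrices, plus recovery metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import GroupNetworks
from .preprocess import Experiment, create_experiment

GRAPH_TYPES = ("chain", "hub", "random", "block")

Edge = tuple[int, int]


@dataclass
class SimTruth:
    theta: dict[str, np.ndarray]
    shared_edges: set[Edge]
    control_only_edges: set[Edge]
    case_only_edges: set[Edge]
    module_partition: list[list[int]] | None
    params: dict
    seed: int
    diagonal_inflated: dict[str, float] = field(default_factory=dict)

    def edges(self, level: str) -> set[Edge]:
        if level == "control":
            return self.shared_edges | self.control_only_edges
        return self.shared_edges | self.case_only_edges


def _base_edges(
    graph: str, m: int, rng: np.random.Generator, edge_prob: float,
    n_blocks: int, within_prob: float, between_prob: float,
) -> tuple[set[Edge], list[list[int]] | None]:
    partition = None
    edges: set[Edge] = set()
    if graph == "chain":
        edges = {(i, i + 1) for i in range(m - 1)}
    elif graph == "hub":
        edges = {(0, j) for j in range(1, m)}
    elif graph == "random":
        for i in range(m):
            for j in range(i + 1, m):
                if rng.random() < edge_prob:
                    edges.add((i, j))
    elif graph == "block":
        bounds = np.linspace(0, m, n_blocks + 1).astype(int)
        partition = [list(range(bounds[k], bounds[k + 1])) for k in range(n_blocks)]
        block_of = np.empty(m, dtype=int)
        for k, nodes in enumerate(partition):
            for v in nodes:
                block_of[v] = k
        for i in range(m):
            for j in range(i + 1, m):
                p = within_prob if block_of[i] == block_of[j] else between_prob
                if rng.random() < p:
                    edges.add((i, j))
    else:
        raise ValueError(f"graph must be one of {GRAPH_TYPES}")
    return edges, partition


def _precision_from_edges(
    m: int, edges: set[Edge], weight: float, margin: float = 0.05
) -> tuple[np.ndarray, float]:
    """Unit diagonal plus -weight at each edge; the diagonal is inflated
    just enough to keep the smallest eigenvalue above ``margin``."""
    theta = np.eye(m)
    for i, j in edges:
        theta[i, j] = theta[j, i] = -weight
    mineig = np.linalg.eigvalsh(theta).min()
    inflation = 0.0
    if mineig < margin:
        inflation = margin - mineig
        theta += inflation * np.eye(m)
    return theta, inflation


def simulate_from_precisions(
    thetas: dict[str, np.ndarray],
    n_k: dict[str, int],
    seed: int = 0,
    mean_shift: dict[str, np.ndarray] | None = None,
    log_scale: bool = False,
) -> Experiment:
    """Draw i.i.d. multivariate-normal samples per condition from the given
    precision matrices (abundances = exp of the latent normals unless
    ``log_scale``)."""
    rng = np.random.default_rng(seed)
    levels = list(thetas)
    m = thetas[levels[0]].shape[0]
    cols, data, labels = [], [], []
    for lvl in levels:
        sigma = np.linalg.inv(thetas[lvl])
        L = np.linalg.cholesky(0.5 * (sigma + sigma.T))
        Z = L @ rng.standard_normal((m, n_k[lvl]))
        if mean_shift and lvl in mean_shift:
            Z += np.asarray(mean_shift[lvl], dtype=float)[:, None]
        data.append(Z)
        cols += [f"{lvl}_{i + 1}" for i in range(n_k[lvl])]
        labels += [lvl] * n_k[lvl]
    Z = np.hstack(data)
    X = Z if log_scale else np.exp(Z)
    df = pd.DataFrame(X, index=[f"F{i + 1:03d}" for i in range(m)], columns=cols)
    cond = pd.Series(labels, index=cols)
    return create_experiment(df, cond, condition_levels=tuple(levels), already_log=log_scale)


def simulate_experiment(
    m: int = 20,
    n_control: int = 100,
    n_case: int = 100,
    graph: str = "chain",
    edge_weight: float = 0.4,
    differential_fraction: float = 0.0,
    differential_mode: str = "add",
    shift_nodes: list[int] | None = None,
    effect_size: float = 0.0,
    edge_prob: float = 0.1,
    n_blocks: int = 2,
    within_prob: float = 0.6,
    between_prob: float = 0.0,
    seed: int = 0,
    log_scale: bool = False,
    condition_levels: tuple[str, str] = ("control", "case"),
) -> tuple[Experiment, SimTruth]:
    """Generate a two-condition experiment with known network truth.

    The case condition copies the control precision and then, for the
    requested fraction of base edges, either adds new random edges
    (``differential_mode="add"``) or moves existing ones
    (``differential_mode="rewire"``, which also creates control-only edges).
    ``shift_nodes``/``effect_size`` add a case-condition mean shift on the
    latent (log) scale for enrichment power studies.
    """
    if m < 4:
        raise ValueError("m must be >= 4")
    if min(n_control, n_case) < 10:
        raise ValueError("need n_k >= 10")
    if not 0 <= differential_fraction <= 1:
        raise ValueError("differential_fraction must be in [0, 1]")
    if differential_mode not in ("add", "rewire"):
        raise ValueError("differential_mode must be 'add' or 'rewire'")

    rng = np.random.default_rng(seed)
    base_edges, partition = _base_edges(
        graph, m, rng, edge_prob, n_blocks, within_prob, between_prob
    )
    n_diff = int(round(differential_fraction * len(base_edges)))

    case_edges = set(base_edges)
    removed: set[Edge] = set()
    all_pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    if n_diff > 0:
        candidates = [e for e in all_pairs if e not in base_edges]
        pick = rng.choice(len(candidates), size=min(n_diff, len(candidates)), replace=False)
        added = {candidates[int(k)] for k in pick}
        case_edges |= added
        if differential_mode == "rewire":
            base_list = sorted(base_edges)
            drop = rng.choice(len(base_list), size=min(n_diff, len(base_list)), replace=False)
            removed = {base_list[int(k)] for k in drop}
            case_edges -= removed
    else:
        added = set()

    lc, lcase = condition_levels
    theta_ctrl, infl_c = _precision_from_edges(m, base_edges, edge_weight)
    theta_case, infl_a = _precision_from_edges(m, case_edges, edge_weight)
    truth = SimTruth(
        theta={lc: theta_ctrl, lcase: theta_case},
        shared_edges=base_edges & case_edges,
        control_only_edges=base_edges - case_edges,
        case_only_edges=case_edges - base_edges,
        module_partition=partition,
        params=dict(
            m=m, n_control=n_control, n_case=n_case, graph=graph,
            edge_weight=edge_weight, differential_fraction=differential_fraction,
            differential_mode=differential_mode, effect_size=effect_size,
            shift_nodes=list(shift_nodes or []),
        ),
        seed=seed,
        diagonal_inflated={lc: infl_c, lcase: infl_a},
    )

    mean_shift = None
    if shift_nodes and effect_size:
        mu = np.zeros(m)
        mu[list(shift_nodes)] = effect_size
        mean_shift = {lcase: mu}

    exp = simulate_from_precisions(
        truth.theta,
        {lc: n_control, lcase: n_case},
        seed=rng.integers(2**31),
        mean_shift=mean_shift,
        log_scale=log_scale,
    )
    return exp, truth


@dataclass
class RecoveryMetrics:
    per_condition: dict[str, dict[str, float]]  # tpr, fpr, f1, tp, fp, fn, tn
    classification_accuracy: float  # over true edges: predicted class vs truth

    def f1(self, level: str) -> float:
        return self.per_condition[level]["f1"]


def _true_class(truth: SimTruth, edge: Edge, levels: tuple[str, str]) -> str:
    if edge in truth.shared_edges:
        return "shared"
    if edge in truth.control_only_edges:
        return "control_only"
    if edge in truth.case_only_edges:
        return "case_only"
    return "absent"


def evaluate_recovery(truth: SimTruth, net: GroupNetworks) -> RecoveryMetrics:
    """Exact confusion counts of the estimated edge sets against truth."""
    m = len(net.feature_ids)
    feat_idx = {f: i for i, f in enumerate(net.feature_ids)}
    levels = net.condition_levels
    est_edges: dict[str, set[Edge]] = {lvl: set() for lvl in levels}
    est_class: dict[Edge, str] = {}
    for _, row in net.edge_table.iterrows():
        i, j = sorted((feat_idx[row["source"]], feat_idx[row["target"]]))
        est_class[(i, j)] = row["edge_class"]
        if row["pcor_control"] != 0:
            est_edges[levels[0]].add((i, j))
        if row["pcor_case"] != 0:
            est_edges[levels[1]].add((i, j))

    n_pairs = m * (m - 1) // 2
    per_condition = {}
    for lvl in levels:
        true = truth.edges("control" if lvl == levels[0] else "case")
        est = est_edges[lvl]
        tp = len(true & est)
        fp = len(est - true)
        fn = len(true - est)
        tn = n_pairs - tp - fp - fn
        tpr = tp / len(true) if true else 0.0
        fpr = fp / (n_pairs - len(true)) if n_pairs > len(true) else 0.0
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        per_condition[lvl] = dict(
            tpr=tpr, fpr=fpr, f1=f1, tp=tp, fp=fp, fn=fn, tn=tn
        )

    true_union = truth.shared_edges | truth.control_only_edges | truth.case_only_edges
    if true_union:
        correct = sum(
            1
            for e in true_union
            if est_class.get(e, "absent") == _true_class(truth, e, levels)
        )
        accuracy = correct / len(true_union)
    else:
        accuracy = 1.0
    return RecoveryMetrics(per_condition=per_condition, classification_accuracy=accuracy)
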