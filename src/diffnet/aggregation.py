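"""Optional collapsing of highly correlated and/or same-class features into
aggregate features before network estimation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .preprocess import Experiment, PreprocessError, create_experiment

METHODS = ("correlation", "knowledge", "hybrid")


@dataclass
class AggregationPlan:
    method: str
    correlation_threshold: float | None
    feature_groups: dict[str, str] | None
    partition: list[list[str]]  # disjoint, exhaustive; singletons allowed


@dataclass
class CollapsedExperiment(Experiment):
    feature_membership: dict[str, list[str]] = None  # aggregate id -> members

    def membership_frame(self) -> pd.DataFrame:
        rows = [
            (agg, member)
            for agg, members in self.feature_membership.items()
            for member in members
        ]
        return pd.DataFrame(rows, columns=["aggregate_feature", "member_feature"])


def _components(features: list[str], edges: set[tuple[int, int]]) -> list[list[str]]:
    m = len(features)
    if edges:
        rows, cols = zip(*edges)
        data = np.ones(len(edges))
        adj = csr_matrix((data, (rows, cols)), shape=(m, m))
    else:
        adj = csr_matrix((m, m))
    n_comp, labels = connected_components(adj, directed=False)
    blocks: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        blocks.setdefault(int(lab), []).append(features[i])
    # deterministic order: by first member index
    return [blocks[k] for k in sorted(blocks)]


def compute_aggregation_plan(
    exp: Experiment,
    method: str,
    threshold: float | None = None,
    feature_groups: dict[str, str] | None = None,
) -> AggregationPlan:
    """Partition features for aggregation.

    correlation: connected components of the graph linking features with
    |Pearson r| >= threshold on X_log across all samples.  knowledge: the
    user-supplied class labels verbatim.  hybrid: components of the
    thresholded correlation graph restricted to within-class pairs.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if method in ("correlation", "hybrid"):
        if threshold is None or not (0 < threshold <= 1):
            raise ValueError("correlation threshold must be in (0, 1]")
    if method in ("knowledge", "hybrid"):
        if feature_groups is None:
            raise PreprocessError(f"{method} aggregation requires feature_groups")
        missing = [f for f in exp.feature_ids if f not in feature_groups]
        if missing:
            raise PreprocessError(f"feature_groups is missing labels for: {missing}")

    features = list(exp.feature_ids)
    if method == "knowledge":
        groups: dict[str, list[str]] = {}
        for f in features:
            groups.setdefault(feature_groups[f], []).append(f)
        partition = [groups[g] for g in sorted(groups)]
    else:
        # pooled correlations: aggregation precedes condition-specific modeling
        corr = np.corrcoef(exp.X_log) if exp.m > 1 else np.ones((1, 1))
        edges = set()
        for i in range(exp.m):
            for j in range(i + 1, exp.m):
                if abs(corr[i, j]) >= threshold:
                    if method == "hybrid" and (
                        feature_groups[features[i]] != feature_groups[features[j]]
                    ):
                        continue
                    edges.add((i, j))
        partition = _components(features, edges)

    return AggregationPlan(
        method=method,
        correlation_threshold=threshold,
        feature_groups=dict(feature_groups) if feature_groups else None,
        partition=partition,
    )


def apply_aggregation(exp: Experiment, plan: AggregationPlan) -> CollapsedExperiment:
    """Collapse each partition block to the mean of its members' log rows;
    standardization is re-run on the collapsed matrix."""
    covered = [f for block in plan.partition for f in block]
    if sorted(covered) != sorted(exp.feature_ids):
        raise PreprocessError("aggregation plan does not cover the experiment's features")

    index = {f: i for i, f in enumerate(exp.feature_ids)}
    membership: dict[str, list[str]] = {}
    rows = []
    for block in plan.partition:
        members = sorted(block)
        name = members[0] if len(members) == 1 else "+".join(members)
        membership[name] = members
        rows.append(exp.X_log[[index[f] for f in members]].mean(axis=0))

    collapsed = pd.DataFrame(
        np.vstack(rows), index=list(membership), columns=exp.sample_ids
    )
    base = create_experiment(
        collapsed,
        pd.Series(exp.condition, index=exp.sample_ids),
        condition_levels=exp.condition_levels,
        already_log=True,
    )
    return CollapsedExperiment(
        feature_ids=base.feature_ids,
        sample_ids=base.sample_ids,
        condition=base.condition,
        condition_levels=base.condition_levels,
        X_raw=None,
        X_log=base.X_log,
        X_std=base.X_std,
        already_log=True,
        already_scaled=False,
        feature_membership=membership,
    )
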