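"""Experiment construction: filtering, imputation, covariate adjustment,
log transform, per-condition standardization, conditioning diagnostics and
node-level differential analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class PreprocessError(ValueError):
    pass


class EmptyExperimentError(PreprocessError):
    pass


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise mean 0 / unit variance (population sd, so that
    (1/n) X X' has a unit diagonal)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True, ddof=0)
    if np.any(sd == 0):
        bad = np.where(sd.ravel() == 0)[0]
        raise PreprocessError(f"constant feature rows cannot be standardized: indices {bad.tolist()}")
    return (X - mu) / sd


@dataclass
class Experiment:
    """Two-condition feature x sample container.

    ``X_raw``/``X_log`` are m x n with features as rows; ``X_std`` maps each
    condition level to its m x n_k standardized block.  The first declared
    condition level is the control; all case-vs-control signs follow from it.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    condition: np.ndarray  # per-sample labels, aligned with sample_ids
    condition_levels: tuple[str, str]
    X_raw: np.ndarray | None
    X_log: np.ndarray
    X_std: dict[str, np.ndarray]
    already_log: bool = False
    already_scaled: bool = False

    @property
    def m(self) -> int:
        return len(self.feature_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def control(self) -> str:
        return self.condition_levels[0]

    @property
    def case(self) -> str:
        return self.condition_levels[1]

    def sample_counts(self) -> dict[str, int]:
        return {lvl: int(np.sum(self.condition == lvl)) for lvl in self.condition_levels}

    def condition_mask(self, level: str) -> np.ndarray:
        return self.condition == level

    def log_block(self, level: str) -> np.ndarray:
        """m x n_k slice of X_log for one condition."""
        return self.X_log[:, self.condition_mask(level)]

    def pooled_standardized(self) -> np.ndarray:
        """X_log standardized per feature across *all* samples (ddof=0).

        Per-condition standardization removes group mean differences by
        construction, so enrichment testing operates on this pooled view
        where node-level shifts survive.
        """
        return _standardize_rows(self.X_log)


@dataclass
class NodeStats:
    feature_ids: list[str]
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mean_difference: np.ndarray  # case - control, log scale
    mean_control: np.ndarray
    mean_case: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "mean_difference": self.mean_difference,
                "mean_control": self.mean_control,
                "mean_case": self.mean_case,
            }
        )


@dataclass
class DiagnosticsReport:
    eigenvalues: dict[str, np.ndarray]  # sorted descending per condition
    min_eigenvalue: dict[str, float]
    condition_number: dict[str, float]
    aggregation_recommended: bool
    eig_threshold: float = 1e-6
    cond_threshold: float = 1e6


@dataclass
class FilterReport:
    dropped_features: list[str] = field(default_factory=list)
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)  # (feature, sample)
    n_input_features: int = 0
    n_output_features: int = 0


def filter_and_impute(
    X: pd.DataFrame, max_missing_fraction: float = 0.30
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop features missing in more than ``max_missing_fraction`` of samples
    and impute remaining missing cells with the feature's observed median."""
    if not 0 <= max_missing_fraction <= 1:
        raise PreprocessError("max_missing_fraction must be in [0, 1]")
    if X.shape[0] < 1:
        raise PreprocessError("matrix must have at least one feature")

    report = FilterReport(n_input_features=X.shape[0])
    frac_missing = X.isna().mean(axis=1)
    keep = frac_missing <= max_missing_fraction
    report.dropped_features = [str(f) for f in X.index[~keep]]
    out = X.loc[keep].copy()
    if out.shape[0] == 0:
        raise EmptyExperimentError(
            "all features exceed the missingness threshold; empty experiment"
        )
    for feat in out.index[out.isna().any(axis=1)]:
        row = out.loc[feat]
        observed = row.dropna()
        if observed.empty:
            raise PreprocessError(f"feature {feat!r} has no observed values")
        med = float(observed.median())
        for sample in row.index[row.isna()]:
            out.at[feat, sample] = med
            report.imputed_cells.append((str(feat), str(sample)))
    report.n_output_features = out.shape[0]
    return out, report


def adjust_covariates(X: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each feature row by its OLS residuals against
    (intercept + covariates), then shift so the row minimum is exactly 0."""
    if list(covariates.index) != list(X.columns):
        if set(covariates.index) == set(X.columns):
            covariates = covariates.loc[X.columns]
        else:
            raise PreprocessError("covariate rows do not align with samples")
    n, q = covariates.shape
    if n <= q + 1:
        raise PreprocessError(f"need more samples ({n}) than covariates + intercept ({q + 1})")
    D = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise PreprocessError("covariate design is rank deficient (after adding intercept)")
    # hat projection applied to all features at once
    coef, *_ = np.linalg.lstsq(D, X.to_numpy(dtype=float).T, rcond=None)
    resid = X.to_numpy(dtype=float) - (D @ coef).T
    resid -= resid.min(axis=1, keepdims=True)
    return pd.DataFrame(resid, index=X.index, columns=X.columns)


def create_experiment(
    X: pd.DataFrame,
    condition: pd.Series | dict[str, str],
    condition_levels: tuple[str, str] | None = None,
    already_log: bool = False,
    already_scaled: bool = False,
    log_base: float | None = None,
) -> Experiment:
    """Build an :class:`Experiment` from a feature x sample table.

    ``condition_levels`` fixes the (control, case) order; by default the
    order of first appearance in ``condition`` is used.  ``log_base=None``
    means natural log.
    """
    if isinstance(condition, dict):
        condition = pd.Series(condition)
    condition = condition.reindex(X.columns)
    if condition.isna().any():
        missing = condition.index[condition.isna()].tolist()
        raise PreprocessError(f"samples without a condition label: {missing}")
    labels = condition.astype(str).to_numpy()
    levels_seen = list(dict.fromkeys(labels))
    if condition_levels is None:
        condition_levels = tuple(levels_seen)
    if len(levels_seen) != 2 or set(levels_seen) != set(condition_levels):
        raise PreprocessError(
            f"exactly two condition levels required, got {levels_seen} "
            f"(declared {condition_levels})"
        )
    if X.index.duplicated().any():
        raise PreprocessError("duplicated feature IDs")
    if X.columns.duplicated().any():
        raise PreprocessError("duplicated sample IDs")

    vals = X.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise PreprocessError("matrix contains non-finite values")
    for lvl in condition_levels:
        if int(np.sum(labels == lvl)) < 2:
            raise PreprocessError(f"condition {lvl!r} has fewer than 2 samples")

    if already_scaled:
        X_log = vals
        X_std = {lvl: vals[:, labels == lvl] for lvl in condition_levels}
        return Experiment(
            feature_ids=[str(f) for f in X.index],
            sample_ids=[str(s) for s in X.columns],
            condition=labels,
            condition_levels=tuple(condition_levels),
            X_raw=None,
            X_log=X_log,
            X_std=X_std,
            already_log=True,
            already_scaled=True,
        )

    if already_log:
        X_raw = None
        X_log = vals
    else:
        if np.any(vals <= 0):
            rows, cols = np.where(vals <= 0)
            cells = [(str(X.index[r]), str(X.columns[c])) for r, c in zip(rows[:10], cols[:10])]
            raise PreprocessError(
                f"nonpositive values cannot be log-transformed (first offenders: {cells}); "
                "pass already_log=True or apply a pseudo-count explicitly"
            )
        X_raw = vals
        X_log = np.log(vals) if log_base is None else np.log(vals) / np.log(log_base)

    X_std = {
        lvl: _standardize_rows(X_log[:, labels == lvl]) for lvl in condition_levels
    }
    return Experiment(
        feature_ids=[str(f) for f in X.index],
        sample_ids=[str(s) for s in X.columns],
        condition=labels,
        condition_levels=tuple(condition_levels),
        X_raw=X_raw,
        X_log=X_log,
        X_std=X_std,
        already_log=already_log,
        already_scaled=False,
    )


def diagnose_conditioning(
    exp: Experiment, eig_threshold: float = 1e-6, cond_threshold: float = 1e6
) -> DiagnosticsReport:
    """Eigen-spectrum of the per-condition Pearson correlation matrices.

    Recommends feature aggregation when the smallest eigenvalue is (nearly)
    zero or the condition number is extreme in either condition.
    """
    eigenvalues, min_eig, cond_num = {}, {}, {}
    flag = False
    for lvl in exp.condition_levels:
        block = exp.log_block(lvl)
        sd = block.std(axis=1, ddof=0)
        if np.any(sd == 0):
            bad = [exp.feature_ids[i] for i in np.where(sd == 0)[0]]
            raise PreprocessError(
                f"constant features in condition {lvl!r}: {bad}; correlation undefined"
            )
        if exp.m == 1:
            ev = np.array([1.0])
        else:
            corr = np.corrcoef(block)
            ev = np.linalg.eigvalsh(corr)[::-1]
        eigenvalues[lvl] = ev
        min_eig[lvl] = float(ev[-1])
        cond_num[lvl] = float(ev[0] / ev[-1]) if ev[-1] > 0 else np.inf
        if min_eig[lvl] < eig_threshold or cond_num[lvl] > cond_threshold:
            flag = True
    return DiagnosticsReport(
        eigenvalues=eigenvalues,
        min_eigenvalue=min_eig,
        condition_number=cond_num,
        aggregation_recommended=flag,
        eig_threshold=eig_threshold,
        cond_threshold=cond_threshold,
    )


def differential_expression(exp: Experiment, welch: bool = False) -> NodeStats:
    """Per-feature two-sided two-sample t-test on the log data
    (pooled-variance Student's by default), with BH adjustment across
    features.  Requires unscaled input."""
    from .enrichment import bh_adjust

    if exp.already_scaled:
        raise PreprocessError(
            "differential analysis is disabled for pre-scaled input: "
            "per-condition scaling removes group mean differences"
        )
    ctrl = exp.log_block(exp.control)
    case = exp.log_block(exp.case)
    if ctrl.shape[1] < 2 or case.shape[1] < 2:
        raise PreprocessError("each condition needs at least 2 samples for the t-test")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mean_ctrl = ctrl.mean(axis=1)
    mean_case = case.mean(axis=1)
    diff = mean_case - mean_ctrl
    # zero pooled variance: equal means -> t=0, p=1; unequal -> infinite t
    degenerate = ~np.isfinite(t)
    equal = np.isclose(diff, 0.0)
    t[degenerate & equal] = 0.0
    p[degenerate & equal] = 1.0
    t[degenerate & ~equal] = np.sign(diff[degenerate & ~equal]) * np.inf
    p[degenerate & ~equal] = 0.0
    q = bh_adjust(p)
    return NodeStats(
        feature_ids=list(exp.feature_ids),
        t=t,
        p=p,
        q=q,
        mean_difference=diff,
        mean_control=mean_ctrl,
        mean_case=mean_case,
    )
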