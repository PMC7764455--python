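"""PROMETHEE outranking: rank alternatives from a multi-measure decision matrix.

Given alternatives (prediction methods, or question subsets) scored on N
performance measures q_j — each flagged maximizing or minimizing — the
method compares every ordered pair (A, B) per measure through a V-shaped
preference function

    p(x) = 0 for x <= 0,  x/Q for 0 <= x <= Q,  1 for x > Q,

where Q is the indifference threshold, aggregates the per-measure
preferences into the index π(A, B) = (1/N) Σ_j ω_j P_j(A, B), and sums the
indices into positive, negative and net preference flows

    φ+(A) = Σ_x π(A, x) / (n−1),   φ−(A) = Σ_x π(x, A) / (n−1),
    φ(A) = φ+(A) − φ−(A).

Alternatives are ranked by decreasing net flow; ties receive fractional
(average) ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MEASURE_MAXIMIZING",
    "CLASSIFICATION_MEASURES",
    "REGRESSION_MEASURES",
    "PreferenceParams",
    "DecisionMatrix",
    "FlowResult",
    "preference_value",
    "pairwise_preferences",
    "flows",
    "rank_alternatives",
    "aggregate_ranks",
]

CLASSIFICATION_MEASURES = ("precision", "recall", "f1")
REGRESSION_MEASURES = ("MAE", "MSE", "RMSE", "R2")

#: orientation of every benchmark measure (True = higher is better)
MEASURE_MAXIMIZING = {
    "precision": True,
    "recall": True,
    "f1": True,
    "MAE": False,
    "MSE": False,
    "RMSE": False,
    "R2": True,
}


@dataclass(frozen=True)
class PreferenceParams:
    """Indifference thresholds Q_j and weights ω_j, one per measure.

    ``q=None`` uses, per measure, the largest observed pairwise difference
    in the decision matrix at hand (so the linear branch spans the observed
    range; 1.0 when a measure is constant).  ``weights=None`` means equal
    unit weights, making π the plain mean of the per-measure preferences.
    """

    q: Sequence[float] | None = None
    weights: Sequence[float] | None = None


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives × measures table of q_j values with orientation flags."""

    alternatives: tuple[str, ...]
    measures: tuple[str, ...]
    maximizing: tuple[bool, ...]
    values: np.ndarray  # shape (n_alt, N)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype="float64")
        if v.shape != (len(self.alternatives), len(self.measures)):
            raise ValueError("decision matrix shape mismatch")
        if len(self.maximizing) != len(self.measures):
            raise ValueError("one orientation flag per measure required")
        if len(self.alternatives) < 2 or len(self.measures) < 1:
            raise ValueError("need >= 2 alternatives and >= 1 measure")
        if not np.isfinite(v).all():
            raise ValueError("decision matrix values must be finite")


@dataclass(frozen=True)
class FlowResult:
    """Positive, negative and net preference flows plus fractional ranks."""

    alternatives: tuple[str, ...]
    phi_plus: np.ndarray
    phi_minus: np.ndarray
    phi_net: np.ndarray
    ranks: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phi_plus": self.phi_plus,
                "phi_minus": self.phi_minus,
                "phi_net": self.phi_net,
                "rank": self.ranks,
            },
            index=list(self.alternatives),
        )


def preference_value(d, q: float):
    """V-shaped preference: 0 below 0, linear d/Q on [0, Q], 1 above Q."""
    if q <= 0:
        raise ValueError("indifference threshold Q must be positive")
    d = np.asarray(d, dtype="float64")
    out = np.clip(d / q, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _resolve_params(D: DecisionMatrix, params: PreferenceParams) -> tuple[np.ndarray, np.ndarray]:
    N = len(D.measures)
    if params.weights is None:
        w = np.ones(N)
    else:
        w = np.asarray(params.weights, dtype="float64")
        if w.shape != (N,):
            raise ValueError("one weight per measure required")
        if (w < 0).any() or not w.any():
            raise ValueError("weights must be non-negative and not all zero")
    if params.q is None:
        spread = D.values.max(axis=0) - D.values.min(axis=0)
        q = np.where(spread > 0, spread, 1.0)
    else:
        q = np.asarray(params.q, dtype="float64")
        if q.shape != (N,):
            raise ValueError("one Q per measure required")
        if (q <= 0).any():
            raise ValueError("indifference thresholds must be positive")
    return q, w


def pairwise_preferences(
    D: DecisionMatrix, params: PreferenceParams = PreferenceParams()
) -> pd.DataFrame:
    """Preference index π(A, B) for every ordered pair of alternatives.

    Per measure j, the difference d_j = q_j(A) − q_j(B) (negated for
    minimizing measures) passes through the V-shaped function with threshold
    Q_j; π is the weighted mean (1/N) Σ_j ω_j P_j.  The diagonal is 0.
    """
    q, w = _resolve_params(D, params)
    N = len(D.measures)
    sign = np.where(np.asarray(D.maximizing), 1.0, -1.0)
    # d[a, b, j] = oriented difference between alternatives a and b on measure j
    diff = (D.values[:, None, :] - D.values[None, :, :]) * sign
    pref = np.clip(diff / q, 0.0, 1.0)
    pi = (pref * w).sum(axis=2) / N
    np.fill_diagonal(pi, 0.0)
    return pd.DataFrame(pi, index=list(D.alternatives), columns=list(D.alternatives))


def fractional_ranks(phi_net: np.ndarray) -> np.ndarray:
    """Fractional (average-tie) ranks of net flows, rank 1 = largest flow."""
    return rankdata(-np.asarray(phi_net, dtype="float64"), method="average")


def flows(pi: pd.DataFrame | np.ndarray) -> FlowResult:
    """Positive/negative/net preference flows of a preference-index matrix."""
    if isinstance(pi, pd.DataFrame):
        labels = tuple(str(a) for a in pi.index)
        mat = pi.to_numpy(dtype="float64")
    else:
        mat = np.asarray(pi, dtype="float64")
        labels = tuple(f"A{i}" for i in range(mat.shape[0]))
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("preference index matrix must be square")
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 alternatives")
    off = mat.copy()
    np.fill_diagonal(off, 0.0)
    phi_plus = off.sum(axis=1) / (n - 1)
    phi_minus = off.sum(axis=0) / (n - 1)
    phi_net = phi_plus - phi_minus
    return FlowResult(
        alternatives=labels,
        phi_plus=phi_plus,
        phi_minus=phi_minus,
        phi_net=phi_net,
        ranks=fractional_ranks(phi_net),
    )


def rank_decision_matrix(
    D: DecisionMatrix, params: PreferenceParams = PreferenceParams()
) -> FlowResult:
    """Convenience: π then flows for one decision matrix."""
    return flows(pairwise_preferences(D, params))


# ---------------------------------------------------------------------------
# metric-table orientation


def _decision_matrix_from(
    cell: pd.DataFrame, alternatives: Sequence[str], measures: Sequence[str]
) -> DecisionMatrix:
    values = (
        cell.pivot_table(index="alternative", columns="measure", values="value")
        .reindex(index=list(alternatives), columns=list(measures))
        .to_numpy()
    )
    if np.isnan(values).any():
        missing = [
            (a, m)
            for i, a in enumerate(alternatives)
            for j, m in enumerate(measures)
            if np.isnan(values[i, j])
        ]
        raise ValueError(f"missing metric cells: {missing[:5]}")
    return DecisionMatrix(
        alternatives=tuple(alternatives),
        measures=tuple(measures),
        maximizing=tuple(MEASURE_MAXIMIZING[m] for m in measures),
        values=values,
    )


def rank_alternatives(
    metrics: pd.DataFrame,
    axis: str,
    target: str,
    task: str,
    params: PreferenceParams = PreferenceParams(),
) -> pd.DataFrame:
    """Rank methods per subset, or subsets per method, for one target.

    *metrics* is the tidy benchmark table (model, subset, target, fold,
    measure, value, task).  Fold-mean q_j values feed one decision matrix
    per context — per subset for ``axis="methods_per_subset"`` (alternatives
    are the methods), per method for ``axis="subsets_per_method"``
    (alternatives are the subsets).  Returns a frame of fractional ranks,
    alternatives × contexts, plus an ``avg`` column: the fractional ranking
    of each alternative's mean rank across contexts.
    """
    if axis not in ("methods_per_subset", "subsets_per_method"):
        raise ValueError(f"unknown axis {axis!r}")
    sub = metrics[(metrics["target"] == target) & (metrics["task"] == task)]
    if sub.empty:
        raise ValueError(f"no metric records for target {target!r}, task {task!r}")
    measures = CLASSIFICATION_MEASURES if task == "classification" else REGRESSION_MEASURES
    agg = (
        sub.groupby(["model", "subset", "measure"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    if axis == "methods_per_subset":
        contexts = list(dict.fromkeys(agg["subset"]))
        alternatives = list(dict.fromkeys(agg["model"]))
        ctx_col, alt_col = "subset", "model"
    else:
        contexts = list(dict.fromkeys(agg["model"]))
        alternatives = list(dict.fromkeys(agg["subset"]))
        ctx_col, alt_col = "model", "subset"
    table = pd.DataFrame(index=alternatives, columns=contexts, dtype="float64")
    for ctx in contexts:
        cell = agg[agg[ctx_col] == ctx].rename(columns={alt_col: "alternative"})
        D = _decision_matrix_from(cell, alternatives, measures)
        table[ctx] = rank_decision_matrix(D, params).ranks
    table["avg"] = fractional_ranks(-table[contexts].mean(axis=1).to_numpy())
    return table


def aggregate_ranks(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-target rank tables: cell-wise mean of ranks across
    targets, then fractional re-ranking of the means within each column."""
    if not tables:
        raise ValueError("no tables to aggregate")
    first = tables[0]
    for t in tables[1:]:
        if not (t.index.equals(first.index) and t.columns.equals(first.columns)):
            raise ValueError("rank tables are not conformable")
    mean = sum(t.to_numpy(dtype="float64") for t in tables) / len(tables)
    out = pd.DataFrame(index=first.index, columns=first.columns, dtype="float64")
    for j in range(mean.shape[1]):
        out.iloc[:, j] = rankdata(mean[:, j], method="average")
    return out
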