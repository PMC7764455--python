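"""Correlation-threshold dimensionality reduction into nested question subsets.

Pairs of questions whose answers correlate above a threshold are near
redundant: one member of each such pair can be dropped with little loss.
Applying a strictly decreasing ladder of thresholds TH_1 > TH_2 > … > TH_n,
each subset built from the previous one, yields nested question lists
F_0 ⊃ F_1 ⊃ … ⊃ F_n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureSubset", "pearson_matrix", "build_subsets"]


@dataclass(frozen=True)
class FeatureSubset:
    """A question subset F_i: its threshold TH_i (None for F_0) and item list.

    ``removed`` is an audit trail of (kept item, removed item, r) triples for
    the removals that produced this subset from its parent.
    """

    tag: str
    threshold: float | None
    items: tuple[str, ...]
    removed: tuple[tuple[str, str, float], ...] = field(default=())

    def __contains__(self, item: str) -> bool:
        return item in self.items

    def __len__(self) -> int:
        return len(self.items)


def pearson_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Zero-variance columns (for which Pearson is undefined) are assigned
    r = 0 against every other column, so they are never flagged redundant.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 rows to correlate")
    X = features.to_numpy(dtype="float64")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=features.columns, columns=features.columns)


def _drop_later(a: str, b: str, order: dict[str, int], corr: pd.DataFrame) -> str:
    return a if order[a] > order[b] else b


def _drop_higher_mean_abs(a: str, b: str, order: dict[str, int], corr: pd.DataFrame) -> str:
    n = len(corr) - 1
    ma = (corr[a].abs().sum() - 1.0) / max(n, 1)
    mb = (corr[b].abs().sum() - 1.0) / max(n, 1)
    if ma == mb:
        return _drop_later(a, b, order, corr)
    return a if ma > mb else b


_RULES: dict[str, Callable] = {
    "later": _drop_later,
    "higher_mean_abs_r": _drop_higher_mean_abs,
}


def build_subsets(
    corr: pd.DataFrame,
    thresholds: Sequence[float],
    rule: str | Callable = "later",
    use_abs: bool = True,
) -> list[FeatureSubset]:
    """Build the nested subsets F_0, F_1, …, F_n from a correlation matrix.

    F_0 is the full item set.  Each F_i is built from F_{i-1}: among the
    remaining items, pairs with |r| > TH_i (signed r if ``use_abs=False``)
    are visited in decreasing |r|; if both members are still present, one is
    removed by *rule* (default: the later item in questionnaire order) and
    the removal is recorded in the audit trail.  Building each subset from
    the previous one makes the nesting F_0 ⊇ F_1 ⊇ … ⊇ F_n structural.

    Parameters
    ----------
    thresholds
        Strictly decreasing, each in (0, 1).
    rule
        ``"later"``, ``"higher_mean_abs_r"``, or a callable
        ``(a, b, order, corr) -> item to remove``.
    """
    ths = [float(t) for t in thresholds]
    if any(b >= a for a, b in zip(ths, ths[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    if any(not (0.0 < t < 1.0) for t in ths):
        raise ValueError("thresholds must lie in (0, 1)")
    chooser = _RULES[rule] if isinstance(rule, str) else rule
    items = tuple(corr.columns)
    order = {item: i for i, item in enumerate(items)}
    subsets = [FeatureSubset(tag="F0", threshold=None, items=items)]
    current = list(items)
    for i, th in enumerate(ths, start=1):
        pairs = []
        for ai in range(len(current)):
            for bi in range(ai + 1, len(current)):
                a, b = current[ai], current[bi]
                r = float(corr.at[a, b])
                strength = abs(r) if use_abs else r
                if strength > th:
                    pairs.append((strength, order[a], order[b], a, b, r))
        # decreasing strength; item order breaks ties deterministically
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        alive = set(current)
        removals = []
        for strength, _, _, a, b, r in pairs:
            if a not in alive or b not in alive:
                continue
            drop = chooser(a, b, order, corr)
            keep = b if drop == a else a
            alive.discard(drop)
            removals.append((keep, drop, r))
        current = [it for it in current if it in alive]
        subsets.append(
            FeatureSubset(
                tag=f"F{i}",
                threshold=th,
                items=tuple(current),
                removed=tuple(removals),
            )
        )
    return subsets
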