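"""Nutrient amounts, diet-quality scores, and the two imputation baselines.

The deterministic scoring pipeline sums per-item per-frequency gram
contributions into a daily intake amount and maps the amount through
per-target cutoffs onto a discrete quality score (1 bad / 2 medium /
3 good).  When only a subset of questions is answered, the two statistical
baselines complete the matrix first: *zero imputation* sets unanswered items
to the lowest frequency ("rarely or never") — systematically underestimating
intake — and *MICE* fills them by iterated conditional modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .questionnaire import QuestionnaireDef, ScoreCutoffs, TargetSpec

__all__ = [
    "compute_amount",
    "amount_to_score",
    "compute_ground_truth",
    "zero_impute",
    "ImputationSpec",
    "mice_impute",
    "pool_amounts",
]


def _keep_items(keep) -> tuple[str, ...]:
    items = getattr(keep, "items", keep)
    if callable(items):  # a Mapping's .items method, not a FeatureSubset field
        raise TypeError("keep must be a FeatureSubset or a sequence of item tags")
    return tuple(items)


def compute_amount(row: Mapping[str, int] | pd.Series, target: TargetSpec) -> float:
    """Daily intake amount (g) for one respondent: the sum over the target's
    items of the gram contribution at the answered frequency code."""
    total = 0.0
    for item in target.amounts.items:
        try:
            code = row[item]
        except (KeyError, IndexError) as exc:
            raise ValueError(f"missing answer for item {item!r}") from exc
        if pd.isna(code):
            raise ValueError(f"missing answer for item {item!r}; impute first")
        total += target.amounts.contribution(item, int(code))
    return total


def amount_to_score(amount: float, cutoffs: ScoreCutoffs) -> int:
    """Map a daily amount onto the discrete quality score {1, 2, 3}.

    Both boundary amounts belong to the middle class (e.g. with vegetable
    cutoffs 80/240 g, both 80 g and 240 g score 2).
    """
    if amount < 0:
        raise ValueError("amount must be non-negative")
    lo, hi = cutoffs.boundaries
    if amount < lo:
        klass = 0
    elif amount <= hi:
        klass = 1
    else:
        klass = 2
    if cutoffs.direction == "lower_better":
        klass = 2 - klass
    return cutoffs.scores[klass]


def compute_ground_truth(answers: pd.DataFrame, qdef: QuestionnaireDef) -> pd.DataFrame:
    """Amounts and scores for every respondent × target from complete answers.

    Returns a tidy frame (respondent, target, amount, score).  These are the
    "true values" against which predictions from question subsets are judged.
    """
    if answers.isna().any().any():
        raise ValueError("answers contain missing entries; impute first")
    records = []
    for rid, row in answers.iterrows():
        for t in qdef.targets:
            amount = compute_amount(row, t)
            records.append(
                {
                    "respondent": rid,
                    "target": t.name,
                    "amount": amount,
                    "score": amount_to_score(amount, t.cutoffs),
                }
            )
    return pd.DataFrame.from_records(records)


def zero_impute(answers: pd.DataFrame, keep) -> pd.DataFrame:
    """Complete *answers* by setting every column outside *keep* to code 0
    ("rarely or never") for all respondents; kept columns pass through."""
    kept = set(_keep_items(keep))
    missing_cols = set(kept) - set(answers.columns)
    if missing_cols:
        raise ValueError(f"keep refers to absent columns: {sorted(missing_cols)}")
    out = answers.copy()
    for col in out.columns:
        if col not in kept:
            out[col] = 0
    return out.astype("Int64")


@dataclass(frozen=True)
class ImputationSpec:
    """Parameters of the chained-equations baseline.

    m completed matrices are drawn (residual-scale Gaussian noise added
    before rounding); downstream amounts are pooled by averaging and the
    pooled amount is re-mapped to a score (see :func:`pool_amounts`).
    """

    method: str = "MICE"
    m: int = 5
    max_iter: int = 10
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("imputation parameters must be positive")


def mice_impute(
    answers: pd.DataFrame,
    keep,
    spec: ImputationSpec = ImputationSpec(),
    train: pd.DataFrame | None = None,
    n_levels: int = 8,
) -> list[pd.DataFrame]:
    """Fill the columns outside *keep* by chained-equations imputation.

    Each dropped column is regressed (linear model) on all other columns
    using *train* — a complete matrix where those columns were observed
    (default: *answers* itself).  Predictions are cycled in questionnaire
    order until the largest change falls below ``spec.tol`` or
    ``spec.max_iter`` rounds elapse, then rounded and clipped to the valid
    code range.  Returns ``spec.m`` completed matrices; kept columns are
    bit-identical to the input.  Fixed seed ⇒ identical output.
    """
    kept = list(dict.fromkeys(_keep_items(keep)))
    if not kept:
        raise ValueError("keep must be non-empty: MICE needs columns to condition on")
    if answers[kept].isna().any().any():
        raise ValueError("kept columns contain missing entries")
    cols = list(answers.columns)
    drop_cols = [c for c in cols if c not in kept]
    if not drop_cols:
        return [answers.astype("Int64").copy() for _ in range(spec.m)]
    if train is None:
        train = answers
    if train[cols].isna().any().any():
        raise ValueError("training matrix must be complete")

    Xtr = train[cols].to_numpy(dtype="float64")
    models: dict[str, tuple[LinearRegression, float]] = {}
    for col in drop_cols:
        j = cols.index(col)
        other = [k for k in range(len(cols)) if k != j]
        reg = LinearRegression().fit(Xtr[:, other], Xtr[:, j])
        resid = Xtr[:, j] - reg.predict(Xtr[:, other])
        models[col] = (reg, float(resid.std(ddof=0)))

    # iterate point predictions to a fixed point (visit in questionnaire order)
    X = answers[cols].astype("Float64").to_numpy(dtype="float64", na_value=np.nan)
    for col in drop_cols:
        j = cols.index(col)
        X[:, j] = Xtr[:, j].mean()
    for _ in range(spec.max_iter):
        delta = 0.0
        for col in drop_cols:
            j = cols.index(col)
            other = [k for k in range(len(cols)) if k != j]
            reg, _ = models[col]
            new = reg.predict(X[:, other])
            delta = max(delta, float(np.abs(new - X[:, j]).max(initial=0.0)))
            X[:, j] = new
        if delta < spec.tol:
            break

    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.m):
        Xi = X.copy()
        for col in drop_cols:
            j = cols.index(col)
            _, sigma = models[col]
            noisy = Xi[:, j] + rng.normal(0.0, sigma, size=len(Xi))
            Xi[:, j] = np.clip(np.rint(noisy), 0, n_levels - 1)
        df = pd.DataFrame(Xi, index=answers.index, columns=cols)
        df[kept] = answers[kept]
        out.append(df.astype("Int64"))
    return out


def pool_amounts(imputed: Sequence[pd.DataFrame], qdef: QuestionnaireDef) -> pd.DataFrame:
    """Pool multiply-imputed matrices: average per-imputation amounts, then
    re-map the pooled amount to a score.  Returns a ground-truth-shaped
    tidy frame (respondent, target, amount, score)."""
    tables = [compute_ground_truth(df, qdef) for df in imputed]
    pooled = tables[0][["respondent", "target"]].copy()
    pooled["amount"] = np.mean([t["amount"].to_numpy() for t in tables], axis=0)
    pooled["score"] = [
        amount_to_score(a, qdef.target(t).cutoffs)
        for a, t in zip(pooled["amount"], pooled["target"])
    ]
    return pooled
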