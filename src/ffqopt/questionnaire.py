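"""Questionnaire definitions, answer matrices and feature standardization.

A food frequency questionnaire (FFQ) is modelled as an ordered list of item
tags, an ordered consumption-frequency scale, and a set of nutrient targets.
Each target carries an *amount table* (grams/day contributed by each item at
each frequency level) and *score cutoffs* that map a daily amount onto a
discrete diet-quality score (1 bad / 2 medium / 3 good).

Answers are held in a plain :class:`pandas.DataFrame` (respondents × items)
with nullable-integer frequency codes; missing answers are ``pd.NA``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "QuestionnaireError",
    "FrequencyScale",
    "AmountTable",
    "ScoreCutoffs",
    "TargetSpec",
    "QuestionnaireDef",
    "load_questionnaire",
    "write_questionnaire",
    "load_answers",
    "validate_answers",
    "ColumnStats",
    "standardize",
]


class QuestionnaireError(ValueError):
    """Raised when a questionnaire file or answer matrix violates the schema."""


def _normalize_label(label: str) -> str:
    # en-dash and hyphen spellings of ranges ("1–2" vs "1-2") are equivalent
    return " ".join(str(label).strip().lower().replace("–", "-").split())


@dataclass(frozen=True)
class FrequencyScale:
    """Ordered consumption-frequency scale; codes are 0..L-1 aligned with labels.

    Level 0 is always the "never" anchor ("rarely or never"), which is what
    zero imputation assigns to unanswered items.
    """

    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise QuestionnaireError("scale needs at least 2 levels")
        norm = [_normalize_label(lv) for lv in self.levels]
        if len(set(norm)) != len(norm):
            raise QuestionnaireError("scale labels are not unique")
        if norm[0] != "rarely or never":
            raise QuestionnaireError(
                f"level 0 must be 'rarely or never', got {self.levels[0]!r}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def codes(self) -> range:
        return range(len(self.levels))

    def code_of(self, label: str) -> int:
        """Resolve a level label (case/dash-insensitive) to its integer code."""
        want = _normalize_label(label)
        for code, lv in enumerate(self.levels):
            if _normalize_label(lv) == want:
                return code
        raise QuestionnaireError(f"unknown frequency label {label!r}")


@dataclass(frozen=True)
class AmountTable:
    """Per-item grams/day contributions for each frequency code.

    ``grams[item][code]`` is the daily amount contributed by *item* when it
    is consumed at frequency *code*.  Contributions start at 0 for code 0 and
    are non-decreasing in frequency.
    """

    grams: Mapping[str, tuple[float, ...]]

    def validate(self, n_levels: int) -> None:
        for item, row in self.grams.items():
            if len(row) != n_levels:
                raise QuestionnaireError(
                    f"amount row for {item!r} has {len(row)} entries, scale has {n_levels}"
                )
            if row[0] != 0.0:
                raise QuestionnaireError(f"amount for {item!r} at level 0 must be 0")
            if any(v < 0 for v in row):
                raise QuestionnaireError(f"negative amount entry for {item!r}")
            if any(b < a for a, b in zip(row, row[1:])):
                raise QuestionnaireError(f"amounts for {item!r} not non-decreasing")

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.grams)

    def contribution(self, item: str, code: int) -> float:
        return float(self.grams[item][int(code)])


@dataclass(frozen=True)
class ScoreCutoffs:
    """Two amount boundaries splitting grams/day into 3 score classes.

    With ``direction='higher_better'``: amount < boundaries[0] scores 1,
    boundaries[0] <= amount <= boundaries[1] scores 2 (both boundary amounts
    fall in the middle class), amount > boundaries[1] scores 3.  With
    ``'lower_better'`` the outer classes swap.
    """

    boundaries: tuple[float, float]
    direction: str = "higher_better"

    scores: tuple[int, int, int] = field(default=(1, 2, 3), init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.boundaries) != 2:
            raise QuestionnaireError("exactly 3 score classes: give 2 boundaries")
        if not self.boundaries[0] < self.boundaries[1]:
            raise QuestionnaireError("cutoff boundaries must be strictly increasing")
        if self.direction not in ("higher_better", "lower_better"):
            raise QuestionnaireError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class TargetSpec:
    """A nutrient target: its amount table and its score cutoffs."""

    name: str
    amounts: AmountTable
    cutoffs: ScoreCutoffs


@dataclass(frozen=True)
class QuestionnaireDef:
    """A full questionnaire: items, frequency scale, and nutrient targets."""

    name: str
    items: tuple[str, ...]
    scale: FrequencyScale
    targets: tuple[TargetSpec, ...]
    reconstructed_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            dupes = sorted({t for t in self.items if list(self.items).count(t) > 1})
            raise QuestionnaireError(f"duplicate item tags: {dupes}")
        names = [t.name for t in self.targets]
        if len(set(names)) != len(names):
            raise QuestionnaireError("duplicate target names")
        for t in self.targets:
            t.amounts.validate(self.scale.n_levels)
            extra = set(t.amounts.items) - set(self.items)
            if extra:
                raise QuestionnaireError(
                    f"target {t.name!r} amount table covers unknown items {sorted(extra)}"
                )
        extra = set(self.reconstructed_items) - set(self.items)
        if extra:
            raise QuestionnaireError(f"reconstructed_items not in items: {sorted(extra)}")

    def target(self, name: str) -> TargetSpec:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def target_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.targets)


# ---------------------------------------------------------------------------
# file I/O


def load_questionnaire(path: str | Path) -> QuestionnaireDef:
    """Read a questionnaire definition from its YAML schema file.

    The schema holds ``name``, ``scale`` (ordered labels), ``items`` (ordered
    tags), optional ``reconstructed_items``, and ``targets``: a mapping of
    target name to ``{direction, amounts: {item: [per-code grams]}, cutoffs:
    [low, high]}``.  All type invariants are checked; violations raise
    :class:`QuestionnaireError` naming the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _from_dict(raw)


def _from_dict(raw: Mapping) -> QuestionnaireDef:
    try:
        scale = FrequencyScale(tuple(raw["scale"]))
        targets = []
        for name, spec in (raw.get("targets") or {}).items():
            amounts = AmountTable(
                {item: tuple(float(v) for v in row) for item, row in spec["amounts"].items()}
            )
            cutoffs = ScoreCutoffs(
                tuple(float(v) for v in spec["cutoffs"]),
                direction=spec.get("direction", "higher_better"),
            )
            targets.append(TargetSpec(name=name, amounts=amounts, cutoffs=cutoffs))
        return QuestionnaireDef(
            name=raw.get("name", "questionnaire"),
            items=tuple(raw["items"]),
            scale=scale,
            targets=tuple(targets),
            reconstructed_items=tuple(raw.get("reconstructed_items") or ()),
        )
    except KeyError as exc:
        raise QuestionnaireError(f"missing schema field: {exc}") from exc


def _to_dict(qdef: QuestionnaireDef) -> dict:
    return {
        "name": qdef.name,
        "scale": list(qdef.scale.levels),
        "items": list(qdef.items),
        "reconstructed_items": list(qdef.reconstructed_items),
        "targets": {
            t.name: {
                "direction": t.cutoffs.direction,
                "amounts": {item: [float(v) for v in row] for item, row in t.amounts.grams.items()},
                "cutoffs": [float(v) for v in t.cutoffs.boundaries],
            }
            for t in qdef.targets
        },
    }


def write_questionnaire(qdef: QuestionnaireDef, path: str | Path) -> None:
    """Write *qdef* to YAML such that :func:`load_questionnaire` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(qdef), fh, sort_keys=False, allow_unicode=True)


def load_answers(
    path: str | Path,
    qdef: QuestionnaireDef,
    missing_token: str = "",
) -> pd.DataFrame:
    """Read an answer CSV into a respondents × items frame of frequency codes.

    The CSV has a header row of item tags and one respondent per row; cells
    may be level labels, integer codes, or the *missing_token* (default:
    empty cell), which becomes ``pd.NA``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(qdef.items)
    if unknown:
        raise QuestionnaireError(f"unknown item tags in answer header: {sorted(unknown)}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype="Int64")
    for col in df.columns:
        for i, cell in df[col].items():
            cell = cell.strip()
            if cell == missing_token:
                out.at[i, col] = pd.NA
                continue
            try:
                code = int(cell)
                if code not in qdef.scale.codes:
                    raise QuestionnaireError(
                        f"code {code} out of range at row {i}, column {col!r}"
                    )
            except ValueError:
                try:
                    code = qdef.scale.code_of(cell)
                except QuestionnaireError as exc:
                    raise QuestionnaireError(
                        f"unresolvable label {cell!r} at row {i}, column {col!r}"
                    ) from exc
            out.at[i, col] = code
    return out


def validate_answers(answers: pd.DataFrame, qdef: QuestionnaireDef) -> None:
    """Check that *answers* columns and non-missing codes fit *qdef*."""
    unknown = set(answers.columns) - set(qdef.items)
    if unknown:
        raise QuestionnaireError(f"unknown item tags: {sorted(unknown)}")
    vals = answers.to_numpy(dtype="float64", na_value=np.nan)
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite.min() < 0 or finite.max() >= qdef.scale.n_levels):
        raise QuestionnaireError("answer codes out of scale range")


# ---------------------------------------------------------------------------
# standardization


@dataclass(frozen=True)
class ColumnStats:
    """Fitted per-column mean and scale used by :func:`standardize`."""

    items: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray  # population standard deviation; 1.0 for constant columns


def standardize(
    answers: pd.DataFrame,
    stats: ColumnStats | None = None,
) -> tuple[pd.DataFrame, ColumnStats]:
    """Center each column to mean 0 and scale it to unit (population) variance.

    When *stats* is None the statistics are fitted on *answers* and returned,
    so that test folds can be transformed with training-fold statistics
    (transform-only contract).  Zero-variance columns are emitted as all
    zeros with a warning so downstream models never see non-finite values.
    """
    if answers.isna().any().any():
        raise QuestionnaireError("standardize requires a complete matrix; impute first")
    X = answers.to_numpy(dtype="float64")
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        constant = sd == 0.0
        if constant.any():
            cols = [c for c, flag in zip(answers.columns, constant) if flag]
            warnings.warn(f"zero-variance columns emitted as zeros: {cols}", stacklevel=2)
        scale = np.where(constant, 1.0, sd)
        stats = ColumnStats(items=tuple(answers.columns), mean=mean, scale=scale)
    else:
        if tuple(answers.columns) != stats.items:
            raise QuestionnaireError("stats were fitted on a different item set")
    Z = (X - stats.mean) / stats.scale
    return pd.DataFrame(Z, index=answers.index, columns=answers.columns), stats
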