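"""Synthetic FFQ cohorts with known planted structure.

The study's raw answers are not public, so every stage of the pipeline is
exercised on generated cohorts instead: ordinal 8-level frequency answers
drawn through a Gaussian copula (a latent multivariate normal thresholded
at per-item cut-points), with exact control over planted inter-item
correlations, and nutrient targets whose amounts are deterministic sums of
per-item per-frequency contributions — so ground truth is recomputable
bit-for-bit through the scoring module.

The default cohort size, 289, mirrors the study population (92 project
respondents joined with 197 national-survey respondents).  The default
frequency marginals are mildly right-skewed; the real answer marginals are
unpublished, so this choice is explicitly arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import scoring
from .questionnaire import (
    AmountTable,
    FrequencyScale,
    QuestionnaireDef,
    ScoreCutoffs,
    TargetSpec,
)

__all__ = [
    "DEFAULT_MARGINALS",
    "TABLE1_LADDER",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_amount_tables",
    "generate_cohort",
    "make_missing",
]

#: default probability of each of the 8 frequency levels (right-skewed:
#: "rarely or never" is the most common answer)
DEFAULT_MARGINALS = (0.25, 0.20, 0.15, 0.12, 0.10, 0.08, 0.06, 0.04)

#: the published vegetable gram ladder, reused (rescaled) for generated targets
TABLE1_LADDER = (0.0, 4.0, 11.2, 28.8, 56.8, 120.0, 280.0, 480.0)

_SCALE_LABELS = (
    "rarely or never",
    "less than once a week",
    "once a week",
    "2–3 times a week",
    "4–6 times a week",
    "1–2 times a day",
    "3–4 times a day",
    "5+ a day",
)

_VEGETABLE_PRESET_ITEMS = ("salad", "vegetables")


def _derived_seed(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions under which a cohort is generated.

    ``planted_pairs`` are (item A, item B, latent r) triples layered on a
    uniform ``background_r``; ``noise`` shrinks the whole latent correlation
    matrix toward independence by ``(1 - noise)``.  ``target_items`` names
    each target's contributing items; their per-frequency gram
    contributions are the published vegetable ladder rescaled by a
    seed-deterministic per-item weight (or given explicitly via
    ``target_contributions``).
    """

    n_respondents: int = 289
    items: tuple[str, ...] = ()
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    background_r: float = 0.0
    marginals: tuple[float, ...] = DEFAULT_MARGINALS
    target_items: Mapping[str, Sequence[str]] = field(default_factory=dict)
    target_contributions: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=dict
    )
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.items:
            from .datasets import esfffq

            object.__setattr__(self, "items", esfffq().items)
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be positive")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must lie in [0, 1)")
        probs = np.asarray(self.marginals, dtype="float64")
        if (probs <= 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("marginals must be positive and sum to 1")
        seen = {}
        for a, b, r in self.planted_pairs:
            if a not in self.items or b not in self.items:
                raise ValueError(f"planted pair ({a}, {b}) names unknown items")
            if not -1.0 < r < 1.0:
                raise ValueError(f"planted r must lie in (-1, 1), got {r}")
            key = frozenset((a, b))
            if key in seen and seen[key] != r:
                raise ValueError(f"conflicting r for pair ({a}, {b})")
            seen[key] = r
        for name, its in self.target_items.items():
            if not its:
                raise ValueError(f"target {name!r} has no contributing items")
            unknown = set(its) - set(self.items)
            if unknown:
                raise ValueError(f"target {name!r} names unknown items {sorted(unknown)}")

    @property
    def n_levels(self) -> int:
        return len(self.marginals)

    def cutpoints(self) -> np.ndarray:
        """Latent-normal thresholds (7 per item for 8 levels) realizing the
        marginal level probabilities."""
        return norm.ppf(np.cumsum(self.marginals)[:-1])


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated cohort together with everything needed to verify it."""

    answers: pd.DataFrame
    qdef: QuestionnaireDef
    latent: np.ndarray  # the latent normal draws (respondents × items)
    latent_corr: pd.DataFrame  # the exact correlation matrix sampled from
    truth: pd.DataFrame  # tidy (respondent, target, amount, score)
    planted_pairs: tuple[tuple[str, str, float], ...]


def _item_weights(config: SyntheticConfig) -> dict[str, float]:
    rng = _derived_seed(config.seed, 1)
    return {item: float(rng.uniform(0.3, 1.0)) for item in config.items}


def generate_amount_tables(
    config: SyntheticConfig,
) -> dict[str, tuple[AmountTable, ScoreCutoffs]]:
    """Amount tables and cutoffs for each configured target.

    Contributions follow the published vegetable gram ladder rescaled by a
    per-item weight (explicit contributions in ``target_contributions``
    win).  A target named ``vegetable`` over exactly (salad, vegetables)
    returns the published tables verbatim.  Cutoffs are placed at the 1/3
    and 2/3 quantiles of the amount distribution induced by the marginals,
    so all three score classes are populated.
    """
    if not config.target_items:
        raise ValueError("config defines no targets")
    weights = _item_weights(config)
    rng = _derived_seed(config.seed, 2)
    out: dict[str, tuple[AmountTable, ScoreCutoffs]] = {}
    for name, its in config.target_items.items():
        if name == "vegetable" and tuple(its) == _VEGETABLE_PRESET_ITEMS:
            out[name] = (
                AmountTable({item: TABLE1_LADDER for item in its}),
                ScoreCutoffs((80.0, 240.0)),
            )
            continue
        explicit = config.target_contributions.get(name, {})
        grams = {}
        for item in its:
            if item in explicit:
                grams[item] = tuple(float(v) for v in explicit[item])
            else:
                w = weights[item]
                grams[item] = tuple(round(v * w, 4) for v in TABLE1_LADDER)
        table = AmountTable(grams)
        # empirical amount distribution under independent marginal answers
        codes = rng.choice(config.n_levels, size=(4000, len(its)), p=config.marginals)
        amounts = np.zeros(4000)
        for j, item in enumerate(its):
            amounts += np.asarray(grams[item])[codes[:, j]]
        lo, hi = np.quantile(amounts, [1 / 3, 2 / 3])
        if hi <= lo:
            hi = lo + max(1.0, abs(lo) * 0.1)
        out[name] = (table, ScoreCutoffs((float(lo), float(hi))))
    return out


def _correlation_matrix(config: SyntheticConfig) -> np.ndarray:
    p = len(config.items)
    R = np.full((p, p), config.background_r, dtype="float64")
    np.fill_diagonal(R, 1.0)
    idx = {item: i for i, item in enumerate(config.items)}
    for a, b, r in config.planted_pairs:
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    if config.noise:
        R = (1.0 - config.noise) * R
        np.fill_diagonal(R, 1.0)
    return R


def _nearest_psd(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= -1e-10:
        return R
    warnings.warn("correlation spec not positive semi-definite; repairing by eigenvalue clipping")
    vals = np.clip(vals, 1e-8, None)
    R2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def generate_cohort(config: SyntheticConfig) -> SyntheticTruth:
    """Draw a cohort: latent multivariate-normal rows with the configured
    correlation, thresholded per item into ordinal codes, with amounts and
    scores computed through the scoring module.  Deterministic under seed."""
    R = _nearest_psd(_correlation_matrix(config))
    try:
        L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation spec could not be repaired to PSD") from exc
    rng = _derived_seed(config.seed, 0)
    Z = rng.standard_normal((config.n_respondents, len(config.items)))
    latent = Z @ L.T
    cut = config.cutpoints()
    codes = np.searchsorted(cut, latent, side="left")
    answers = pd.DataFrame(codes, columns=list(config.items)).astype("Int64")
    answers.index.name = "respondent"

    tables = generate_amount_tables(config)
    targets = tuple(
        TargetSpec(name=name, amounts=table, cutoffs=cuts)
        for name, (table, cuts) in tables.items()
    )
    qdef = QuestionnaireDef(
        name="synthetic",
        items=tuple(config.items),
        scale=FrequencyScale(_SCALE_LABELS[: config.n_levels]),
        targets=targets,
    )
    truth = scoring.compute_ground_truth(answers, qdef)
    return SyntheticTruth(
        answers=answers,
        qdef=qdef,
        latent=latent,
        latent_corr=pd.DataFrame(R, index=list(config.items), columns=list(config.items)),
        truth=truth,
        planted_pairs=tuple(config.planted_pairs),
    )


def make_missing(answers: pd.DataFrame, keep) -> pd.DataFrame:
    """Blank every column outside *keep* (the respondent did not answer it);
    kept columns pass through unchanged."""
    kept = set(getattr(keep, "items", keep))
    out = answers.astype("Int64").copy()
    for col in out.columns:
        if col not in kept:
            out[col] = pd.NA
    return out
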