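"""End-to-end experiment orchestration: load → score → reduce → benchmark →
rank → report, from a single config with one master seed.

The master seed fans out deterministically to the fold plan, the learners,
the chained-equations baseline and the synthetic generator (independent
seed streams derived via :class:`numpy.random.SeedSequence`), so a rerun
with the same config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bench, promethee, reduction, scoring, synthetic
from .questionnaire import QuestionnaireDef, load_answers, load_questionnaire, standardize

__all__ = ["RunConfig", "RunResult", "derive_seed", "run_experiment", "recommend_questions"]

_SEED_STREAMS = {"folds": 0, "learners": 1, "mice": 2, "synthetic": 3}


def derive_seed(master: int, stream: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the master seed."""
    ss = np.random.SeedSequence([int(master), _SEED_STREAMS[stream]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment needs.

    Either ``questionnaire``/``answers`` paths or a ``synthetic`` cohort
    config must be given.  ``thresholds`` is the strictly decreasing
    correlation ladder; ``targets`` defaults to all targets of the
    questionnaire; ``promethee_q``/``promethee_weights`` default to the
    per-decision-matrix automatic threshold and equal weights.
    """

    thresholds: tuple[float, ...]
    questionnaire: str | None = None
    answers: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    targets: tuple[str, ...] | None = None
    folds: int = 5
    seed: int = 0
    mice_m: int = 5
    mice_max_iter: int = 10
    removal_rule: str = "later"
    models: tuple[str, ...] | None = None  # roster filter by label; None = all 8 + baselines
    promethee_q: tuple[float, ...] | None = None
    promethee_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and (self.questionnaire is None or self.answers is None):
            raise ValueError("give questionnaire+answers paths or a synthetic config")
        ths = list(self.thresholds)
        if any(b >= a for a, b in zip(ths, ths[1:])):
            raise ValueError("thresholds must be strictly decreasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            for key in ("planted_pairs",):
                if key in syn:
                    syn[key] = tuple(tuple(p) for p in syn[key])
            if "items" in syn:
                syn["items"] = tuple(syn["items"])
            syn = synthetic.SyntheticConfig(**syn)
        raw["thresholds"] = tuple(raw["thresholds"])
        for key in ("targets", "models", "promethee_q", "promethee_weights"):
            if raw.get(key):
                raw[key] = tuple(raw[key])
        return cls(synthetic=syn, **raw)


@dataclass
class RunResult:
    """The report bundle: inputs, intermediates, and every rank table."""

    config: RunConfig
    qdef: QuestionnaireDef
    answers: pd.DataFrame
    subsets: list[reduction.FeatureSubset]
    plan: bench.FoldPlan
    metrics: pd.DataFrame
    rank_tables: dict[tuple[str, str, str], pd.DataFrame]  # (target, task, axis)
    overall: dict[tuple[str, str], pd.DataFrame]  # (task, axis) aggregated over targets
    log: list[str] = field(default_factory=list)

    def targets(self) -> list[str]:
        return sorted({t for t, _, _ in self.rank_tables})


def _load_inputs(config: RunConfig) -> tuple[QuestionnaireDef, pd.DataFrame]:
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=derive_seed(config.seed, "synthetic"))
        truth = synthetic.generate_cohort(syn)
        return truth.qdef, truth.answers
    qdef = load_questionnaire(config.questionnaire)
    answers = load_answers(config.answers, qdef)
    if answers.isna().any().any():
        raise ValueError("experiment answers must be complete")
    return qdef, answers


def run_experiment(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Run the full pipeline and (optionally) persist the report bundle.

    Per target, produces a methods-ranking table and a subsets-ranking
    table for each task (classification on quality scores, regression on
    amounts), then aggregates ranks across targets into the overall
    best-method, best-subset and per-subset best-method tables.  All
    intermediates (subsets, removal audit, tidy metric table, rank tables)
    are written as CSV when *outdir* is given.
    """
    log: list[str] = [f"seed={config.seed}"]
    qdef, answers = _load_inputs(config)
    log.append(f"cohort: {len(answers)} respondents x {len(answers.columns)} items")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        features, _ = standardize(answers)
        corr = reduction.pearson_matrix(features)
        subsets = reduction.build_subsets(corr, config.thresholds, rule=config.removal_rule)
    log.extend(f"warning: {w.message}" for w in caught)
    log.append("subsets: " + ", ".join(f"{s.tag}({len(s)})" for s in subsets))

    plan = bench.make_folds(len(answers), config.folds, derive_seed(config.seed, "folds"))
    log.append(f"fold plan: k={plan.k} seed={plan.seed} hash={hash(plan.assignments.tobytes())}")
    learner_seed = derive_seed(config.seed, "learners")
    roster = bench.default_roster("classification", learner_seed) + bench.default_roster(
        "regression", learner_seed
    )
    if config.models is not None:
        roster = [m for m in roster if m.id in config.models]
        if not roster:
            raise ValueError("models filter matches no roster entry")
    mice_spec = scoring.ImputationSpec(
        m=config.mice_m, max_iter=config.mice_max_iter, seed=derive_seed(config.seed, "mice")
    )
    log.append(f"mice: m={mice_spec.m} max_iter={mice_spec.max_iter} seed={mice_spec.seed}")
    targets = list(config.targets) if config.targets else list(qdef.target_names)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics = bench.run_benchmark(
            answers, qdef, subsets, targets=targets, roster=roster, plan=plan, mice_spec=mice_spec
        )

    params = promethee.PreferenceParams(q=config.promethee_q, weights=config.promethee_weights)
    rank_tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    for target in targets:
        for task in ("classification", "regression"):
            for axis in ("methods_per_subset", "subsets_per_method"):
                rank_tables[(target, task, axis)] = promethee.rank_alternatives(
                    metrics, axis, target, task, params
                )
    overall: dict[tuple[str, str], pd.DataFrame] = {}
    for task in ("classification", "regression"):
        for axis in ("methods_per_subset", "subsets_per_method"):
            overall[(task, axis)] = promethee.aggregate_ranks(
                [rank_tables[(t, task, axis)] for t in targets]
            )

    result = RunResult(
        config=config,
        qdef=qdef,
        answers=answers,
        subsets=subsets,
        plan=plan,
        metrics=metrics,
        rank_tables=rank_tables,
        overall=overall,
        log=log,
    )
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


def _persist(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# seed={result.config.seed}\n"

    rows = [(s.tag, item) for s in result.subsets for item in s.items]
    pd.DataFrame(rows, columns=["subset", "item"]).to_csv(outdir / "subsets.csv", index=False)
    audit = [
        (s.tag, s.threshold, kept, removed, r)
        for s in result.subsets
        for kept, removed, r in s.removed
    ]
    pd.DataFrame(audit, columns=["subset", "threshold", "kept", "removed", "r"]).to_csv(
        outdir / "removals.csv", index=False
    )
    result.metrics.to_csv(outdir / "metrics.csv", index=False)
    for (target, task, axis), table in result.rank_tables.items():
        table.to_csv(outdir / f"ranks_{target}_{task}_{axis}.csv")
    for (task, axis), table in result.overall.items():
        table.to_csv(outdir / f"overall_{task}_{axis}.csv")
        with open(outdir / f"overall_{task}_{axis}.txt", "w") as fh:
            fh.write(header + table.round(1).to_string() + "\n")
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(header + "\n".join(result.log) + "\n")


def recommend_questions(
    result: RunResult | Sequence[reduction.FeatureSubset], budget: int
) -> tuple[list[str], str | None]:
    """Questions to ask under a budget, plus the model to use.

    Questions come in subset-nesting order — all of the innermost subset
    F_n first, then the questions F_{n-1} adds, and so on — truncated at
    *budget*.  The recommended model is the best-ranked method (overall
    classification ranking aggregated across targets) on the largest subset
    fully covered by the budget; passing a bare subset chain instead of a
    completed run yields the question list with no model recommendation.
    """
    subsets = result.subsets if isinstance(result, RunResult) else list(result)
    ordered: list[str] = []
    covered_tag = None
    chain = list(reversed(subsets))  # F_n, ..., F_0
    innermost = chain[0]
    if budget < len(innermost):
        raise ValueError(
            f"budget {budget} below the minimum feasible {len(innermost)} (|{innermost.tag}|)"
        )
    for s in chain:
        for item in s.items:
            if item not in ordered:
                ordered.append(item)
    ordered = ordered[:budget]
    answered = set(ordered)
    for s in chain:
        if set(s.items) <= answered:
            covered_tag = s.tag
    if not isinstance(result, RunResult):
        return ordered, None
    table = result.overall[("classification", "methods_per_subset")]
    column = covered_tag if covered_tag in table.columns else "avg"
    best_model = table[column].idxmin()
    return ordered, str(best_model)
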