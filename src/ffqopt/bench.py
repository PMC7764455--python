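"""Cross-validated benchmark of learners and imputation baselines.

For every (question subset, nutrient target) pair, eight classification and
eight regression learners — sklearn at default settings, no tuning — are
trained on standardized answers to the subset's questions against ground
truth computed from the full questionnaire (quality scores for
classification, gram amounts for regression).  The two statistical
baselines instead complete the test fold's unanswered questions (zero or
chained-equations imputation fitted on the training fold) and run the
deterministic scoring pipeline.  One shared fold plan is used for every
model, subset and target so comparisons are fair; fold-level metric values
are recorded in a tidy table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    BaggingClassifier,
    BaggingRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
    VotingClassifier,
    VotingRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import (
    mean_absolute_error,
    mean_squared_error,
    precision_recall_fscore_support,
    r2_score,
)
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from . import scoring
from .questionnaire import QuestionnaireDef, standardize
from .reduction import FeatureSubset

__all__ = [
    "ModelSpec",
    "FoldPlan",
    "ZERO_BASELINE",
    "MICE_BASELINE",
    "default_roster",
    "make_folds",
    "classification_metrics",
    "regression_metrics",
    "run_benchmark",
]

ZERO_BASELINE = "Zero imputation"
MICE_BASELINE = "Multiple imputation"
BASELINES = (ZERO_BASELINE, MICE_BASELINE)


@dataclass(frozen=True)
class ModelSpec:
    """A benchmark entry: label, task, and an estimator factory (None for
    the two statistical baselines, which are not fitted learners)."""

    id: str
    task: str  # "classification" | "regression"
    factory: Callable | None


def _classifier_factories(seed: int) -> dict[str, Callable]:
    return {
        "Logistic/Linear Regression": lambda: LogisticRegression(random_state=seed),
        "K-Nearest Neighbors": lambda: KNeighborsClassifier(),
        "Decision Tree": lambda: DecisionTreeClassifier(random_state=seed),
        "SVM": lambda: SVC(random_state=seed),
        "Bagging": lambda: BaggingClassifier(random_state=seed),
        "Gradient Boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "Random Forest": lambda: RandomForestClassifier(random_state=seed),
    }


def _regressor_factories(seed: int) -> dict[str, Callable]:
    return {
        "Logistic/Linear Regression": lambda: LinearRegression(),
        "K-Nearest Neighbors": lambda: KNeighborsRegressor(),
        "Decision Tree": lambda: DecisionTreeRegressor(random_state=seed),
        "SVM": lambda: SVR(),
        "Bagging": lambda: BaggingRegressor(random_state=seed),
        "Gradient Boosting": lambda: GradientBoostingRegressor(random_state=seed),
        "Random Forest": lambda: RandomForestRegressor(random_state=seed),
    }


def default_roster(task: str, seed: int = 0, include_baselines: bool = True) -> list[ModelSpec]:
    """The 8-learner roster for *task* (the eighth, Voting, combines the
    other seven), optionally followed by the two baseline entries."""
    if task == "classification":
        base = _classifier_factories(seed)
        voting = lambda: VotingClassifier(  # noqa: E731
            estimators=[(k, f()) for k, f in _classifier_factories(seed).items()],
            voting="hard",
        )
    elif task == "regression":
        base = _regressor_factories(seed)
        voting = lambda: VotingRegressor(  # noqa: E731
            estimators=[(k, f()) for k, f in _regressor_factories(seed).items()]
        )
    else:
        raise ValueError(f"unknown task {task!r}")
    roster = [ModelSpec(id=k, task=task, factory=f) for k, f in base.items()]
    roster.append(ModelSpec(id="Voting", task=task, factory=voting))
    if include_baselines:
        roster.append(ModelSpec(id=ZERO_BASELINE, task=task, factory=None))
        roster.append(ModelSpec(id=MICE_BASELINE, task=task, factory=None))
    return roster


@dataclass(frozen=True)
class FoldPlan:
    """A k-fold partition of respondents, shared across all benchmark cells."""

    k: int
    seed: int
    assignments: np.ndarray  # fold index per respondent position

    def splits(self):
        for fold in range(self.k):
            test = np.flatnonzero(self.assignments == fold)
            train = np.flatnonzero(self.assignments != fold)
            yield fold, train, test


def make_folds(n: int, k: int = 5, seed: int = 0) -> FoldPlan:
    """Balanced shuffled k-fold plan: fold sizes differ by at most one and
    the assignment is deterministic under a fixed seed."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} respondents into {k} folds")
    assignments = np.empty(n, dtype=int)
    for fold, (_, test) in enumerate(KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n))):
        assignments[test] = fold
    return FoldPlan(k=k, seed=seed, assignments=assignments)


def classification_metrics(
    pred: Sequence[int], truth: Sequence[int], average: str = "weighted"
) -> dict[str, float]:
    """Precision, recall and F1 of predicted vs true score classes.

    Multi-class values are support-weighted averages of per-class scores
    (macro selectable); F1 is the harmonic mean per class before averaging.
    Classes absent from the predictions contribute 0 with a warning.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("prediction and truth vectors must be equal-length, non-empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f, _ = precision_recall_fscore_support(
            truth, pred, average=average, zero_division=0
        )
    return {"precision": float(p), "recall": float(r), "f1": float(f)}


def regression_metrics(pred: Sequence[float], truth: Sequence[float]) -> dict[str, float]:
    """MAE, MSE, RMSE (= sqrt of MSE) and R2 of predicted vs true amounts."""
    pred = np.asarray(pred, dtype="float64")
    truth = np.asarray(truth, dtype="float64")
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("need equal-length vectors of at least 2 values")
    if not (np.isfinite(pred).all() and np.isfinite(truth).all()):
        raise ValueError("metric inputs must be finite")
    mse = float(mean_squared_error(truth, pred))
    return {
        "MAE": float(mean_absolute_error(truth, pred)),
        "MSE": mse,
        "RMSE": float(np.sqrt(mse)),
        "R2": float(r2_score(truth, pred)),
    }


def _fit_predict(spec: ModelSpec, X_train, y_train, X_test):
    """Fit one learner and predict; degenerate single-class/constant training
    targets fall back to a constant prediction with a warning."""
    if spec.task == "classification" and len(np.unique(y_train)) < 2:
        warnings.warn(f"{spec.id}: single-class training fold, predicting constant")
        return np.full(len(X_test), y_train[0])
    try:
        est = spec.factory()
        est.fit(X_train, y_train)
        return est.predict(X_test)
    except Exception as exc:  # pragma: no cover - defensive, benchmark must not abort
        warnings.warn(f"{spec.id}: fit failed ({exc}), predicting training mean/mode")
        if spec.task == "regression":
            return np.full(len(X_test), float(np.mean(y_train)))
        vals, counts = np.unique(y_train, return_counts=True)
        return np.full(len(X_test), vals[np.argmax(counts)])


def run_benchmark(
    answers: pd.DataFrame,
    qdef: QuestionnaireDef,
    subsets: Sequence[FeatureSubset],
    targets: Sequence[str] | None = None,
    roster: Sequence[ModelSpec] | None = None,
    plan: FoldPlan | None = None,
    mice_spec: scoring.ImputationSpec | None = None,
    average: str = "weighted",
) -> pd.DataFrame:
    """Run the full cross-validated benchmark.

    Returns the tidy metric table with columns (model, subset, target, fold,
    measure, value, task).  Learners are fit per fold on the standardized
    kept columns of the training rows (scaler fitted on the training fold
    only) against full-questionnaire ground truth; baselines impute the test
    fold's dropped columns — zero, or MICE with conditional models fitted on
    the training fold — and score deterministically.
    """
    if answers.isna().any().any():
        raise ValueError("answers must be complete")
    if targets is None:
        targets = list(qdef.target_names)
    if plan is None:
        plan = make_folds(len(answers), 5, 0)
    if roster is None:
        roster = default_roster("classification", plan.seed) + default_roster(
            "regression", plan.seed
        )
    if mice_spec is None:
        mice_spec = scoring.ImputationSpec(seed=plan.seed)

    truth = scoring.compute_ground_truth(answers, qdef)
    amounts = truth.pivot(index="respondent", columns="target", values="amount").loc[answers.index]
    scores = truth.pivot(index="respondent", columns="target", values="score").loc[answers.index]

    learners = [m for m in roster if m.factory is not None]
    wants_zero = any(m.id == ZERO_BASELINE for m in roster)
    wants_mice = any(m.id == MICE_BASELINE for m in roster)
    baseline_tasks = {
        m.id: sorted({r.task for r in roster if r.id == m.id}) for m in roster if m.factory is None
    }

    records: list[dict] = []

    def emit(model: str, subset: str, target: str, fold: int, task: str, vals: dict):
        for measure, value in vals.items():
            records.append(
                {
                    "model": model,
                    "subset": subset,
                    "target": target,
                    "fold": fold,
                    "measure": measure,
                    "value": value,
                    "task": task,
                }
            )

    for fold, train_idx, test_idx in plan.splits():
        train_rows = answers.iloc[train_idx]
        test_rows = answers.iloc[test_idx]
        for subset in subsets:
            cols = list(subset.items)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                X_train, stats = standardize(train_rows[cols])
                X_test, _ = standardize(test_rows[cols], stats)
            X_train = X_train.to_numpy()
            X_test = X_test.to_numpy()

            baseline_preds: dict[str, pd.DataFrame] = {}
            if wants_zero:
                completed = scoring.zero_impute(test_rows, subset)
                baseline_preds[ZERO_BASELINE] = scoring.compute_ground_truth(completed, qdef)
            if wants_mice:
                dropped = [c for c in answers.columns if c not in subset.items]
                if not dropped:  # nothing to impute: predictions are the truth
                    baseline_preds[MICE_BASELINE] = scoring.compute_ground_truth(test_rows, qdef)
                else:
                    masked = test_rows.copy()
                    masked[dropped] = pd.NA
                    imputed = scoring.mice_impute(
                        masked.astype("Int64"),
                        subset,
                        mice_spec,
                        train=train_rows,
                        n_levels=qdef.scale.n_levels,
                    )
                    baseline_preds[MICE_BASELINE] = scoring.pool_amounts(imputed, qdef)

            for target in targets:
                y_score_tr = scores[target].iloc[train_idx].to_numpy()
                y_score_te = scores[target].iloc[test_idx].to_numpy()
                y_amt_tr = amounts[target].iloc[train_idx].to_numpy()
                y_amt_te = amounts[target].iloc[test_idx].to_numpy()

                for spec in learners:
                    if spec.task == "classification":
                        pred = _fit_predict(spec, X_train, y_score_tr, X_test)
                        emit(spec.id, subset.tag, target, fold, spec.task,
                             classification_metrics(pred, y_score_te, average))
                    else:
                        pred = _fit_predict(spec, X_train, y_amt_tr, X_test)
                        emit(spec.id, subset.tag, target, fold, spec.task,
                             regression_metrics(pred, y_amt_te))

                for bid, table in baseline_preds.items():
                    cell = table[table["target"] == target].set_index("respondent").loc[
                        test_rows.index
                    ]
                    if "classification" in baseline_tasks.get(bid, []):
                        emit(bid, subset.tag, target, fold, "classification",
                             classification_metrics(cell["score"].to_numpy(), y_score_te, average))
                    if "regression" in baseline_tasks.get(bid, []):
                        emit(bid, subset.tag, target, fold, "regression",
                             regression_metrics(cell["amount"].to_numpy(), y_amt_te))

    return pd.DataFrame.from_records(records)
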