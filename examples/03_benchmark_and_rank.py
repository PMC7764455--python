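"""Benchmark learners against the imputation baselines and rank them.

Runs a scaled-down experiment on a synthetic cohort: three learners plus
the zero-imputation and chained-equations baselines, evaluated on three
nested question subsets under shared 5-fold cross-validation, then ranked
per subset with the PROMETHEE scheme (classification measures: precision,
recall, F1).  Rank 1 is best; tied alternatives share fractional ranks.
"""

from ffqopt.pipeline import RunConfig, run_experiment
from ffqopt.synthetic import SyntheticConfig

items = tuple(f"q{i}" for i in range(10))
config = RunConfig(
    thresholds=(0.4, 0.3),
    synthetic=SyntheticConfig(
        n_respondents=200,
        items=items,
        planted_pairs=(("q0", "q1", 0.9), ("q2", "q3", 0.9)),
        target_items={"nutrient": items[:6]},
        seed=0,
    ),
    models=(
        "Logistic/Linear Regression", "Random Forest", "Gradient Boosting",
        "Zero imputation", "Multiple imputation",
    ),
    seed=7,
)

result = run_experiment(config)
table = result.rank_tables[("nutrient", "classification", "methods_per_subset")]
print("method ranks per question subset (classification, rank 1 = best):")
print(table.round(1).to_string())
# On the full questionnaire F0 the baselines tie at rank 1.5 — with nothing
# to impute they ARE the ground truth.  On the reduced subsets the learners
# overtake them.
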