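"""Build nested question subsets by correlation thresholding.

Generates a synthetic cohort with three planted redundant question pairs
(latent r = 0.9), computes the Pearson matrix of the standardized answers,
and applies a decreasing threshold ladder.  Exactly one member of each
planted pair should disappear; the audit trail shows which and why.
"""

from ffqopt import build_subsets, pearson_matrix, standardize
from ffqopt.synthetic import SyntheticConfig, generate_cohort

config = SyntheticConfig(
    n_respondents=2000,
    planted_pairs=(
        ("fruit", "juice", 0.9),
        ("salad", "vegetables", 0.9),
        ("cheese", "cream", 0.9),
    ),
    target_items={"vegetable": ("salad", "vegetables")},
    seed=42,
)
truth = generate_cohort(config)

features, _ = standardize(truth.answers)
corr = pearson_matrix(features)
subsets = build_subsets(corr, thresholds=[0.4, 0.3])

for s in subsets:
    th = f"|r| > {s.threshold}" if s.threshold else "full questionnaire"
    print(f"{s.tag}: {len(s)} questions ({th})")
    for kept, removed, r in s.removed:
        print(f"   dropped {removed!r} (r = {r:.3f} with kept {kept!r})")
# Each planted pair loses its later member; uncorrelated questions survive.
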