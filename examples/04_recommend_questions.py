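"""Recommend which questions to ask under a budget.

Uses the published nested subset chain of the ESFFFQ: questions are asked
innermost-subset first (F5, then what F4 adds, and so on), so any prefix of
the order covers the largest possible validated subset.
"""

from ffqopt.datasets import esfffq_subsets
from ffqopt.pipeline import recommend_questions

subsets = esfffq_subsets()
for budget in (2, 6, 10):
    questions, _ = recommend_questions(subsets, budget)
    print(f"budget {budget:>2}: ask {', '.join(questions)}")
# budget 6 reproduces the published 6-question subset: the respondent's
# answers then cover F4 exactly, and any model validated on F4 applies.
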