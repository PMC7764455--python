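"""Score a single respondent's vegetable intake from frequency answers.

Loads the bundled 27-item ESFFFQ, sums the per-item gram contributions for
one respondent's answers, and maps the daily amount onto the 1/2/3
diet-quality score.
"""

from ffqopt import amount_to_score, compute_amount
from ffqopt.datasets import esfffq

qdef = esfffq()
veg = qdef.target("vegetable")

answers = {"salad": "1–2 times a day", "vegetables": "4–6 times a week"}
row = {item: qdef.scale.code_of(label) for item, label in answers.items()}

amount = compute_amount(row, veg)
score = amount_to_score(amount, veg.cutoffs)

print(f"answers: {answers}")
print(f"vegetable intake: {amount:.1f} g/day")
print(f"diet-quality score: {score} (1 = bad, 2 = medium, 3 = good)")
# 176.8 g/day falls between the 80 g and 240 g cutoffs, hence the medium score.
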