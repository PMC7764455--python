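# Extended Short Form Food Frequency Questionnaire (ESFFFQ).
#
# 27 non-quantitative items answered on an 8-level consumption-frequency
# scale.  The 19 tags that appear in the published correlation-subset table
# are reproduced verbatim; the remaining 8 tags were reconstructed from the
# instrument's stated food groups and are listed under `reconstructed_items`
# so users can tell printed tags from re-derived ones.
#
# Only the vegetable target's amount table and cutoffs are published; the
# other targets' tables are user-supplied (see `ffqopt.synthetic` for
# generated stand-ins).
name: ESFFFQ
scale:
  - rarely or never
  - less than once a week
  - once a week
  - 2–3 times a week
  - 4–6 times a week
  - 1–2 times a day
  - 3–4 times a day
  - 5+ a day
items:
  - fruit
  - juice
  - salad
  - vegetables
  - chips
  - beans
  - fiber
  - wholebread
  - cheese
  - cakes
  - cream
  - grains
  - pizza
  - nuts_salt
  - nuts
  - potato
  - readmeat
  - whitemeat
  - fish
  - oilyfish
  - milk
  - eggs
  - processedmeat
  - sugarydrinks
  - sweets
  - butter
  - friedfood
reconstructed_items:
  - oilyfish
  - milk
  - eggs
  - processedmeat
  - sugarydrinks
  - sweets
  - butter
  - friedfood
targets:
  vegetable:
    direction: higher_better
    amounts:
      salad: [0.0, 4.0, 11.2, 28.8, 56.8, 120.0, 280.0, 480.0]
      vegetables: [0.0, 4.0, 11.2, 28.8, 56.8, 120.0, 280.0, 480.0]
    cutoffs: [80.0, 240.0]
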