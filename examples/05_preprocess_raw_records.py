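"""Preprocess raw antenatal weight records into an analysis-ready cohort.

Builds a small raw-records table by hand (the long format a registry export
would produce), then runs the full preprocessing chain: weight-gain
computation, late/delivery deduplication, the implausibility filter
(gains over 30 kg or under -10 kg are removed), covariate banding, and the
eligibility rule (live birth, known gestational age, >= 3 valid measures).
"""

import pandas as pd

import gwgcharts as g

rows = []
def woman(wid, live, prepreg_w, height_cm, age, parity, smoking, disease, visits):
    for label, ga, weight in visits:
        rows.append(dict(woman_id=wid, live_birth=live, ga_known=1,
                         prepreg_weight_kg=prepreg_w, prepreg_height_cm=height_cm,
                         age_years=age, parity=parity, smoking=smoking,
                         previous_disease=disease, visit_label=label,
                         ga_weeks=ga, weight_kg=weight))

woman(1, 1, 50.0, 158.0, 29, "primipara", "never", "no",
      [("early", 10.2, 50.8), ("mid", 22.5, 54.6), ("late", 33.0, 58.1),
       ("delivery", 39.1, 61.3)])
woman(2, 1, 47.0, 152.0, 24, "multipara", None, "no",     # identical late/delivery
      [("early", 11.0, 48.0), ("mid", 24.0, 52.0), ("late", 38.5, 57.5),
       ("delivery", 38.5, 57.5)])
woman(3, 1, 65.0, 160.0, 36, "multipara", "during", "yes",  # implausible spike
      [("early", 9.5, 66.0), ("mid", 23.0, 69.0), ("late", 32.0, 110.0)])
woman(4, 0, 55.0, 165.0, 31, "primipara", "never", "no",   # stillbirth
      [("early", 10.0, 55.5), ("mid", 22.0, 58.0), ("delivery", 38.0, 64.0)])

cohort, tally = g.preprocess_raw(pd.DataFrame(rows))
print("Eligible cohort rows:")
print(cohort.to_string(index=False))
print("\nExclusion tally:", tally)
print("\nWoman 2's duplicate late-pregnancy row was collapsed into the "
      "delivery row; woman 3 lost her +45 kg spike and then failed the "
      ">= 3-measures rule; woman 4 was excluded as a stillbirth. "
      "Missing smoking answers become an explicit 'missing' level.")
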