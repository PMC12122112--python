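# Default laryngomalacia score table and algorithm thresholds.
# Items are data, not code: point values are ordinal severity levels
# (0 = normal .. 3 = most severe); each part score is the plain sum.
version: 1
score_table:
  history:
    inspiratory_sound:
      points: [0, 1, 2]
      labels:
        0: Intermittent
        1: Persistent, mild (not associated with sucked-in chest skin)
        2: Persistent, severe (associated with sucked-in chest skin)
    cyanotic_spells:
      points: [0, 3]
      labels:
        0: Never
        3: Present
    interrupted_sleep:
      points: [0, 1, 2]
      labels:
        0: Never
        1: Infrequent (not in every sleep)
        2: Frequent (persistent in every sleep)
    growth:
      points: [0, 1, 2]
      labels:
        0: Growing well
        1: Growing less than ideally
        2: Losing weight
    choking:
      points: [0, 1, 2]
      labels:
        0: Never
        1: Infrequent (not in every feeding)
        2: Frequent (persistent in every feeding)
    regurgitation:
      points: [0, 1, 2]
      labels:
        0: Never
        1: Infrequent (not in every feeding)
        2: Frequent (persistent in every feeding)
    icu_admission:
      points: [0, 1, 2]
      labels:
        0: Never
        1: Once
        2: More than once
  exam:
    growth_chart:
      points: [0, 1, 2]
      labels:
        0: Normal (weight-for-length Z in [-2, +2])
        1: Moderate delay (Z in [-3, -2))
        2: Marked delay (Z below -3)
    chest_retractions:
      points: [0, 1, 2, 3]
      labels:
        0: Absent
        1: Suprasternal
        2: Intercostal or subcostal
        3: Pectus excavatum
    collapse_degree:
      points: [0, 1, 2]
      labels:
        0: 25-50% of vocal cords obscured
        1: 75% of vocal cords obscured
        2: 100% of vocal cords obscured
    swallowing_fees:
      points: [0, 1, 2]
      labels:
        0: Normal
        1: Penetration
        2: Aspiration
    developmental:
      points: [0, 1, 2]
      labels:
        0: Normal (all GMDS-III domains in normal range)
        1: Mild impairment (one domain below normal)
        2: Global delay (two or more domains below normal)
    congenital_anomalies:
      points: [0, 1, 2]
      labels:
        0: None
        1: One
        2: More than one
  investigation:
    echo:
      points: [0, 1, 2, 3]
      labels:
        0: Normal
        1: Associated congenital cardiac anomaly
        2: Mild or moderate pulmonary hypertension
        3: Severe pulmonary hypertension or right-sided heart failure
    overnight_oximetry:
      points: [0, 1, 2, 3]
      labels:
        0: No nocturnal desaturation
        1: "O2 desaturation nadir 86-91%"
        2: "O2 desaturation nadir 76-85%"
        3: "O2 desaturation nadir < 75%"
    synchronous_airway_lesion:
      points: [0, 1, 2]
      labels:
        0: No other lesions
        1: One lesion
        2: More than one lesion
    gerd:
      points: [0, 1, 2]
      labels:
        0: Normal (PAS 1 / RI < 3%)
        1: Penetration (PAS 2-5 / RI 3-7%)
        2: Aspiration (PAS 6-8 / RI > 7%)
thresholds:
  # history score -> grade
  grade_bands:
    mild: [0, 3]
    moderate: [4, 9]
    severe: [10, 15]
  # exam score routing for moderate-grade patients
  exam_bands:
    conservative: [0, 3]
    stage3: [4, 9]
    surgery: [10, 13]
  # investigation score routing for stage-3 patients
  investigation_watchful_max: 5
follow_up:
  horizon_months: 6
  mild_monthly_visits: 3
advisories:
  acid_suppression: >-
    GERD management follows a step-up/step-down acid-suppression regimen
    (PPI and/or H2RA, e.g. omeprazole 1 mg/kg/day) maintained for at least
    3 months; weaning is not advised until safe feeding is well tolerated.
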