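# lmscore

Numerical severity scoring and stepwise management triage for infant
laryngomalacia, with a constrained synthetic-cohort generator.

Laryngomalacia — dynamic collapse of the supraglottic structures causing
inspiratory stridor — is the most common congenital laryngeal condition.
Most infants are managed conservatively, but deciding *which* patients
need supraglottoplasty has traditionally rested on qualitative grades.
`lmscore` implements a three-part numerical severity score and the
staged decision algorithm built on it, for clinicians and methodologists
who want a reproducible, auditable mapping from clinical findings to a
management disposition.

## The score and the algorithm

Three ordinal checklists, each item worth 0–3 points (3 = most severe),
each part score the plain sum:

| Part | Items | Range |
|---|---|---|
| History & symptom score *H* | stridor, cyanotic spells, sleep, growth, choking, regurgitation, ICU admission | 0–15 |
| Examination score *E* | growth chart, chest retractions, degree of collapse, FEES swallowing, development, congenital anomalies | 0–13 |
| Investigation score *I* | echocardiography, overnight oximetry, synchronous airway lesions, GERD (MBS/pH) | 0–10 |

Management proceeds in three stages:

1. **Grade** from *H*: mild (*H* < 4) → conservative care with monthly
   review; moderate (4 ≤ *H* ≤ 9) → stage 2; severe (*H* > 9) →
   supraglottoplasty, with stages 2–3 recorded as preoperative baseline.
2. **Examination** routing for moderate patients: *E* < 4 conservative;
   *E* > 9 surgery; 4 ≤ *E* ≤ 9 → stage 3.
3. **Investigation** routing: *I* ≤ 5 watchful waiting; *I* > 5 surgery.

Raw measurements (weight-for-length Z score, fraction of the vocal cords
obscured, PAS 1–8, reflux index %, pulmonary pressure, oximetry nadir,
lesion counts, GMDS-III domains) are converted to item points by monotone
band mappers. Follow-up is an event-driven state machine: reassessments
re-grade from the new history score and the disposition only ever
ratchets upward within the 6-month horizon.

Because no patient-level dataset is public, the `synthetic` module
reconstructs cohorts from the published per-grade marginal tables: a
seeded constrained-assignment solver distributes each item's point
multiset over patients so the per-item counts match the marginals
*exactly* while every patient's part score stays in its grade band.

## Worked example

```sh
lmscore synth --mode replica --seed 7 --out cohort.csv
lmscore flow --in cohort.csv --paper-events
```

prints

```
Cohort flow (n = 112)

Stage 1 - history/symptom score:
  mild        44  (39.3% / 39.29%)
  moderate    48  (42.9% / 42.86%)
  severe      20  (17.9% / 17.86%)

Stage 2 - examination score applied to 68 patients
  moderate subgroups: <4 -> 13, 4-9 -> 22, >9 -> 13

Stage 3 - investigation score applied to 55 patients
  stage-3 moderate: <=5 -> 11, >5 -> 11

Final dispositions:
  conservative         57  (50.9%)
  watchful_waiting     10  (8.9%)
  supraglottoplasty    45  (40.2%)

Follow-up: 6 reassessed, 6 escalated a grade band
Tracheostomies: 4
Mild-at-baseline patients reaching surgery: 0
```

Reading the output: of 112 reconstructed patients, 44 grade mild and
stay conservative; all 68 moderate/severe patients receive the
examination score; 55 receive the investigation score (20 severe
preoperative baselines, 13 moderate with *E* > 9, 22 moderate in the
middle band). 45 patients end at supraglottoplasty — 44 at baseline plus
one watchful-waiting patient whose follow-up history score escalated to
the severe band. Four patients carry a tracheostomy annotation (one
postoperative airway compromise, three synchronous-airway-lesion
managements). The scripted follow-up events come from the packaged
`paper_events.csv` fixture.

The same things are available from Python:

```python
from lmscore import reconstruct_paper_cohort, run_cohort_flow
from lmscore.io import load_paper_events

cohort = reconstruct_paper_cohort(seed=7)
summary, traces = run_cohort_flow(cohort, load_paper_events())
print(summary.dispositions)   # {'conservative': 57, 'watchful_waiting': 10, 'supraglottoplasty': 45}
```

Other CLI verbs: `lmscore score` (one part score from item points),
`lmscore map` (one raw measurement to its point, e.g.
`--item o2_nadir --value 88` → `1`), `lmscore triage` (cohort CSV →
JSON-lines traces), `lmscore validate` (schema check plus exact
comparison against the packaged marginals).

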