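# Methods

## Score model

The severity instrument is three ordinal checklists whose part scores
are plain integer sums: history/symptoms (7 items, 0–15), examination
(6 items, 0–13), investigation (4 items, 0–10). Most items take points
{0, 1, 2}; cyanotic spells is all-or-nothing {0, 3}; chest retractions
and echocardiography run {0, 1, 2, 3}. The table is shipped as data
(`data/config.yaml`, versioned) rather than code, because band cut-offs
of a young clinical instrument are the part most likely to be refined.
A part score is undefined on incomplete data: the engine raises a
validation error naming the missing item rather than imputing, since a
missing finding is not a normal one.

The swallowing item of the examination score is the FEES outcome alone;
the instrumental GERD modalities (modified barium swallow, pH-metry)
contribute only to the investigation score. Exhaustive enumeration of
the valid item vectors (1458 history, 972 examination, 144
investigation) is provided as a brute-force oracle for the arithmetic
and the range claims.

## Raw-measurement mappers

Each mapper is a total, monotone step function of its severity axis.
Published band edges leave small gaps or overlaps; they are resolved by
closing each band on the milder side, which preserves every published
anchor while making the mapping gap-free:

| Measurement | 0 | 1 | 2 | 3 |
|---|---|---|---|---|
| weight-for-length Z | ≥ −2 | [−3, −2) | < −3 | — |
| vocal cords obscured | ≤ 50% | (50%, 100%) | 100% | — |
| O₂ nadir (%) | none or ≥ 92 | [86, 92) | (75, 86) | ≤ 75 |
| pulmonary pressure (mmHg) | < 25, no anomaly | < 25 with cardiac anomaly | [25, 45) | ≥ 45 or right-heart failure |
| PAS | 1 | 2–5 | 6–8 | — |
| reflux index (%) | < 3 | [3, 7] | > 7 | — |

Specific decisions: Z > +2 maps to 0 because the item measures growth
faltering only; "no nocturnal desaturation" is operationalised as a
nadir ≥ 92% (an event-count definition would need data the instrument
does not collect); the unclassified 75–76% oximetry sliver goes to the
worst band (≤ 75 → 3) so severity is never understated at a boundary;
when both GERD modalities were performed the worse point wins, because
pH-metry is invoked precisely to escalate refractory cases. Each
mapper's surjectivity onto its item's allowed points and its
monotonicity are property-tested.

## Triage engine

Grade bands (history < 4 / 4–9 / > 9), the stage-2 examination split
(< 4 / 4–9 / > 9) and the stage-3 watchful-waiting cut (investigation
≤ 5) act on integers with explicit inclusive sides, so no tie-breaking
is needed; completeness and monotonicity of the disposition in each
part score are verified exhaustively over all 16 × 14 × 11 composite
score triples. Severe-grade patients are surgical from stage 1; their
examination and investigation scores are recorded as a preoperative
baseline and can never alter the disposition (rule priority, not
arithmetic). The examination score is mandatory for any grade above
mild; the investigation score is mandatory exactly when the decision
depends on it (stage-3 routing) and is otherwise recorded as baseline
when supplied.

Follow-up is deterministic and event-driven — events come from input
files or the synthetic module, never from an internal stochastic
process — over a 6-month horizon with monthly review scheduled for mild
patients in the first three months. A reassessment re-grades from the
new history score and re-enters the algorithm at the corresponding
stage; a missing examination or investigation at a follow-up visit
carries the last recorded score forward with a warning. The disposition
is a ratchet (never decreases), matching the clinical asymmetry that a
surgical decision, once made, is not undone by a later quiet visit.
Every fired rule is recorded in an immutable trace; `replay_trace`
re-derives the disposition from the records as an audit.

## Synthetic cohorts

The published evidence about the cohort is (a) per-grade, per-item
point-count marginal tables for each score part, (b) the grade score
bands, and (c) subgroup sizes along the management flow (44/48/20
grades; moderate examination split 13/22/13; stage-3 investigation
split 11/11). The joint distribution across items is *not* identified
by these constraints.

**Replica mode** treats reconstruction as constrained assignment: for a
group of *n* patients, each item contributes a fixed multiset of point
values (the marginal column), and an assignment distributes every
multiset over the patients so each patient's part sum lies in its
required band. The solver validates marginal consistency (each item's
counts must sum to the group total), seeds a greedy initialisation
(values handed out largest-first to the patients furthest below their
band midpoint), then repairs violations by pairwise swaps within an
item (swaps preserve the marginals, so exactness holds by
construction), with sideways moves accepted with probability 0.25 to
escape plateaus, bounded iterations and up to 40 restarts before
raising an infeasibility error — never a silent relaxation. The
moderate investigation table (n = 35) is solved with quota bands
11 × [0, 5], 11 × [6, 10] and 13 unconstrained; the unconstrained
vectors attach to the examination > 9 subgroup, whose membership is
otherwise unpublished and therefore randomised within constraints.
An exhaustive depth-first oracle checks the solver's feasibility
verdicts on instances of up to ~6 patients. Sampling is uniform only
over assignments reachable by this heuristic, not over all feasible
joint tables — the replica is *a* cohort consistent with everything
published, not *the* cohort.

Patient ids are canonicalised after solving (mild by history score;
moderate by management subgroup; severe by synchronous-airway-lesion
point, descending), so the scripted-events fixture can reference ids
whose relevant attributes are guaranteed for every seed. The fixture
transcribes the narrative outcomes: five mild escalations into the
moderate band that remain conservative (examination < 4), one
watchful-waiting deterioration into the severe band (surgery), one
postoperative airway compromise, and three synchronous-airway-lesion
managements requiring tracheostomy (two patients with two lesions, one
with one). Morphology labels (type I/II/III/mixed = 21/61/6/24) are
shuffled independently of scores, and ages are drawn from a clipped
normal (mean 4.3, SD 2.2 months), as no dependence on severity is
published for either.

**Parametric mode** samples item points independently from per-grade
multinomials (defaulting to the published proportions) and
rejection-samples history vectors into the grade band, for cohorts of
arbitrary size. Both modes are deterministic given the seed.

What passing tests therefore show: the scoring arithmetic, thresholds,
flow counts and marginal structure are reproduced exactly. What they do
not show: anything about inter-item correlation, morphology–severity
association, or real-world score distributions beyond the published
margins — the generator has no information about those.

## Flow summary and rounding

`run_cohort_flow` triages the whole cohort, applies events in visit
order, and tallies the flow nodes (grades, stages applied, routing
subgroups, final dispositions, escalations, tracheostomies).
Percentages are emitted at both one- and two-decimal precision using
half-up rounding, since published figures mix both precisions. With
half-up rounding 20/112 is 17.86% at two decimals; a printed value of
17.85 for the same fraction is a truncation artifact, and this package
does not reproduce truncation.

## Problem sizes and numerical choices

The packaged cohort is 112 patients; reconstruction solves seven
assignment instances of at most 48 patients × 7 items and completes in
well under a second, with exhaustive routing checks covering all 2464
composite score triples. The solver's only tolerance is structural
(integer band membership; no floating-point comparisons). Degenerate
inputs fail loudly: empty cohorts produce all-zero summaries, empty
files a warning, inconsistent marginals and infeasible bands explicit
errors.

## Known limitations

- The replica cohort is one feasible joint table; analyses sensitive to
  inter-item correlation should not treat it as real data.
- The history score is caregiver-reported and inherently subjective;
  the package models the instrument, not its measurement error.
- Acid-suppression therapy is emitted as a fixed advisory string only;
  dosing, surgical technique and outcome prediction are out of scope.
- Borderline cases in practice involve clinical judgement beyond the
  numeric cut-offs; the engine is a decision *support*, encoding only
  the published thresholds.
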