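# Methods

`ffrisk` implements a risk-classification methodology for coronary-artery
patients built around the fractional flow reserve (FFR), designed for the
regime where only a small labeled cohort exists (on the order of 181
patients).  This note documents the models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical choices that pin down behaviour at the edges.

## 1. Data model and preprocessing

A cohort is a table of patients over a fixed schema: two binary
demographics (smoker, gender), twenty-ish numeric biomarkers (cardiac
enzymes, lipids, renal markers, inflammation markers), and three
descriptive-or-numeric lesion fields for the LAD, LCx and RCA coronary
arteries.  Two optional columns carry supervision: a numeric FFR in
[0, 1] and a binary risk class (0 = low, 1 = high on disk; the dangerous
class is the positive one).  Records without an FFR are kept — they still
inform imputation statistics.

### Lesion-text translation

Angiography reports describe narrowing in free text.  Translation applies
six rules in strict order (an explicit figure always wins over a
qualitative phrase):

1. a single explicit percentage → that value;
2. a percentage range → the arithmetic mean of its endpoints;
3. a "not substantial" narrowing → 10 %;
4. a "very minor" narrowing → 5 %;
5. an "orderly arterial lumen" → 0 %;
6. anything else → unresolved, later replaced by the column mean of the
   translated values.

An *empty* lesion cell is missing, not unresolved: it falls to the generic
imputer rather than the rule-6 column mean.  The phrase lists live in an
editable YAML lexicon (`ffrisk/data/lesion_lexicon.yaml`); since the
original reports were translated by hand, any lexicon is an emulation of
plausible clinical dialects and is labelled as such.

Lesion values are percentages in [0, 100] internally; the model-input
matrix rescales them to [0, 1] (a monotone transform that tree learners
are invariant to, kept for consistency with the fractional convention).

### Imputation

Missing numeric cells are filled with the column mean, missing binary
cells with the column mode (ties break toward the smaller value, a fixed
deterministic rule).  Statistics are computed over **all** records,
labeled or not.  The operation is idempotent and preserves present values
bit-exactly.  Chained-equation multiple imputation is deliberately out of
scope: with features this weakly correlated it underperforms the simple
column statistics.

### Risk transcription

FFR strictly above 0.8 is low risk.  The band [0.74, 0.8] is clinically
ambiguous (border class); it is merged into the high-risk class, closed at
both ends, because the costly error is falsely reassuring a high-risk
patient.  Both thresholds are configurable (`ClassificationThresholds`).

### Correlations

Feature–FFR association uses the Pearson product–moment coefficient
(point-biserial for binaries, the same formula), computed on the labeled
subset only.  A zero-variance feature yields NaN — undefined, deliberately
not 0.

## 2. Reduced-order hemodynamics

FFR is the ratio of maximal stenosed to maximal normal flow; with a shared
microvascular resistance it reduces to the pressure ratio
(p_d − p_v)/(p_a − p_v) ≈ p_d/p_a.  The resistance R cancels and is never
given a numeric value.

The distal pressure comes from an excess-Poiseuille model: the pressure
drop of the stenotic segment minus that of the same segment at reference
radius,

    ΔP_excess = (8 μ L Q / π) (1/r_s⁴ − 1/r₀⁴),  r_s = r₀ (1 − f),

with f the fractional **diameter** reduction (clinical percent-stenosis
usage).  This replaces a full 3-D finite-element Navier–Stokes simulation;
it is a deliberate fidelity reduction that preserves exactly the
properties downstream consumers rely on: FFR = 1 bit-exactly at zero
stenosis (the excess drop vanishes by construction), strict monotone decay
in stenosis severity and in flow, and the r⁻⁴ radius scaling.  Defaults:
μ = 0.00365 Pa·s, ρ = 1050 kg/m³, inlet pressure 100 mmHg, flow 3 mL/s
(adenosine hyperemia; 1 mL/s for rest), reference radius 1.5 mm, stenosis
length 10 mm, venous pressure 0.  Pressures are mmHg, flows mL/s, geometry
m; conversions are centralized (1 mmHg = 133.322 Pa).  For extreme
stenoses p_d is clamped at the venous pressure rather than erroring, so
derived FFR saturates at 0 (for the default geometry this happens near
75 % narrowing); the stenting criterion is FFR ≤ 0.75.  The closed-form
inverse (`stenosis_for_ffr`) maps a target FFR back to the stenosis
fraction; it is exact to machine precision and is what the synthetic
generator uses.

## 3. The group-split ensemble

With 181 labeled patients no comprehensive test set exists.  The strategy:

- Partition the labeled set into 20 groups (19×9 + 1×10 at n = 181), each
  containing both classes.  Construction: shuffle each class independently
  with the seed, deal minority class first in one continuing round-robin —
  this guarantees class coverage whenever each class has at least as many
  members as groups, and group sizes differing by at most one.
- Enumerate every train/test assignment holding out 1, 2, 3 or 4 groups:
  C(20,1) + C(20,2) + C(20,3) + C(20,4) = 6195 configurations, ordered
  lexicographically by held-out ids.
- Train one base model per configuration: a 50-tree random forest with no
  minimum-sample constraints (an established bagged-tree implementation is
  used; bootstrap sampling, impurity feature importances normalized per
  model).  Per-model seeds derive deterministically from (master seed,
  configuration index), so builds are reproducible yet models differ.
- Retain a model iff its held-out accuracy clears the size-dependent
  threshold: 66 % for one held-out group, 75 % for two or three, 80 % for
  four.  The comparison is **inclusive** (≥): on a 9-sample group 6
  correct (66.7 %) is the smallest retained score, and on the 10-sample
  group 7 correct are required; a model hitting exactly 80 % on four
  groups is kept.  Exclusive comparison is available as a flag.
- The final classifier is a plurality vote over all retained models.
  Ties resolve to high risk, consistent with the asymmetric cost of
  missing a high-risk patient; the tie-break is configurable.

An empty retained set is an explicit failure state
(`EmptyEnsembleError`) carrying per-size diagnostics, not a silent empty
model.  The retained count is data-dependent by design; only containment
in the enumerated candidate set is a portable invariant.

## 4. Evaluation

*Simulated accuracy* is the unweighted mean of the retained models'
held-out accuracies — an estimate of the average quality of the
ensemble's parts, not a held-out accuracy of the voting classifier (no
data remain to measure that).  Per-held-out-size means break it down by
split ratio; their count-weighted mean equals the overall value by
algebraic identity (asserted to 1e-12).  Feature importance is the
per-feature unweighted mean of the members' normalized
mean-decrease-in-impurity importances, so the aggregate sums to one and is
invariant to member order; a lesion-feature aggregate (mean over LAD, LCx,
RCA) is reported alongside the per-artery values.  The high-risk F1 is
provided but returns *undefined* (None), never 0, when the truth contains
no high-risk sample — with test sets of nine patients this happens often
enough to spoil any F1-based aggregate, which is why accuracy is the
primary metric.

## 5. The synthetic cohort generator

No public cohort exists (patient privacy), so the generator emulates the
*structure* of the study data and is itself first-class, tested code.
Defaults are the study conditions: 276 patients, 181 labeled, 58/181 high
risk (exact counts within rounding), biomarkers inside the published
ranges, free-text lesion cells covering all six translation rules, and a
3 % missing-cell rate with half of lesion cells rendered as text.

Generation is physics-first.  Each patient gets a class (to hit the
target imbalance exactly), then a class-conditional FFR drawn uniformly
from [0.55, 0.795] (high) or [0.81, 0.98] (low) — bands that stop short of
the 0.8 boundary by more than the combined rounding and noise drift
(< 0.005), so physics, label and count stay mutually consistent.  The
worst-lesion stenosis is obtained by inverting the reduced-order model at
that FFR (rounded to 0.1 %), the FFR is recomputed forward through the
physics plus bounded noise (±0.002), and the label is assigned from the
final FFR.  The worst lesion lands on the LAD half the time (echoing its
dominant association in the study); other arteries draw milder values,
snapped onto the {0, 5, 10} % grid below 12.5 % so the qualitative
translation rules occur naturally.

Biomarkers are uniform within their schema ranges (log-uniform when the
range spans more than a factor of 20, e.g. pBNP and CK), mixed with an
FFR-linked component whose sign follows the published correlation table
and whose weight is `signal_strength × |ρ|` (capped at 0.95).  The
published table prints HDL twice and omits LDH; the −0.33 row is read
here as LDH.  Binary features draw from a Bernoulli whose rate shifts
linearly with the FFR rank.

`signal_strength` is the informativeness dial: it scales the biomarker
shifts *and* sets the fraction of patients whose lesions are physically
coupled to their FFR.  At 0 every feature — lesions included — is drawn
independently of FFR, giving the null cohort used to verify the pipeline
does not manufacture signal; at ≥ 1 the generator follows the full
physics chain.  An optional `label_flip_rate` moves that fraction of
labeled patients' FFR just across the 0.8 boundary (features keep their
original class's structure), emulating borderline label ambiguity; its
default is 0.

What the generator does **not** emulate: the real joint distribution of
biomarkers (only ranges and association signs), the real missingness
mechanism (cells blank uniformly at random here), the real lesion-text
dialects (the lexicon is invented), or correlated comorbidity structure.
Passing tests therefore show the pipeline recovers signal of the kind it
assumes, not that the real cohort's accuracy is reproduced — the study's
headline numbers depend on private data and are not reproduction targets.

## 6. Problem sizes used in the test suite

The acceptance-grade checks run at full methodological scale where that is
what is being checked: the filter-containment test builds all 6195
configurations with 50-tree forests at n = 181 (about six minutes on one
CPU).  The stochastic signal-recovery check runs the full pipeline over
20 seeds per arm with 10-tree forests and held-out sizes {1, 2}
(210 configurations per build) — the reduced base-learner and enumeration
sizes keep 40 complete pipeline runs affordable while exercising every
stage.  The zero-signal arm's tolerance band (±0.08 around the
majority-class baseline, and never more than +0.02 above it) comes from a
vote-imbalance argument: with no signal the ensemble's accuracy is
q·b + (1−q)(1−b) for test low-fraction b and low-vote fraction q, and
plurality voting over many retained models drives q toward 1, leaving
only a bounded downward residual.  Unit tests use cohorts of 40–120
patients with 4–8 groups.

## 7. Known limitations

- The reduced-order pressure model ignores pulsatility, entrance/exit
  (Bernoulli) losses, vessel taper and microvascular adaptation; absolute
  FFR values are indicative, only the monotone structure is load-bearing.
- The six translation rules cover the dialects in the lexicon; genuinely
  novel phrasings fall to rule 6 and receive the column mean.
- With very small cohorts the class-coverage requirement (each class at
  least as large as the group count) can be unsatisfiable; the partition
  fails loudly rather than degrading.
- Simulated accuracy is upward-biased relative to a true held-out
  accuracy of the voting ensemble, because retention conditions on
  held-out performance; it should be read as the study defines it.
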