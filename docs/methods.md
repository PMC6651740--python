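# Methods

## The problem

Cardiorespiratory endurance — the capacity of the heart and lungs to supply
oxygen during sustained effort — is measured in the laboratory as VO₂max, which
is impractical outside one. Two resting/recovery heart-rate quantities are
cheap proxies: the resting heart rate (RHR, bpm; lower is fitter) and the heart
rate recovery (HRR, bpm; the drop in heart rate within two minutes of stopping
exercise; larger is fitter). `cardiofuzz` implements two Mamdani fuzzy
inference systems over these quantities:

* a **treadmill-speed recommender**: RHR and the planned exercise time (min)
  in, a training speed in km/h out;
* an **endurance evaluator**: RHR and HRR in, a 0–100 endurance score with a
  linguistic level (Please Strengthen / Medium / Good / Excellent / Special
  Excellent) out;

together with the scalar physiology layer (age-predicted maximal heart rate
208 − 0.7·age, the VO₂ polynomial 0.002·HR² − 0.13·HR + 2.3, reference lookup
tables) and a pre/post training-study pipeline with its packaged 25-subject
cohort.

## Inference model

Both systems are classical Mamdani controllers with crisp (singleton) inputs:

1. **Fuzzification.** Each input variable is partitioned into labelled terms
   with trapezoid/triangle membership functions (four knots a ≤ b ≤ c ≤ d).
   Readings outside a variable's universe are clamped to it, which together
   with the shoulder plateaus makes extreme readings behave like the worst/best
   modelled value instead of failing.
2. **Rule firing.** Each rule is `IF x is A AND y is B THEN z is C`; AND = min.
   The rule grids are complete (7 RHR terms × 5 time/recovery terms = 35
   rules per system) and identical to the crisp reference matrices, which the
   test suite asserts.
3. **Aggregation.** Min implication (each rule clips its consequent set at the
   firing level) and max aggregation across rules — the max–min composition.
4. **Defuzzification.** Discrete centre of gravity
   y* = Σ μ(yᵢ)·yᵢ / Σ μ(yᵢ) over `cog_samples` evenly spaced points spanning
   the output universe, endpoints included. An all-zero envelope raises
   `NoRuleFiredError`; it is never silently 0.

Rule weights, OR antecedents, fuzzy-set inputs, Gaussian memberships and
defuzzifiers other than COG are deliberately out of scope.

## Membership reconstruction

The source system documentation gives each term's *support* (e.g. RHR "Below
Average" = 75–85 bpm) but not its apex coordinates. The package uses one fixed
reconstruction convention:

* interior terms are triangles with the apex at the support midpoint;
* the two extreme terms of each variable are shoulder trapezoids whose sloped
  edge spans the intersection of their support with the neighbouring term's
  support, and whose unit plateau extends to the universe bound.

Universes: RHR [50, 90] bpm, Time [10, 70] min, speed [0, 12] km/h, HRR
[20, 70] bpm, endurance score [0, 100]. This makes adjacent terms cross at
membership 0.5 and gives a partition of unity (term memberships sum to 1) at
every point — with one exception. The printed HRR supports are asymmetric at
the top end: Slightly Young spans 47–65 while Young spans 55–70, so Young's
rising edge (55→65) overlaps Slightly Young's apex. On HRR ∈ [55, 65] the term
sum rises to a maximum of 1.1 (at 56 bpm) before returning to 1, and on
[55, 56] three consecutive terms are briefly active. The reconstruction honours
the printed supports rather than forcing symmetry; the tests encode exactly
this band.

## Numerical choices

* **COG resolution**: `cog_samples = 1201` by default (configurable,
  minimum 101), i.e. steps of 0.01 km/h on the speed universe and ≤ 0.085 on
  the others; the tests check agreement with a 100×-finer grid to within half
  a default step and with closed-form centroids of single clipped terms
  (continuous quadrature oracle).
* **Label assignment**: the endurance label is the output term with maximal
  membership at the defuzzified score; an exact tie at a 0.5 crossover resolves
  to the higher (better) category, so the deterministic wording shown to a
  user is the favourable one.
* **Monotonicity**: the recommended speed trends downward in RHR and in time,
  and the endurance score upward in HRR and downward in RHR — but not strictly.
  Where both active input terms conclude the same extreme consequent (the grid
  flanks), only the clip level varies and the centroid of a single clipped
  shoulder drifts slightly against the trend. The drift is bounded by about
  0.21 km/h (speed) and 2.6 points (score) over any sweep; this is an intrinsic
  property of max–min inference with COG, and the tests assert monotone
  behaviour up to these bounds (0.25 km/h / 3.0 points) plus a strict overall
  trend across each full sweep.

## Study pipeline conventions

The packaged cohort is the 25-subject, 8-week treadmill study: 13 "control"
subjects trained exactly as the recommender prescribed, 12 "reference" subjects
combined the recommendation with their own judgement (the pipeline keeps these
group labels verbatim). Per subject,

    DRHR = (pre RHR − post RHR) / pre RHR × 100   (decrease rate of RHR)
    GHRR = (post HRR − pre HRR) / pre HRR × 100   (growth rate of HRR)

rounded half away from zero to integer percent; the unrounded values are also
exposed. Conventions, each validated against all printed values by the suite:

* standard deviations are **population** form (÷ n) — the only convention that
  reproduces all eight printed group STDs at one decimal;
* displayed means are rounded (half away from zero) to one decimal and the
  mean pre/post difference is the difference of the rounded means;
* a group's average improvement is the rounded mean of the per-subject rounded
  percentages (this reproduces the printed 23% and 80% HRR improvements, which
  a ratio-of-means convention does not), and the overall improvement is the
  unweighted mean of the two group values;
* the RHR categories split at pre-test RHR ≥ 80, [70, 80) and < 70 bpm;
* the source table's pre/post difference-STD column is of unclear provenance
  and is **not** reproduced; the report instead computes the population STD of
  the per-subject paired differences under the explicit name
  `paired_diff_std`.

Per-subject endurance scores in reports are computed from the post-test
readings. The per-subject endurance letters printed in the source category
tables are not asserted: they are not reproducible from any obvious pairing of
the tabulated readings, and which readings fed the original evaluator is not
recorded.

## Synthetic cohorts

`CohortModel.from_study()` builds the default generative model from the
packaged table at run time: per group, pre-test RHR and HRR are truncated
normals with the group's mean and population SD, and training effects (RHR
decrease, HRR increase) are normal draws with the mean and population SD of the
group's paired differences, applied per subject and clipped into the plausible
ranges (RHR [40, 120] bpm; HRR [5, 90] bpm — a recovery delta lives well below
an absolute heart rate, and a positive floor keeps the GHRR denominator
valid). Mean and SD are the only distributional facts the study reports, which
is why a truncated normal is the model; a seed fully determines the draw.

What the generator does *not* emulate: integer-valued readings, correlation
between a subject's pre value and effect size (the real data show larger HRR
gains for less fit subjects), week-by-week dynamics, and drop-out. Passing the
parameter-recovery tests therefore shows the pipeline estimates group effects
correctly from data matching its assumptions, not that the study's effects
would replicate.

## Problem sizes

Everything is printed-data scale: the cohort pipeline runs on 25 subjects;
property sweeps use 401–801 grid points per variable; synthetic parameter
recovery uses 1000 subjects per group (standard error ≈ 0.1 bpm, tested at
3 SE with a 0.1 rounding allowance). The full suite runs in a few seconds.

## Known limitations

* The membership apexes are a reconstruction convention (midpoints), not a
  recorded fact; defuzzified values inherit that uncertainty (the worked
  example yields 4.60 km/h where the original app displayed 4 km/h), so the
  tests assert tolerance bands, not exact fuzzy outputs.
* The engine supports exactly two inputs and one output — what these systems
  need, nothing more.
* No inferential statistics: the study pipeline reproduces descriptive
  summaries only, and the source study reports none either.
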