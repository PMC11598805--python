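# Methods

This note documents the models, numerical choices, and limitations of
`metalret` in the package's own terms: what is computed, under which
assumptions, and what the synthetic-cohort tests do and do not establish.

## The retention statistic

Retention of a metal M is defined from renal clearance.  Clearance
(mL/min) follows the Reberg formula,

    CL_M = (c_M^urine · DM) / (c_M^blood · 1440 · BS),

with urine/blood concentrations in µg/mL, daily diuresis DM in mL, 1440
the minutes per day, and BS a body-surface correction.  Retention is the
Gaussian-kernel transform

    Retention_M = exp(−CL_M² / 2σ²)  ∈ (0;1],

with σ the standard deviation of the cohort's clearance series (population
n-denominator by default; the sample n−1 variant is selectable).  The
statistic is invariant to rescaling the clearance series, equals 1 exactly
at zero clearance, and is strictly anti-monotone in clearance.

**Body-surface correction.**  The source formula's grouping is
typographically ambiguous, so two readings are kept:

- `printed` (default): `BS = 1.73·√(weight·height/3600)` — the reference
  surface multiplied onto the Mosteller radical, as the formula prints.
- `mosteller_ratio`: `√(weight·height/3600)/1.73` — the conventional
  clinical normalisation of subject BSA to the 1.73 m² population average.

Retention is unaffected by a *cohort-wide* constant factor between the
two (σ rescales), but mixing variants within a cohort changes per-subject
values; the variant is therefore a single pipeline-level switch.  When a
subject record carries an explicit `body_area_m2`, that value is used
as given.

## Network blocks

Each per-metal block is a single-hidden-layer perceptron: 7 inputs
(long-term: weight, height, body area, age, sex, water, soil) or 6
(short-term: without soil), 5 hidden `tanh(0.7·x)` units, one linear
output.  The curvature 0.7 is an input-slope multiplier.  Loss is the
plain mean of squared residuals on the normalised output scale (no ½
factor), so the reported aggregate error is literally the mean of the
per-example squared errors whose min/max the error tables also show.

**Training.**  Full-batch iRPROP− for 10,000 epochs: per-weight step
sizes start at Δ₀ = 0.5, grow by η⁺ = 1.2 while the gradient sign
persists, shrink by η⁻ = 0.5 on a sign flip (the stored gradient is then
zeroed, so that coordinate skips one direction update), and stay clamped
to [10⁻⁶, 50].  Only gradient signs are used.  The mapping of the
published settings is: "descent step 0.5" → η⁻, "split factor 1.2" → η⁺,
and the separately stated constant "learning rate 0.5" → Δ₀.  Weights
initialise uniformly on [−0.5, 0.5] with zero biases, from an explicit
seed.  Because RPROP does not descend monotonically, the weights with the
lowest training error seen anywhere in the run are the ones retained.

**Restart selection.**  A single RPROP run from one random
initialisation occasionally settles in a sharp minimum: training error is
excellent but the fitted surface spikes between training points, and the
training error itself cannot expose this (in controlled sweeps,
selecting among restarts *by training error* preferentially picked the
sharp fits).  By default each block therefore trains `n_restarts = 3`
candidates from independent initialisations; a validation subset (20% of
the training rows, seeded) is held out, candidates train on the
remainder, and the candidate with the lowest validation error is kept as
trained.  `n_restarts = 1` restores the bare single-run protocol (the
block then trains on every training row).

## Preprocessing and splits

Order of operations: gross-error filtering and Z-score standardisation
belong to data QC; the model pipeline itself assembles the per-metal
design matrix, maps every column (and the retention target) affinely onto
[−1, 1] *over the whole assembled dataset*, and only then splits 80/20.
Normalising before the split follows the published preprocessing order
and guarantees every held-out row lies inside the fitted cube; the
information shared with the test split is limited to per-column min/max.
The affine map is stored with the model and inverted exactly at
prediction time (round-trip identity to 1e−12); values outside the fitted
range extrapolate linearly (no clipping by default), and block outputs
that leave (0;1) on the retention scale are reported as-is with a
warning.

A note on the Z-score switch: applying a per-column z-score *before* the
[−1, 1] map is numerically inert, because both stages are per-column
affine maps and the composition still sends the column minimum to −1 and
maximum to 1.  The switch exists for pipeline fidelity and runs the
stage for its diagnostics (it names zero-spread columns).

The gross-error filter is a single-pass mean ± k·σ band (k = 3 default,
population σ).  A consequence worth knowing: a lone extreme value
inflates σ enough to sit inside its own band (e.g. [1,1,1,1,100] at k=3
retains everything), which is inherent to the rule, not a bug; with more
inliers the same outlier is rejected.

The 80/20 split is seeded uniform sampling without replacement.
Cross-validation uses contiguous *sequential-shift* windows: fold j
tests rows [⌊j·n/k⌋, ⌊(j+1)·n/k⌋), so any n is partitioned exactly.
Because every subject — including the extreme-exposure tails a random
split usually leaves in training — appears in a test window exactly once,
pooled cross-validation error sits systematically above a single random
split's test error (about 2× in our synthetic sweeps); that is a property
of the protocols, not a regression.

## Closed-loop fusion

The closed model's output is a convex combination of the two blocks,

    Retention_M = a_l·Retention_M^l + a_s·Retention_M^s,
    a_l = Err_T(l)/(Err_T(l)+Err_T(s)),  a_s = 1 − a_l,

computed on the retention scale after inverse normalisation.  The
published convention weights each block *proportionally* to its mean test
error — the worse block receives the larger weight — and the published
per-metal weight table confirms the formula as printed, so that is the
default; an `inverse` option provides conventional inverse-error
weighting for comparison.  The weights are scale-invariant and undefined
when both errors are zero.

## Synthetic cohorts

The generator emulates the statistical shape of the study cohort — 242
children/teenagers, 54 boys (mean age 11.7) / 188 girls (mean age 10.4),
age-indexed height and weight, log-normal water (mg/L) and soil (mg/kg)
concentrations at typical urban levels — with a planted ground truth:

    η  = 0.9·z_water + 0.15·z_soil + 0.25·z_age − 0.2·sex + 0.3·z_bsa
    CL = cl_scale · (0.05 + 0.95·(1 − expit(1.2·η)))

where z are standardised logs (environment) or standardised physiology.
Higher exposure → lower clearance → higher retention.  Blood and urine
concentrations and diuresis are back-solved from the clearance formula,
so running the measurement pipeline on a noiseless cohort reproduces the
planted retention to float precision (a construction identity the tests
assert).  Gaussian observation noise (default sd 0.02) is added to the
retention target only, then clipped into (0;1).

Parameter choices, fixed once: log-normal σ_log 0.35–0.4 keeps the
within-city concentration spread realistic — heavier tails would compress
the bulk of the [−1, 1]-scaled feature into a thin slice and make the
planted surface needlessly sharp; the logistic gain 1.2 spreads retention
over most of the unit interval; the soil coefficient is deliberately
small relative to water (soil acts as a secondary chronic integrator)
because the short-term block cannot see soil, and its irreducible error
(≈0.009 on the normalised scale at these settings) must stay well below
the recovery tolerance.  With a realistic unimodal clearance
distribution the recomputed retention spans roughly (0.001, 0.95) at
n ≈ 242: pushing the minimum above 0.05 while keeping the maximum near 1
would require an implausibly bimodal clearance distribution, since
min(retention) = exp(−max(CL)²/2σ²) and (max−min)/sd ≳ 3.5 for unimodal
samples of this size.

**What the synthetic tests show — and don't.**  Parameter-recovery runs
(n = 200, noise 0.02, 10,000 epochs) demonstrate that the pipeline can
learn a smooth monotone exposure→retention mapping to normalised test
error ≤ 0.05 and that fusion behaves as designed.  They do not establish
accuracy on real cohorts: real retention involves unmodelled intake
routes (diet, inhalation), measurement error in every column, non-smooth
physiology, and cohort-specific missingness, none of which the generator
emulates.  The published cohort-level accuracies are not reproducible
here because the clinical data are private.

## Numerical details and degenerate inputs

- Clearance errors: zero blood concentration or zero body-surface
  correction raise a division-domain error; zero urine concentration is
  valid and yields retention 1.
- A constant clearance series has σ = 0 and is rejected (degenerate
  cohort).
- Constant feature columns are rejected at normalisation with the column
  named.
- Non-finite losses or gradients abort training with a diagnostic naming
  the weight array.
- All randomness flows through explicit integer seeds (cohort generation,
  splits, initialisations, restart streams); equal seeds give bit-equal
  results.
- Problem sizes used by the test suite (n = 50–242 subjects, 150–10,000
  epochs) were chosen to exercise the study-scale configuration (n = 242,
  10,000 epochs) where the contract demands it and smaller configurations
  elsewhere.

## Known limitations

- The error-proportional fusion weights are reproduced as published;
  inverse-error weighting (provided as an option) is what decision
  theory would suggest, and the published rationale for the proportional
  scheme is unknown.
- Per-example squared errors are reported on the normalised [−1, 1]
  output scale, so they are comparable across metals but not directly
  interpretable as retention differences.
- The retention statistic is cohort-relative (σ is estimated from the
  cohort at hand); predictions for a new subject inherit the training
  cohort's σ implicitly through the learned mapping.
- Factor/component analysis for feature selection is out of scope; the
  feature sets are fixed by the two block topologies.
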