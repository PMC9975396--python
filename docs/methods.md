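# Methods

This note documents the modeling assumptions, parameter choices and known
limitations of `fcnorm`. It describes what the code computes; every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes itself.

## The normative-modeling procedure

The unit of analysis is a subject's inter-network functional connectivity:
Pearson correlations between the BOLD time series of 14 canonical
resting-state networks (anterior/posterior salience, auditory, basal
ganglia, dorsal/ventral default mode, higher/primary visual, language,
left/right executive control, precuneus, sensorimotor, visuospatial). The
symmetric 14×14 correlation matrix carries no directional information, so
the strict lower triangle — 91 features — represents the subject.
Vectorization order is row-major over the strict lower triangle
((1,0), (2,0), (2,1), ...); the order is a pure convention, so the
feature-index → network-pair map is persisted with every output and
`devectorize` inverts `vectorize` exactly.

**Motion rejection.** A scan is excluded when maximum framewise
displacement exceeds 3 mm, any translation magnitude exceeds 3 mm, or any
rotation magnitude exceeds 3°. "Exceeds" is strict: a value of exactly 3
passes. When a motion table carries no FD column, FD is computed
Power-style as the sum of absolute backward differences of the six
realignment parameters with rotations converted to arc length on a 50 mm
sphere; whether an RMS-based definition was intended instead is genuinely
open, and the choice is surfaced here for users with their own motion
tables.

**Standardization.** Features are z-scored with the healthy training
set's per-feature mean and *population* SD (divide by n; the two-subject
case {0, 2} → z = ∓1 pins the convention down in a unit test). Test sets
are always transformed with training parameters. A dedicated guard test
asserts that adding any test subject changes the fitted parameters, i.e.
that the leakage-free contract is meaningful.

**Autoencoder.** Fully connected 91–46–13–46–91, leaky-ReLU hidden
activations, linear output (targets are standardized reals), MSE loss,
L2 penalty 1e-5 on all weight matrices, dropout 0.5, He fan-in normal
initialization, 1000 epochs of Adam (lr 5e-4, β₁ 0.9, β₂ 0.999, ε 1e-7).
Choices the architecture description leaves open, fixed here and
configurable:

- batch size 32;
- leaky-ReLU negative slope 0.01;
- dropout after each hidden activation, never on the output layer;
- no Fisher z-transform of the correlations (the model consumes raw r).

The implementation is plain numpy. A single seeded generator drives weight
initialization, batch shuffling and dropout masks, so training is
bit-reproducible on a fixed platform; inference applies no dropout and is
deterministic. Training raises a structured error (with epoch index) on a
non-finite loss.

**Cross-validation and model selection.** Ten-fold CV stratified by
dataset label: within each label, subjects are shuffled (seeded) and dealt
round-robin across folds, which keeps label proportions as equal as counts
allow and degrades gracefully (with a warning) when a label has fewer
members than folds. Two selection metrics — the mean over folds of the
median training MSE_s, and the train-validation gap of those means — are
min-max normalized across candidate models; the candidate minimizing the
sum of the two normalized metrics is selected. "Best balance" is not a
formula with a unique reading; the sum rule is the simplest symmetric one
and is exposed as a function so users can substitute their own.

**Deviation statistics.**

- `MSE_s` (per subject) and `MSE_f` (per feature, per group) are two
  marginalizations of the same squared-residual table, so the mean of
  `MSE_s` over a group's subjects equals the mean of `MSE_f` over the 91
  features; the pipeline asserts this identity at 1e-10 on every run.
- Group comparisons use two-sided Mann–Whitney U (sidedness configurable):
  exact null when the smaller group has ≤ 8 subjects and no ties,
  tie-corrected normal approximation otherwise. Shapiro–Wilk normality
  p-values are reported per group but never gate the analysis. No
  multiple-testing correction is applied across comparisons; reports say
  so and carry raw p-values.
- All absolute differences entering thresholding are in standardized
  units. The deviation threshold is the empirical 80% quantile (linear
  interpolation) of the merged absolute-difference vector of the core test
  sets; values ≥ threshold are retained, ties at the threshold included.
  Independently simulated replication sets are binarized with the same
  stored threshold rather than their own, so their graphs are comparable.
  The realized threshold is logged (it is data-dependent; on the default
  study it lands near 1.35 z-units).
- Top-decile selection takes floor(0.10 × 91) = 9 pairs, ordered by
  descending value then ascending feature index — fully deterministic
  under ties.
- Characterization of a patient group uses four top-decile sets: before
  and after healthy-baseline subtraction, under condition (a) — the
  configured split — and condition (b) — the healthy test set doubled by
  moving subjects from the training pool, with the model retrained from
  scratch on the reduced pool. Rule 1 (present in all four sets) and rule
  3 (absent before, present after, both conditions) define the
  characteristic pairs; rule-2 pairs (before only) are reported as
  non-characteristic. Retraining under condition (b) is a deliberate
  choice: reusing the condition-(a) model would make the second condition
  a subsample of the first rather than an independent check.

## The synthetic cohort generator

The generator emulates the *downstream product* of an rs-fMRI
preprocessing chain, not the imaging itself: per-subject T×14 network
time-series tables.

- **Generative law.** Time series are i.i.d. multivariate Gaussian draws
  from a subject-specific correlation matrix. The analysis consumes only
  second-order structure (Pearson r), so Gaussianity is a sufficient
  description; no hemodynamics, autocorrelation, physiological noise or
  site effects are modeled.
- **Population template.** Block-structured: seven modules (visual,
  default-mode, executive, salience, sensory/auditory, and two singleton
  networks) with within-module correlation 0.45, between-module 0.10,
  small seeded heterogeneity (SD 0.03), projected to the nearest valid
  correlation matrix by eigenvalue clipping and diagonal rescaling.
- **Patient groups.** Selected edges are offset by a known delta
  (default +0.4 on three edges per group) and recorded in a truth
  manifest; offsets that would leave (−1, 1) raise an error.
- **Subject variability.** Additive Gaussian jitter (SD 0.06 by default)
  on the off-diagonals, re-projected to a valid correlation matrix. The
  empirical dispersion of healthy network-level FC is not well pinned
  down; 0.06 is an order-of-magnitude choice, exposed in the config.
- **Determinism.** One master seed; subject i (in manifest order) receives
  the spawn-key-i child of the master seed stream, so enlarging a group
  appends subjects without changing existing ones.
- **Motion fixtures.** Small-amplitude random walks rescaled to pass the
  rejection rule by construction; the contaminated variant injects a 4 mm
  translation spike that violates both the translation and FD limits.

**Default study conditions.** 200 healthy training subjects; 30 subjects
per test group (healthy test, three patient groups, plus an independent
healthy/patient replication pair); 150 timepoints; delta 0.4 on three
injected edges per patient group. These sizes keep a full run in seconds
while leaving comfortable statistical margins for the recovery properties
the tests assert.

## What passing tests do and do not show

On these synthetic cohorts the pipeline (i) separates perturbed groups
from held-out healthy subjects on median MSE_s with significant rank
tests, (ii) recovers injected edges in the healthy-subtracted top decile,
and (iii) flags injected edges as characteristic under the two-condition
rules. This validates the machinery — bookkeeping, leakage control,
statistics, localization — not clinical performance: real FC data have
between-subject structure (low-rank individual differences, edge-specific
variability, site effects) that the generator deliberately omits.

One consequence is worth spelling out. Because subject jitter is
independent and identically scaled across edges, after z-scoring every
non-injected edge is equally unpredictable to the model; the per-edge
error map beyond the injected pairs is exchangeable sampling noise. Two
independently simulated cohorts with the same injected edges therefore
share those injected pairs in their worst-reconstructed decile, but agree
on the remaining slots only at chance level. Real cohorts, by contrast,
share stable "hard" edges driven by population-level edge-variance
heterogeneity; reproducing that would require correlated (low-rank)
subject variability with edge-specific scales, which this generator does
not attempt.

## Numerical choices and degenerate inputs

- Correlation-matrix validity: symmetric to machine precision, unit
  diagonal exact, smallest eigenvalue > 1e-8 (eigenvalue floor 1e-6 during
  projection, iterated with rescaling).
- Zero-variance time series and zero-SD training features raise errors
  naming the offending network or feature index.
- Identical-constant group comparisons report U = n₁n₂/2 and p = 1 with a
  warning rather than failing.
- Quantile convention: numpy's linear-interpolation quantile; the
  "retained fraction" can exceed the nominal top fraction only through
  ties at the threshold, which are logged.

## Known limitations

- The generator's realism gaps listed above (no autocorrelation, no site
  effects, no intranetwork structure, independent edge jitter).
- The autoencoder is the fixed published-style architecture; no search
  over layer sizes is provided beyond the selection-metric utilities.
- Connectograms are exported as edge lists, not rendered; all figures are
  left to the user, and every reported number exists in a
  machine-readable table first.
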