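# Methods

This note documents the models, numerical choices and limitations behind
`pmgait`.  Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Posture preprocessing

A trial's posture matrix stacks, per frame, the (x, y, z) coordinates of
the configured marker layout (13 markers → D = 39).  Preprocessing is
per trial: subtract the trial's mean posture vector, then divide by the
trial's mean Euclidean distance from that mean posture.  The per-trial
scope removes marker-placement offsets and body-size differences *before*
trials are pooled, which is what makes the pooled covariance reflect
movement rather than anthropometry.  A config switch can normalize with a
global scale instead, but per-trial is the default and the tested path.
Preprocessing is idempotent to 1e-9 and rejects constant trials
(zero scale) as degenerate; variation at the floating-point level of the
coordinate offsets (relative scale ≤ 1e-12) counts as constant.

Trials of unequal length are pooled as sampled, without time
normalization or length weighting: a longer trial contributes more rows.

## Principal movements

The PM basis is the eigendecomposition of the D × D sample covariance of
the pooled matrix (equivalently the SVD of the centered data; the test
suite checks both routes agree to 1e-8).  Eigenvector signs are fixed by
making each column's largest-magnitude element positive — the
decomposition's sign is arbitrary, and score series must be reproducible
across runs and machines.  Zero eigenvalues from rank deficiency are kept.

Relative explained variance uses all K components in the denominator, so
shares sum to 100 regardless of how many PMs are retained (default 5,
configurable).  Two scopes are provided: per subject × condition (the
within-subject variable for the ANOVA stage) and per subject pooled over
conditions (summary-table convention).  Whether a participant-level
summary should average per-condition shares or pool scores first is a
genuine ambiguity; both outputs are emitted and the pooled variant is
labelled `condition = "pooled"`.

Principal accelerations are computed as zero-phase (forward–backward)
third-order Butterworth low-pass at 7 Hz, then a second-order central
difference at the sampling rate.  The 7-Hz cutoff sits above the
stride-harmonic band (≈1–4.5 Hz at stride rates near 1.25 Hz) and below
the noise band that double differentiation would amplify; `spectral_profile`
exists to audit that placement on real data.  The forward–backward pass
squares the magnitude response (a 20-Hz probe is attenuated ≥ 97% in
amplitude) and cancels phase (< 0.5° shift at 3 Hz).  The first and last
frames of each acceleration series are NaN (central differences are
undefined there) and are excluded from downstream statistics; acceleration
rVAR therefore uses NaN-aware variances with the same formula as position
rVAR.

Leave-one-subject-out robustness refits the basis without each subject and
reports |cos| between matching eigenvectors; a PM is robust when its
minimum similarity over left-out subjects stays above the threshold
(default 0.9 — a convention, not an estimated quantity).

## Local dynamic stability

Score series are delay-embedded; the default analysis path uses the fixed
parameters τ = 10 samples, m = 4 at 150 Hz, with AMI/FNN selection
available both as diagnostics and as an adaptive mode:

- AMI is histogram-based (16 bins by default).  Binned AMI curves of
  deterministic signals carry bin-resonance jitter, so the reported
  "first minimum" is detected on a 5-point moving average.  For a pure
  sine the smooth-curve first minimum and the global minimum differ: the
  quarter-period lag is the *global* minimum (what the analytic argument
  predicts), while shallow earlier dips are estimator artifacts.
- FNN uses Kennel's two criteria (distance-ratio tolerance 15, loneliness
  tolerance 2 × attractor size) with a Theiler exclusion of τ·m samples;
  the recommended dimension is the first m with false fraction < 0.01
  (at the looser 5% bar, the m = 2 fraction of Lorenz-like signals
  occasionally slips under, selecting an under-embedded dimension).

The largest Lyapunov exponent is estimated with Wolf's fiducial-trajectory
method, in the fixed-evolution-time form, with one refinement.  Classic
Wolf accumulates log divergence from the instant a neighbor is selected.
A neighbor chosen for being unusually close is, however, subject to
selection-bias regression: its separation initially grows faster than the
true divergence rate (the same transient that divergence-curve estimators
skip by fitting only the later linear region — on 150-Hz Lorenz data the
average log-separation curve is ≈ 2× too steep for the first ~0.4 s and
matches the variational ground truth within ~3% afterwards).  Classic
settings therefore over-estimated the Benettin oracle by 20–60% in our
convergence study.  The estimator consequently:

- follows each neighbor for at most 1.5 mean pseudo-periods and discards
  the first 0.5 period after every replacement (`settle_steps`),
- replaces a neighbor only when its separation outgrows `max_sep`
  (default 0.5 × RMS attractor radius), its age expires, or it runs off
  the record — never for being small,
- searches replacements at distance ≥ `min_sep` (default 0.005 × radius;
  raise above the noise floor for noisy series) within a 30° cone of the
  current separation direction, falling back to the best-angle and then
  the plain nearest admissible candidate,
- applies a Theiler window (max of the embedding window and half a
  pseudo-period) to all neighbor searches,
- uses an evolution/bound-check interval of 1/8 pseudo-period.

The mean pseudo-period itself is the inverse spectral centroid
(power-weighted mean frequency) of the series — the periodogram *peak*
locks onto slow lobe-switching in Lorenz-like signals, and the
autocorrelation zero-crossing tracks lobe residency; the centroid recovers
sine periods exactly and a representative orbital time for chaotic
signals.

With these defaults, held-out validation in the test suite recovers the
Lorenz exponent within 15% from 360 s of scalar data with AMI/FNN-selected
embedding, reports |λ₁| < 0.05 nats/s for noiseless sinusoids, is exactly
invariant to affine scaling of the series, and is consistent across
sampling rates (150 vs 75 Hz) within estimator tolerance.  All knobs are
exposed as keyword arguments.  Exponents are reported in nats per second
by default (per-sample and per-stride available); the unit is recorded in
the output table.

LyE is computed on raw position scores by default — the 7-Hz filter is a
pre-differentiation step, and low-pass filtering before state-space
reconstruction would itself alter small-scale divergence — with a config
switch to use filtered scores.

## Statistics

The ANOVA is a split-plot sums-of-squares decomposition: between factor
(age group, 2 levels), within factor (speed, 8 levels), subject nested in
group.  F, uncorrected p and partial η² match `pingouin.mixed_anova` to
1e-8 on simulated tables (checked in the test suite).  Greenhouse–Geisser
ε is computed from the *pooled within-group* covariance of the repeated
measures (the convention of mainstream commercial ANOVA software; pooling
removes group mean differences first), so it can differ in the second
decimal from implementations that use the raw covariance.  ε is clipped
to its theoretical bounds [1/(L−1), 1]; corrected p-values use
fractional dfs (ε·df₁, ε·df₂).  With a single group level the design
degenerates to one-way repeated measures, where the 2-level within F
equals the squared paired t exactly.  Observed power follows the
"observed power" convention: noncentral F with λ = F·df₁ at the
(corrected) dfs.  Under a compound-symmetric null the uncorrected within
test is exact (type-I error 5% ± 1.5% over 1000 simulations in the
acceptance tests); the GG-corrected test is mildly conservative at small
n, as expected.

Bonferroni post hoc tests run all 28 pairwise paired t-tests over the 8
speed levels.  The default adjusted α is 0.006 (the 0.05/8 convention for
this design); a flag at the all-pairs level 0.05/28 is reported alongside,
since which denominator a given study intends is not always stated.

The a-priori power analysis uses the repeated-measures noncentral-F
convention: λ = N·f²·m·ε/(1−ρ), df₁ = (m−1)ε, df₂ = (N−g)(m−1)ε.  The
returned minimal N is constrained to equal group sizes by default
(`balanced=True`), matching standard a-priori power software for
between × within designs: for f = 0.25, α = 0.05, power 0.95, 2 × 8
design, ρ = 0.5, ε = 1 the smallest admissible totals are 23 (unbalanced)
and 24 (balanced).

Missing cells are handled by listwise deletion per metric × PM, with the
dropped-subject count reported in the ANOVA table.  Shapiro–Wilk screening
is advisory only: no stage branches on it.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
musculoskeletal mechanics.  Each marker coordinate is a static
anthropometric offset plus three stride harmonics with amplitudes decaying
as 1/h (fundamental = speed factor × 1.25 Hz; pelvis markers ≈ 15 mm,
distal markers up to ≈ 70 mm; mediolateral and vertical excursions scaled
0.4 and 0.7 of anteroposterior), left–right antiphase at odd harmonics,
plus white measurement noise (default SD 1 mm, typical of optical capture).
Harmonic phases are shared across the cohort with per-subject jitter
(SD 0.3 rad) and log-normal amplitude variation (SD 0.1), so subjects
share common movement synergies — giving a dominant pooled PM and
meaningful leave-one-out robustness — while remaining individually
distinct.  Preferred walking speed is drawn per subject from
N(1.25, 0.12²) m/s; the default design is 26 subjects (half young, half
older) × 8 speed factors 0.40–1.45 × one 30 s trial at 150 Hz.

The chaotic component is the x-coordinate of a Lorenz system
(σ = 10, ρ = 28, β = 8/3), integrated with fixed-step RK4 (step ≤ 2 ms),
first 10 time units discarded as burn-in, time axis compressed by
`chaos_timescale` (default 2, placing the signal's power inside the 7-Hz
passband) and injected along a fixed unit posture-space direction.  The
ground-truth exponent is computed by a Benettin variational integrator
(exact Jacobian dynamics with per-step tangent renormalization), entirely
independent of the Wolf estimator it serves as oracle for; an injected
signal diverges at `chaos_timescale × oracle` nats per second.  Because a
Lyapunov exponent is amplitude-invariant, dose-response tests vary the
chaotic *mixing fraction* (gain against fixed harmonic leakage along the
injection direction), which moves the measured exponent of the mixed
series monotonically from ≈ 0 to the injected rate.

What passing synthetic tests do **not** show: correct handling of
non-stationary gait (fatigue, drift), soft-tissue artifact, marker
occlusion/gap structure, stride-to-stride timing variability beyond phase
jitter, or realistic inter-segment coupling.  Results on real data
additionally depend on the marker selection, which is configuration-driven
(a 13-marker subset of a larger protocol is one common choice, but the
bilateral expansion of named landmarks is ambiguous and must be specified
by the user).

## Problem sizes in the tests

The suite exercises the pipeline at deliberately modest scales — cohorts
of 4–6 subjects × 8 conditions × 8–20 s, 60–360 s Lorenz records, 1000
simulation replicates for calibration checks — chosen so the full suite
documents the method's behavior in about a minute while keeping every
statistical tolerance meaningful (each stochastic assertion states its
band in the test).

## Known limitations

- C3D reading requires the optional `ezc3d` dependency and honors
  POINT:UNITS (m/cm → mm); force-plate channels and gap filling are out
  of scope, and gapped trials are rejected rather than repaired.
- The Wolf estimator's accuracy study covers Lorenz-class signals;
  exponents of noisy quasi-periodic gait scores should be read as a
  relative stability measure across conditions, not an absolute invariant.
- The ANOVA stage supports one between factor with two levels (plus the
  one-group degenerate case) and one within factor, as the design
  requires; it is not a general linear-model engine.
- Observed power is the post hoc convention computed from the sample F;
  its well-known interpretive limits apply.
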