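# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `stimnet`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design emulated by the package

The unit of analysis is a within-subject factor, stimulation level 0–3
(0 = stimulation off, 3 = the highest clinically tolerated intensity;
typical group-mean currents for such a design are roughly 0, 1.25, 2.3 and
3.0 mA). At each level a subject draws Archimedean spirals five times under
two tasks (traced over a template, and self-paced), while multichannel EEG
is recorded; the five drawing epochs per condition are concatenated for
spectral analysis. Slopes of any parameter "across levels" are ordinary
least squares against the ordinal level index 0–3, not against current in
mA: the levels, not the currents, are the counterbalanced design variable,
and per-subject currents at a given level differ (this is an explicitly
open choice; fitting against current is a one-line change upstream of the
slope functions).

## Spiral kinematics

A template spiral has loop spacing b = 1.5 cm and 3 loops, sampled at
100 Hz (tablet rate). Tangential velocity is computed as the instantaneous
radius times the rate of change of the unwrapped angle,

v_t(t) = r(t)·|dθ/dt|,

with these conventions:

- **Center = first recorded sample**, matching the instruction to start at
  the center. The centroid would be biased toward the outer loops. The
  angle at the center sample itself is undefined; the first two velocity
  samples therefore carry boundary error and closed-form checks exclude the
  first three samples.
- **Unwrapping** by cumulative signed increments wrapped into (−π, π],
  robust to arbitrarily many turns.
- **Derivatives** are second-order central differences (`np.gradient`,
  `edge_order=2`) on the actual time stamps; no smoothing is applied by
  default, because any pre-smoothing changes the sample entropy of the
  velocity series in ways that are hard to reason about. Non-uniform
  time stamps are handled with per-interval dt and logged, not rejected.
- **Direction** (clockwise for right-handed drawing) is normalized away by
  the absolute value of the angular rate; velocity is non-negative.

For a noise-free spiral at constant angular speed ω the closed form is
v_t(t) = (b/2π)ω²t, and the sample mean over the draw is b·n_loops·ω/2.
These are the oracles for the generator round-trip tests.

**Sample entropy.** SampEn(m, r) = −ln(A/B), with B the number of ordered
template pairs (i < j, both over the N−m start points) whose length-m
templates are within Chebyshev distance r, and A the same count for length
m+1. Defaults m = 2, r = 0.2·SD of the series; because r scales with the
SD, SampEn is invariant under affine transforms of the series. Conventions
pinned here:

- Self-matches are excluded; both counts run over N−m start points
  (the standard Richman–Moorman estimator).
- The SD is computed **per spiral**, not per condition (open choice,
  flagged; per-condition SD would couple the five repeats).
- A = 0 or B = 0 yields NaN ("undefined"), never ±inf; undefined values
  are excluded from the five-spiral average with a warning.
- A constant series returns 0 (all templates match exactly at r = 0).
- The pair counting is an exact O(N²) enumeration (numba-compiled with a
  vectorized numpy fallback); the test suite checks it against an
  independent brute-force oracle, which is exact, not approximate.
- Note that SampEn is **not** monotone in r at finite N — the conditional
  ratio A/B can move either way when counts are small — so only the count
  monotonicity is asserted as an invariant.

Per condition (subject × task × level), the five spirals' parameters are
arithmetically averaged.

## Sensor conditioning

Order pinned by the driver: common average reference → Butterworth
band-pass → notches. The band-pass is implemented as separate fourth-order
high-pass (0.5 Hz) and low-pass (300 Hz; the pipeline default lowers this
to 200 Hz when the simulation rate is 500 Hz) sections rather than a single
band-pass design, whose skirts would be shallower than the stated order
suggests. All filters run forward–backward (zero phase): gPDC rests on
cross-region lag structure, and causal filtering would distort it; the
effective order doubles, which is documented behavior. The 0.5 Hz
high-pass needs padding of ~2·fs/0.5 samples in `filtfilt`, far beyond the
library default — this is set explicitly. Notches are second-order IIR
with quality factor Q = 35 (a standard line-noise width; no bandwidth is
prescribed by the design). ICA-style artifact removal is out of scope: the
driver accepts cleaned input, and the generator can simply disable artifact
injection.

## LCMV beamforming

Scalar (fixed-orientation) sources, one lead-field column per ROI. For
lead column l and sensor covariance C, w = (lᵀC⁻¹l)⁻¹ lᵀC⁻¹; unit gain
wᵀl = 1 holds by construction, the output variance on the training
covariance is (lᵀC⁻¹l)⁻¹, and w minimizes output variance among all
unit-gain filters. Diagonal loading λ·mean(diag C) with default λ = 0.05
is exposed everywhere; loading is mandatory when samples < sensors, and a
condition number above 1e12 is refused with advice to raise λ. Unit-gain
(not unit-noise-gain) normalization is used — the simplest contract; depth
bias is therefore inherited from the lead-field scaling, which the
generator column-normalizes.

## Spectral analysis

Welch periodogram: 1-s Hamming windows, 50% overlap, one-sided density,
resolution 1/win_s Hz. Band power is the trapezoidal integral of the
density over the band inclusive of both edges (integral, not mean density —
only a scale factor, chosen once). Absolute power, not relative. Power
slopes across levels reuse the ordinal OLS of the kinematics module; a
log-power option exists.

## MVAR and generalized partial directed coherence

The K = 5 set {M1, SMA, DPMC, VPMC, STN} enters one joint MVAR per
condition — gPDC is defined on the joint model, not on pairwise fits. The
estimator is multichannel least squares without intercept (the series are
zero-mean by construction after referencing/filtering), innovation
covariance from residuals with degrees-of-freedom correction
(n_eff − K·p). Order selection by BIC over 1..20 when requested; the
pipeline default fixes the order instead. Stability is checked via the
companion-matrix spectral radius; an unstable fit warns and is flagged
rather than silently used. The estimator is cross-checked in the test
suite against an independent implementation (statsmodels VAR) to 1e-6.

gPDC is evaluated exactly from the fitted coefficients:
Ā(f) = I − Σ_r A_r e^(−i2πfr/fs), and
|π_ij(f)| = (1/σ_i)|Ā_ij(f)| / sqrt(Σ_k (1/σ_k²)|Ā_kj(f)|²).
Column normalization Σ_i |π_ij(f)|² = 1 is an algebraic identity and is
asserted on every constructed spectrum at 1e-8 (it holds to machine
precision). Frequency grid: 0.5 Hz spacing over 1–100 Hz. Band summaries
are arithmetic means of |π| over the grid points in the band (max is
available as an option). Analyses run on concatenated data per condition,
not per epoch. No surrogate thresholding is applied in the headline
tables — inference across levels is the ANOVA's job — but a
phase-randomization surrogate utility (per-channel phase scrambling,
amplitude spectra preserved) is provided and used by the directionality
tests.

## Prediction

Features: the eight ROI power slopes (M1, SMA, pre-SMA, DPMC, VPMC, DLPFC,
VC, STN) of one frequency band; one model per band. Model:
ε-insensitive SVR with RBF kernel on z-scored features. The pinned
defaults are scale-free heuristics rather than any library's product
defaults: C = 3·SD(y) (Cherkassky–Ma), ε = 0.1·SD(y), γ = 1/(2d) — for
z-scored features the median squared pairwise distance is ≈ 2d, so this is
the median heuristic. Smaller fixed values (e.g. C = 1 with γ = 1/d)
underfit visibly at the design size n = 38, d = 8. Zero-variance features
are dropped with a warning; a constant target short-circuits to a flagged
constant predictor with R² reported as 0.

Accuracy is repeated k-fold cross-validation (5 folds × 10 repeats by
default), scoring the pooled out-of-fold predictions per repeat and
reporting mean ± SD across repeats — the SD is split-to-split variability,
which parallels how such accuracies are usually quoted.

**Attribution** is exact Shapley: the coalition value v(S) evaluates the
model with features outside S replaced by background means (the marginal
expectation under feature independence that kernel-style explainers
approximate), and φ_i sums the weighted marginal contributions over all
2^d coalitions — at d = 8 this is 256 evaluations, so the weighted
regression approximation is unnecessary. Efficiency, symmetry and dummy
axioms then hold exactly and are asserted. d > 12 is refused (no sampling
approximation is implemented). Rankings are by descending mean |φ| with
alphabetical tie-breaks.

## Group statistics

- Paired t (scipy) with an explicit error on zero-variance differences.
- Wilcoxon matched-pairs signed rank: zeros dropped (Wilcoxon's original
  treatment), statistic pinned to the positive-rank sum W⁺, exact p for
  n ≤ 25, tie-corrected normal approximation above. Verified against full
  2^n sign enumeration.
- One-within-factor repeated-measures ANOVA:
  F = MS_level / MS_subject×level with df (k−1, (k−1)(n−1)); at the design
  size (n = 38, k = 4) that is F(3, 111). No sphericity correction by
  default; Greenhouse–Geisser is available. The sum-of-squares
  decomposition is implemented directly (the Tukey step needs the
  interaction mean square, and the calibration tests need thousands of
  fast fits) and is cross-checked against statsmodels AnovaRM.
  Incomplete subjects are dropped listwise with a warning. Under a
  Gaussian global null the test is exact, and the suite verifies a 5%
  empirical rejection rate within ±1.5% over 1000 replicates.
- Tukey HSD on the level means with q = |m_i − m_j|/sqrt(MS_err/n) against
  the studentized range distribution with k groups and the interaction df.

The five-way interaction ANOVAs of the original design (location × band ×
sub-band × hemisphere × level) are deliberately not implemented: they
cannot be validated without the patient data and add no reusable
computation.

## The synthetic generator: what it emulates, and what it does not

**Spirals.** Constant-rate angular progress with optional smooth random
speed modulation (low-pass-filtered Gaussian noise, relative amplitude =
the "entropy knob"), positional jitter, and optional sinusoidal tremor.
Cohort defaults: per-subject velocity gain ~ N(0.15, 0.05²) per level
(truncated at 0), self-paced drawing 15% faster than traced, and an
entropy knob of 0.4 at level 0 dropping to 0.25 at all stimulation-on
levels — i.e. velocity irregularity falls when stimulation is switched on
but does not track intensity further, which is the pattern the entropy
analysis is designed to detect. Base angular speed 1.3 rad/s puts a
three-loop spiral near 14 s. These effect sizes are free parameters of the
generator, chosen once as clinically plausible magnitudes; no published
per-subject variability estimates exist to calibrate them against.

**Network.** Eight ROIs, each a damped AR(2) resonator (poles at radius
ρ = 0.85–0.9, angle 2πf₀/fs; fs = 500 Hz): beta resonators at 25 Hz (M1,
STN, pre-SMA, DLPFC), high-gamma resonators at 80 Hz (SMA, DPMC, VPMC), an
isolated 10 Hz visual-cortex resonator as a level-invariant null
reference. Directed edges: STN↔M1 at 25 Hz whose gain falls linearly with
level (multipliers 1, 0.75, 0.5, 0.25 on a base of 0.06), and M1↔{SMA,
DPMC, VPMC} at 80 Hz whose gain rises (0.25 → 1). M1 and STN resonators
are broader (ρ = 0.85) because the bidirectional 25 Hz loop between two
sharp resonators is otherwise super-critical — the loop gain at resonance
scales as c²/((1−ρ)²·…) and destabilizes the system long before the
coupling is strong enough to measure.

**Edge kernels.** Edges act through a short FIR kernel rather than a
single lag. A single-lag cross-coefficient has a frequency-flat
|Ā_ij(f)|, so modulating a "beta" edge would modulate gPDC at every
frequency, including high gamma — the level effect would leak into bands
it has no business in, and the high-gamma STN→M1 pair could never be flat.
The kernel places three conjugate zero pairs across the opposing analysis
band, one zero at DC, four "guard" zero pairs between the analysis range
and Nyquist (keeping the out-of-band kernel gain near or below its
in-band gain — unconstrained zero-placement polynomials otherwise grow
large between their zeros and destabilize the network), and a short
raised-cosine taper; taps are normalized so the gain at the edge's center
frequency equals the nominal edge gain. The resulting ground-truth model
has order p = 19 and in-band leakage into the opposing band of order 1%
of the in-band response. Ground-truth gPDC remains fully analytic.

All edges live within {M1, SMA, DPMC, VPMC, STN}, so that 5-ROI subset is
itself an exact MVAR process — the connectivity experiments fit it without
marginalization error. Innovation gains per ROI can additionally be
modulated with level (beta-ROI drive falls, gamma-ROI drive rises) so that
local band power mirrors the couplings; the connectivity experiments turn
this off to isolate the coupling effect, the power/prediction demos turn
it on.

**Sensors.** A smooth random lead field (Gaussian matrix smoothed along
the sensor axis, columns normalized, full column rank enforced with
bounded retries; 64 sensors by default) stands in for volume conduction —
no anatomy, no realistic topographies. Additive white sensor noise, 50 Hz
line noise with per-channel amplitude, and an optional rectangular pulse
train at ~130 Hz (rate, amplitude, duty) mimicking a stimulation artifact
spectrally, not biophysically.

**Simulation.** MVAR recursion from zero initial state with innovations
drawn via a Cholesky (or eigen) factor; burn-in of max(10p, 200) samples
discarded for approximate stationarity. An ensemble mode propagates many
independent realizations through one recursion, which is what makes the
100-run Monte-Carlo experiments cheap.

**What passing tests do and do not show.** The generator's sources are
stationary, linear, and Gaussian; couplings are fixed within a condition.
Real recordings have bursty beta dynamics, nonstationary artifacts,
volume-conduction leakage correlated across ROIs, and head-model error —
none of which are modeled. Passing the direction-of-effect experiments
demonstrates that the pipeline recovers the imposed effect structure under
its own assumptions, not that those effects would be recovered from
patient data; the published patient-level numbers (cross-validated R² near
0.63/0.71, specific F statistics) depend on unavailable recordings and are
deliberately not targets of any test.

**Prediction cohort.** The feature-level generator draws eight
standard-normal power-slope features and forms the velocity slope as
0.9·M1 + 0.7·DLPFC + N(0, 0.3²), i.e. signal confined to M1 and DLPFC
with a ceiling R² around 0.93 at n = 38 — a strong but not noiseless
effect, chosen once so that a correctly working pipeline passes the
recovery experiment with margin and a broken one does not.

## Problem sizes in the validation experiments

Coefficient recovery uses K = 5, p = 3, n = 20 000 at fs = 500 Hz; the
direction-of-effect experiment 100 runs × 4 levels at n = 10 000; the
prediction recovery 50 cohort draws at n = 38 subjects; the ANOVA
calibration 1000 null replicates at n = 38; surrogate nulls use 100
phase-randomized re-fits. These sizes make every experiment reproducible
in minutes on a single core while keeping Monte-Carlo error well inside
the asserted margins.

## Known limitations

- One representative time series per ROI (scalar beamformer); no
  volumetric grids or orientation estimation, and no account of how a
  volumetric pipeline would collapse a grid to ROI series.
- The EDF import path is intentionally absent; recordings enter as plain
  matrices (raw float64 + JSON sidecar, or CSV).
- Wilcoxon's normal approximation (n > 25) uses tie correction but not
  continuity correction beyond scipy's convention.
- The DBS artifact model is spectral only; template subtraction or
  ICA-based cleanup of real artifacts is out of scope.
- `run_pipeline` simulates EEG for a small number of subjects and uses the
  feature-level cohort generator for the prediction stage; simulating 38
  full EEG subjects would add nothing to the validation while multiplying
  runtime.
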