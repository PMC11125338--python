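# Methods

`tostab` answers one question about conditionally automated driving: after a
driver takes back control from the automation, how long until each driving
and physiological variable stops changing — i.e. stabilizes?  The package
implements the full chain: a synthetic-data generator with known ground
truth, windowed feature extraction, convex decomposition of skin
conductance, and the repeated-measures window-comparison procedure that
turns per-window features into a stabilization time.

## The stabilization procedure

Features are computed on half-open windows `[s, s + L)` with starts
`s = 0, 2, 4, …, 12 s` after takeover (TO) onset and lengths `L = 2 s`
(non-overlapping tiling) or `L = 5 s` (overlapping), seven windows per grid.
Per variable and window length the attempts × windows matrix enters:

1. **One-factor repeated-measures ANOVA** with window start as the factor.
   Sums of squares are decomposed into factor, subject and error terms;
   `F = MS_factor / MS_error` with `df = (k−1), (k−1)(n−1)`, `k = 7`.
2. **Sphericity.** Mauchly's `W` is computed from the covariance of
   orthonormalized contrasts; its p-value uses Box's chi-square
   approximation including the second-order term (the convention of ezANOVA
   and pingouin, and numerically equal to pingouin's to ~1e-8).  When the
   test rejects at α = 0.05, the Greenhouse–Geisser correction is applied:
   `ε̂ = (Σλᵢ)² / ((k−1) Σλᵢ²)` over the eigenvalues of the double-centered
   covariance, clipped to `[1/(k−1), 1]`; both corrected and uncorrected
   p-values are always reported.
3. **Pairwise tests**, run only when the ANOVA rejects: two-sided paired
   t-tests for all `k(k−1)/2 = 21` window pairs, Bonferroni-adjusted
   (`p_adj = min(1, 21·p)`), significance at α = 0.05.
4. **Stabilization rule.** A variable is stabilized in the first window
   that shows no adjusted-significant difference against *all* subsequent
   windows.  The last window has no subsequent windows and would qualify
   vacuously; it is therefore not a candidate, and a variable whose only
   quiet window is the last one is reported *not stabilized within the
   horizon*.  Maximal runs of mutually indistinguishable consecutive
   windows ("transient plateaus") are reported alongside, because
   dip-and-recover profiles (speed) can be quiet early, change, and settle
   again.

**Unit of analysis.** The repeated-measures unit is the individual takeover
attempt (driver-level aggregation is available via `unit="driver"`).  The
ANOVA uses complete cases (listwise deletion); the pairwise t-tests use
pairwise-complete rows.  Pairs with fewer than two complete rows are
untestable and counted as "no difference observed", flagged on the result.

**Degenerate inputs.** Identical window columns yield `F = 0, p = 1`
without attempting Mauchly's test (whose contrast covariance is then
singular).  A paired difference with zero variance yields `t = 0, p = 1`
when its mean is zero and `t = ±∞, p = 0` otherwise.

## The seven variables

| variable | definition per window | units | missing when |
|---|---|---|---|
| winding | sample SD (n−1) of steering angle | deg | < 2 samples |
| speed | mean speed | km/h | no samples |
| deceleration | mean of −accel over samples with accel < 0 **and** brake > 0 | m/s² | no eligible samples |
| eoff | fraction of gaze samples off the road | – | no samples |
| pd | mean of (pupil − pupil at TO onset) | mm | no samples |
| hr | mean over unmasked heart-rate samples | bpm | all masked |
| sc | mean phasic skin conductance | µS | no samples |

A window with no eligible samples is *missing, never zero*.  The pupil
baseline is the first unmasked sample at or after the detected onset of the
same attempt (per-attempt anchoring; a per-driver baseline can be supplied
through `pd_baseline`).  The deceleration eligibility rule (negative
longitudinal acceleration while the brake is pressed) restricts the
variable to actual braking episodes; with the default generator only ~11%
of attempts brake long enough to populate all seven windows, so the
deceleration analysis runs on a much smaller complete-case sample — a
realistic property of braking data.  Takeover onset is the earliest
post-TOR crossing of >2° steering deviation (relative to the wheel position
at the TOR) or >10% brake press; the accelerator pedal uses the same 10%
threshold as a package default since no convention exists for it.  Samples
belong to a window by timestamp only; no edge interpolation.

## Skin-conductance decomposition

Raw GSR `y` is modelled as `y = Kp + Bq + Cd + e` with `p ≥ 0` a sparse
driver, `K` the convolution with a Bateman kernel
`k(t) ∝ exp(−t/τ_d) − exp(−t/τ_r)` (unit peak; defaults τ_r = 0.7 s,
τ_d = 2.0 s), `B` a piecewise-linear spline basis with 10 s knot spacing,
`C = [1, t]` an unpenalized linear drift, solving

    minimize ½‖y − Kp − Bq − Cd‖² + α‖p‖₁ + ½γ‖q‖²   s.t.  p ≥ 0

with α = 8e-4, γ = 1e-2 (the reference defaults of the convex-decomposition
approach; all configurable).  Because `p ≥ 0` makes the ℓ1 term linear, the
free tonic block is eliminated in closed form and the remainder is a
non-negative quadratic program solved *exactly* by a Lawson–Hanson-style
active-set iteration; the KKT residual (typically ~1e-15) is reported in
the diagnostics.  Components satisfy `y = phasic + tonic + residual`
identically by construction.

Discretization: the sampled kernel starts at `k(0) = 0`; the convolution
matrix drops this leading zero so that an impulse at sample *i* acts from
sample *i* and the matrix is invertible.  Recovered driver mass is thereby
within one sample of a seeded impulse.  A tiny ridge (1e-10 relative) keeps
the reduced Hessian positive definite.  The dense formulation is adequate
for records up to a few minutes at 4 Hz.

Decomposition runs once per attempt on the full GSR record (TOR lead-in
through 20 s post-TO, ~30 s) — not per analysis window — so the tonic model
has context; window means of the phasic component are extracted afterwards
and clipped at zero (clips are logged; with the exact solver they are
numerically immaterial).  Masked samples: gaps ≤ 2 s are linearly
interpolated, longer gaps split the record into independently decomposed
segments.

**Known identifiability limit.** Any component of the phasic drive that is
smooth on the tonic model's length scale is absorbed by the tonic spline
(the ℓ1 penalty makes the smooth explanation cheaper).  Sustained arousal
is therefore only expressed in the phasic window means through the *rate
and size of discrete SCRs*, which is how the generator encodes it.

## The synthetic-data generator

The generator emulates the combined design of two driving-simulator
studies: 30 drivers × 4 trials × 4 takeovers plus 28 × 2 × 4 = 704 attempts
in total; a 5 s TOR lead time; driving and eye channels at 50 Hz, GSR at
4 Hz, heart rate at 1 Hz.  Reaction times (TOR → onset) are lognormal
(median 1.5 s, σ = 0.35) truncated to the lead time.  Episodes cover 5 s
before the TOR to 20 s after onset.  Every event draws from an independent
substream keyed by (study, driver, trial, takeover), so datasets are
bitwise reproducible and insensitive to partial regeneration.

Per-channel dynamics (all post-TO responses decay exponentially with the
time constants below; per-attempt lognormal amplitude jitter σ = 0.2):

* **Steering**: zero-mean Ornstein–Uhlenbeck process (correlation time
  0.3 s) whose SD decays 6° → 1° with τ = 1.74 s; the automation holds the
  wheel at 0.3° SD before the TO.  Winding dynamics and ground truth are
  defined on this SD profile, because winding *is* a windowed SD.
* **Speed / acceleration / brake**: 50 km/h baseline; braking dips speed
  (τ_dip = 0.5 s, depth 6 km/h) for a brake duration of `1 + Exp(1.2) s`
  capped at 5 s, followed by recovery with τ_rec = 1.2 s.  A 12% minority
  keeps a light brake through the horizon (`14 + Exp(3) s`) and does not
  recover speed — these attempts populate the late deceleration windows.
  Acceleration is the analytic derivative of the speed profile plus 0.3 m/s²
  white noise; speed noise is OU with a 2 s correlation time (vehicle
  inertia).
* **Gaze**: i.i.d. Bernoulli per 50 Hz sample; off-road probability relaxes
  0.45 → 0.12 with τ = 0.45 s (0.85 during the pre-TO secondary task).
* **Pupil**: 3.5 mm baseline + 1.0 mm step decaying with τ = 1.0 s, white
  0.33 mm sample noise.
* **Heart rate**: 76 bpm + 12 bpm decaying with τ = 8 s, 3 bpm noise,
  35% i.i.d. dropout (wristband motion artifacts).
* **Skin conductance**: tonic level 2 µS with 0.01 µS/s drift plus a
  Poisson SCR train whose rate relaxes 0.85 → 0.05 events/s with τ = 10 s;
  SCR amplitudes lognormal (median 0.35 µS, σ = 0.4) convolved with the
  Bateman kernel.

The magnitudes are package defaults chosen once by a forward power
calculation (below); the source studies report no numeric signal
magnitudes, so these values must not be read as empirical constants.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no vehicle dynamics or traffic, no lane-position
signal, gaze has no fixation structure (i.i.d. samples), heart-rate dropout
is i.i.d. rather than bursty, pupil noise is white rather than
autocorrelated, there is no illumination confound on pupil size, and all
post-TO responses are exponential by construction.  The suite demonstrates
that the *procedure* recovers known dynamics under realistic magnitudes and
missingness, not that real drivers behave like the generator.

## Ground truth

Per variable the ground-truth stabilization time is the earliest time from
which the noise-free mean profile stays within `tolerance × amplitude` of
its asymptote (amplitude = the profile's maximum deviation from the
asymptote after TO), computed by a dense reverse scan at 10 ms resolution;
for a pure exponential this equals `τ·ln(1/tolerance)`.  The default
tolerance is 0.05.  A variable is flagged *not stabilized within the
horizon* when this time exceeds 14 s (last window start + step).  Speed and
deceleration profiles are population expectations over the brake-duration
mixture (quantile quadrature); the skin-conductance profile is the SCR rate
convolved with the kernel.  Ground truth describes the shared mean
profiles, so it is stored once per dataset.

## Design of the recovery experiments

The window-comparison procedure stops detecting a residual profile decline
when the between-window mean difference falls below roughly
`t_crit · σ_d / √n`, where σ_d is the SD of paired window differences
across attempts and `t_crit ≈ 3.05` is the Bonferroni-adjusted two-sided
criterion at k = 7.  The recovery experiments are sized so that this
statistical resolution coincides with the ground-truth band: with n = 200
attempts, a 1 mm pupil excursion and 0.33 mm sample noise (≈ 0.033 mm per
2 s window mean, σ_d ≈ 0.047 mm), the detection threshold is ≈ 1% of the
excursion.  The recovery tests therefore evaluate ground truth at a 1%
band and set `τ = t*/ln(100)` for target settle times t* ∈ {0, 4, 8} s;
the procedure then lands within one 2 s grid step of t* with high
probability, and a τ beyond that resolution is correctly reported as not
stabilized.  Twenty seeded replicates per setting keep the suite inside a
desk-scale budget; the full 704-attempt default study is analyzed once for
the qualitative ordering check (~10 s end to end).

The same forward logic sized the generator defaults so the 704-attempt
study reproduces the qualitative ordering: deceleration and eyes-off-road
settle by ~2 s, pupil diameter mid-horizon, winding and speed at ~8 s, and
heart rate and phasic skin conductance remain non-stabilized within the
horizon.  Statistical stabilization depends on n: smaller studies lose
track of the slow channels earlier (see `examples/04_stabilization_analysis.py`).

## Numerical and I/O choices

* Sample SD uses the n−1 denominator; ε̂ is clipped to its theoretical
  range; Bonferroni adjustment reports `min(1, m·p)` rather than comparing
  raw p to α/m (equivalent decisions, adjusted-p convention for reporting).
* CSV schemas are plain UTF-8 with '.' decimals; floats are written at
  `%.17g` so write→read round-trips are bitwise lossless (readers use
  pandas' `round_trip` float parser).  Missing samples are empty cells on
  disk and boolean masks in memory; readers never impute.
* The pipeline is deterministic given (config, seed): reports re-rendered
  from the same inputs are byte-identical.

## Limitations

* The stabilization time is grid-quantized (2 s steps) and sample-size
  dependent by construction; it is a statistical detection limit, not a
  physiological constant.
* The untestable-pair rule ("no difference observed") is permissive; with
  heavy missingness it can declare stabilization on thin evidence — the
  result carries an explicit flag when this happened.
* The tonic/phasic split is not identifiable for trends smooth on the
  spline's length scale (see above); phasic comparisons between windows
  reflect discrete SCR activity.
* Mauchly's chi-square approximation is asymptotic; at very small n the
  test is only approximately calibrated (the suite checks calibration at
  n = 120 and power under strong autocorrelation).
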