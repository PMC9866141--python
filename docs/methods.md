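# Methods

## Model

A session of `M` repeated mental-control trials produces an `N`-channel
recording `ξᵢ(ω, t)`, `i = 1..N`, modeled as a vector of cyclic
rhythmically connected random processes: there is a single rhythm
function `T(t, n)` — positive for `n > 0`, zero at `n = 0`, negative for
`n < 0`, with `t + T(t, n)` strictly increasing and `T` minimal in
modulus among admissible candidates — such that the joint
finite-dimensional distributions of all channels are invariant under
`t ↦ t + T(t, n)`. Each cycle `m` occupies `Wcₘ = Wₘ,₁ ∪ Wₘ,₂`, the
passivity (zone 1) and activity (zone 2) segments; multiplying by the
zone indicator functions decomposes the signal into zone components
whose sum reconstructs it exactly. With equal trial durations
`T(t, n) = n·T` and the model reduces to an ordinary cyclostationary
(periodically correlated) process; real trials differ in duration, so
the rhythm is irregular and must be estimated.

## Rhythm estimation

Cycle/zone boundaries `t̃ₘ,ₖ` are assumed known from the experiment
protocol (`2M + 1` strictly increasing times; boundary detection from
the raw signal is out of scope). The discrete one-step rhythm at a knot
is defined as the successor-boundary difference
`T(t̃ₘ,ₖ, 1) = t̃ₘ₊₁,ₖ − t̃ₘ,ₖ`; the protocol gives no other access to
it, and this choice makes knot reproduction exact by construction.
Consecutive knot readings are joined by straight lines, giving one
affine segment per zone with slope
`gₘₖ = (T(t̃ₘ,ₖ₊₁,1) − T(t̃ₘ,ₖ,1)) / (t̃ₘ,ₖ₊₁ − t̃ₘ,ₖ)` and intercept
`bₘₖ = T(t̃ₘ,ₖ₊₁,1) − gₘₖ·t̃ₘ,ₖ₊₁`. Strict boundary monotonicity makes
every slope exceed −1, so `t + T̂(t,1)` is strictly increasing.

Key structural fact used throughout: each segment's shift map is the
affine bijection of zone `(m,k)` onto zone `(m+1,k)` that preserves the
normalized position `φ` within the zone. `T̂(t, n)` for any integer `n`
(including negative, i.e. the inverse map) is therefore evaluated as the
`φ`-preserving map onto zone `(m+n, k)`, which agrees exactly with the
recursive composition `T̂(t,n) = T̂(t,1) + T̂(t + T̂(t,1), n−1)` and
needs no root finding.

Numerical choices: intervals are half-open `[start, end)`; knots map to
knots by direct boundary lookup (machine-exact); one-step readings need
a successor cycle, so the interpolant's segments cover cycles `1..M−1`
and evaluation outside `[t̃₁,₁, t̃ₘ,₁]` (or with a target zone outside
the annotation) is a domain error rather than an extrapolation.
Minimality of the interpolant is a consequence of interpolating the true
discrete rhythm and is reported informationally, not re-checked.

## Preprocessing

Two Butterworth stages, as used on the original recordings: a 3rd-order
band-stop at the power-grid frequency (default edges 50 ± 2 Hz; the
bandwidth is a package choice, the source method states only center and
order) and a 5th-order 1–17 Hz bandpass. Default application is
zero-phase (forward–backward, which squares the magnitude response) so
that filter group delay cannot bias the cycle-phase alignment
downstream; a causal mode exists for streaming parity. Edge transients
are the caller's concern.

## Cycle-aligned estimation

Estimates live on a *phase grid*: by default the recording's own sample
times inside the chosen zone of cycle 1 (a 2 s zone at 250 Hz gives
~500 values). For grid point `t` and shift `n`, the signal is read at
`t + T̂(t, n)` by linear interpolation between adjacent samples —
order-consistent with the piecewise-linear rhythm — with snapping to
exact sample times within a 10⁻⁶ sample-period tolerance, so that
regular rhythms with integer samples per cycle reproduce naive epoch
averaging bit-exactly. Aligned times overrunning the recording's
coverage by less than one sample period read the final sample (boundary
rounding at fs); larger overruns are errors.

Normalizations follow the method as printed, including its asymmetry:
dispersion uses `1/M` while the `k`-th central moment uses `1/(M−1)`,
so `d̂ = ((M−1)/M)·d̂⁽²⁾` holds identically and is enforced by test.
Mean values at shifted arguments use the cyclic extension
`m̂(t + T(t,n)) := m̂(t)` — the estimate's own invariance under the
fitted rhythm. Mixed moments sum over `n = 0..M−M₁` with normalizations
`1/(M−M₁+1)` (initial) and `1/(M−M₁)` (central), where `M₁` is the
number of leading cycles containing the lag arguments. Lag arguments
are specified rhythm-independently: either tracking the grid point a
fixed number of cycles ahead (`SamePhaseLag`, the probe for inter-cycle
dependence; 0 cycles gives cross-channel same-instant moments) or as a
fixed offset from a cycle start (`FixedLag`), mapped through the rhythm
function. No bias corrections are applied beyond what the printed
normalizations imply, and no confidence intervals are produced.

## Spectral features and sensitivity

Each estimate on a uniform grid is transformed with a one-sided DFT (no
window or detrend; an optional mean-removal flag defaults off). Bin
energies carry one-sided weights so their total equals the time-domain
energy (Parseval, enforced at 10⁻⁹ relative). By Bessel's inequality
the energy of a truncated expansion is bounded by the total, so the
feature vector keeps the smallest prefix of magnitude coefficients whose
cumulative energy reaches the threshold (default 95%); `K` is minimal
and monotone in the threshold. Magnitudes (not complex pairs) of the
lowest-frequency bins, DC included, form the feature vector.

Sensitivity of a characteristic to the mental action is the mean
absolute distance between its activity-zone and passivity-zone
estimates. Zones of unequal duration are compared on a normalized-phase
grid of `L = min(len_a, len_b)` points via linear resampling (raw
estimate values, no normalization); spectra are compared over the first
`min` bins. The report rows are ordered with the higher-order moments
first, matching the convention of the published sensitivity tables.

## Simulator

The generator realizes the model exactly: one jittered annotation shared
by all channels (zone durations uniform in `d_k·[1±j]`), and per
channel/zone the signal `μ(φ) + s(φ)·ε + z` on normalized zone phase
`φ`, where `μ` and `s` are harmonic profiles, `ε` is unit-variance noise
and `z` an optional shared Gaussian component. Supported noise families
are Gaussian and centred exponential (the skewed family with closed
moments `μ₃ = 2s³`, `μ₄ = 9s⁴`); AR(1) dependence across the cycle
index at fixed phase is available for the Gaussian family only, since AR
mixing would not preserve the exponential marginal. Noise is drawn on a
fixed per-zone phase lattice (one cell per nominal sample) from streams
split per channel from the master seed, so enlarging `N` or `M` leaves
existing draws unchanged, and the `φ`-preserving rhythm map lands
aligned samples in the same lattice cell — making the AR(1) structure
visible to the estimators without approximation. Boundaries and cell
indices within floating-point error of the sample lattice are snapped to
it so that jitter-free configurations stay exact.

Defaults are the study conditions the package validates against: 3
channels, 50 cycles, 250 Hz, two 2 s zones (500-value zone estimates),
10% duration jitter, unit Gaussian noise; passivity mean 2.0 µV with a
slow wave, activity mean 2.5 µV with a faster wave.

What the simulator does *not* emulate: 1/f background, neural mass
dynamics, artifacts, or within-cycle noise correlation (distinct phases
are independent by default, which keeps the analytic ground truth
exact). Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not
robustness to real-EEG deviations from them.

## Validation problem sizes

The recovery checks use the smallest sizes at which the Monte-Carlo
tolerances are meaningful: mean recovery at the default 50 cycles
(RMSE ≤ 1.5σ/√M), dispersion at 200, fourth central moment at 1000,
AR(1) lag-one covariance at 500. Dispersion, fourth-moment and AR
recovery are run with zero duration jitter: linear interpolation at
fractional sample times averages adjacent independent noise samples and
damps their variance (by a factor `(1−α)² + α²` at interpolation
fraction `α`), a sampling artifact that would contaminate a
variance-recovery check; with a regular rhythm the aligned times are
exact samples and the estimator is assessed in isolation. Mean recovery,
the normalization identity, zone partition and the sensitivity checks
keep the default irregular rhythm.

## Known limitations

- Boundary annotations must come from the protocol; there is no
  data-driven cycle segmentation.
- The rhythm interpolant is piecewise linear; no spline option.
- Mixed-moment lag handling assumes the lag argument's cycle exists in
  the first `M₁` cycles, and `M₁ < M`.
- Multidimensional distribution and characteristic functions are model
  background only; they are enforced by construction in the simulator,
  not estimated.
- Classifier training and the interaction stage of a BCI pipeline are
  out of scope.
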