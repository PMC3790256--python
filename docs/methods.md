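# Methods

This note records the modeling conventions, parameter defaults and numerical
choices in `pnmkit`, and what the synthetic-data tests do and do not show.

## Physiological model

**Cardiac phase.** Pulse-oximeter peaks are detected by moving-average
smoothing (default width 0.1 s) followed by a local-maximum search with a
refractory period (default 0.4 s, a 150 bpm ceiling). Between consecutive
peaks p_k, p_{k+1} the phase is φc = 2π (t − p_k)/(p_{k+1} − p_k), resetting
to zero at each peak; times outside the peak span extrapolate with the
nearest interval length. Peak detection works on local maxima of the
smoothed waveform, not ECG R-waves; multi-lead ECG is out of scope.

**Respiratory phase.** φr = sign(dR/dt) · π · F(R(t)), where F is the
normalized cumulative histogram (default 100 bins) of the bellows amplitude
over the whole run, and the sign separates inspiration (+) from expiration
(−). This makes the phase depend on breathing depth as well as timing, and
leaves it invariant (up to bin resolution) under affine rescaling of the
bellows signal. The derivative sign comes from a centered difference of the
0.5 s-smoothed trace; derivatives within a relative dead-band of zero
inherit the previous sign, which suppresses sign chatter at breath extremes
and makes the sign decision scale-invariant.

**HR and RVT.** Heart rate at time t is 60 / (mean inter-peak interval
overlapping a window centered at t; default 6 s). RVT per breath is
(end-inspiration peak − preceding trough) / (time to the next peak), placed
at breath midpoints and linearly interpolated; edge times hold the nearest
value. Neither series is convolved with a cardiac- or respiratory-response
function: the raw interpolated series enter the design directly, which is a
documented limitation for latency-sensitive effects.

**Slice timing.** Phases are evaluated at each slice's true acquisition
time — volume trigger plus a within-TR offset of tr/n_slices per slice.
Consequently no slice-timing interpolation should be applied to the data.
The interleaved convention is odd-numbered slices (1-based) first, then
even; this is explicit and configurable because vendor conventions differ.
Simultaneously acquired slices (multiband) receive identical phases.
Per-slice triggers, if logged, can be used directly in a `SliceTiming`.

## Design matrix

Default configuration: cardiac order 4, respiratory order 4, interaction
orders 2×2 with sin/cos of both a·φc + b·φr and a·φc − b·φr (4 columns per
order pair), plus HR and RVT — 8 + 8 + 16 + 1 + 1 = **34 columns** per
slice. The interaction structure (sum and difference combinations) is a
convention: it is the decomposition consistent with the five regressor
families and the total of 34, and the sum/difference terms are exactly the
f_c ± f_r sidebands of cardio-respiratory coupling. A `harvey()` preset
gives the 3C4R1X brainstem model (3 cardiac + 4 respiratory orders + one
interaction set, 18 columns).

Columns are mean-centered and deliberately **not** orthogonalized: the GLM
then apportions shared variance among regressors, which is the conservative
behavior wanted for nuisance modeling. HR and RVT enter unlagged by default
(lags would require a response-function model we do not assume).

The FIR alternative replaces each Fourier set with per-cycle indicator bins
(default 10 per process). The raw bin matrix has exactly one 1 per row; in
the assembled design the last bin of each set is dropped, since a complete
indicator set sums to the intercept column and would make the GLM design
rank deficient. FIR bins ignore breathing depth — another reason the
Fourier basis is the default.

## GLM, DOF and model comparison

Voxelwise ordinary least squares against [intercept | nuisance columns].
Rank deficiency raises an error naming the implicated columns (from the
smallest right-singular vector). Prewhitening/autocorrelation modeling is
out of scope; residual autocorrelation is a known limitation for inference
on task regressors, not for the variance accounting done here.

Degrees of freedom follow the N − 1 − N_reg accounting with N_reg counting
the intercept ("dummy") regressor: 100 time points and 34 nuisance columns
give 100 − 1 − 35 = 64. The same convention sets the denominator DOF
(N − 1 − k1) of the nested F-test

F = ((RSS0 − RSS1)/(k1 − k0)) / (RSS1/(N − 1 − k1)),

referred to F(k1 − k0, N − 1 − k1). This accounting is one DOF more
conservative than the exact OLS residual count N − N_reg; at N = 100 the
effect on null rejection rates is below 0.1% (verified by simulation in the
test suite) and the conservative direction is the safe one for nuisance
modeling.

BIC uses the natural logarithm: BIC(k, N) = N·ln(RSS/N) + k·ln(N); the
pairwise comparison rule ln(RSS1/RSS2) < (k2 − k1)·ln(N)/N is algebraically
the same ordering (property-tested). RSS = 0 yields a −inf sentinel flagged
as a degenerate fit; ties never prefer the larger model. Voxelwise F-maps
get no multiplicity correction by default — the intended use is subjective
judgment of whether enough voxels in the region of interest benefit — but
an optional Benjamini–Hochberg rejection mask (`glm.fdr_threshold`) is
available for the returned p-maps.

## Noise metrics

Raw tSNR is mean/std with sample normalization (N − 1; a flag switches to
N). After cleanup the denominator is the DOF-corrected residual std
sqrt(RSS/DOF). With that correction, fitting pure white noise with random
irrelevant regressors leaves corrected ≈ raw tSNR on average (the expected
mean ratio is sqrt((N − 1 − N_reg)/(N − N_reg)) ≈ 0.994 at N = 100, 35
regressors — slightly conservative, never inflated). CV = 100·std/mean, so
cv × tsnr = 100 wherever both are defined. Ratio maps (corrected/raw) use a
default reporting threshold of 1.1, i.e. >10% improvement. Undefined voxels
(zero variance, zero mean, outside the mask) are NaN and excluded from
summaries.

## Analytic calculators

Physiological noise amplitude is taken ∝ B0² and thermal noise as
field-independent, so the physiological-to-thermal ratio changes by
(B0'/B0)² × (V'/V) between acquisitions; at fixed voxel volume 3 T → 7 T
gives (7/3)² ≈ 5.4, and the volume that restores the 3 T ratio at 7 T has
edge (V·(3/7)²)^(1/3) ≈ 1.7 mm for a 3 mm reference. The constant-voxel
assumption is explicit; tissue-specific λ-style models of the thermal/
physiological partition are not implemented. Aliasing: a frequency f
sampled at interval TR appears at |f − round(f·TR)/TR| ∈ [0, 1/(2·TR)].

## Synthetic data

The simulator emulates a resting multi-slice EPI study with 50 Hz
physiological logging. Defaults (chosen once as typical resting-adult
values at desk scale): heart 66 ± 3 bpm with a raised-cosine systolic bump
per beat; breathing period 4.0 ± 0.4 s with 15% depth jitter, raised-cosine
breaths; TR 3 s, 8 interleaved slices, 100 volumes, 16×16 in-plane;
baseline 100 with order-1 cardiac and respiratory amplitudes of 2.0 (2%
signal), second harmonics at half amplitude, multiplicative
cardio-respiratory interaction 0.8, Gaussian thermal noise σ = 1.0, ±1.0
linear drift, in a random half of the voxels (thermal noise and drift
everywhere). Injected components are locked to each voxel's true slice
time, so a 1.1 Hz cardiac signal sampled at TR 3 s aliases to 0.1 Hz
exactly as the analytic calculator predicts.

What passing tests show: the pipeline recovers injected amplitudes, raises
tSNR where noise was injected, and stays calibrated (no free-variance
inflation, nominal F-test size) under the model's own assumptions. What
they do not show: performance on real data, where physiological noise is
partly multiplicative, non-sinusoidal within cycles, spatially structured
(vessel/CSF geometry), and entangled with motion — none of which the
generator emulates.

## Numerical choices

- Peak/trough detection tolerances are one sample of the physiological
  clock (20 ms at 50 Hz).
- Trigger spacing must match the declared TR within 5% (configurable);
  violations report the offending interval.
- Phase upper bounds are half-open ([0, 2π)); float rounding at the
  boundary is clamped to 0.
- Histogram-equalized phase changes by at most π/n_bins under data
  perturbations smaller than a bin, which sets the natural tolerance for
  invariance checks.
- All simulation randomness flows from one integer seed through
  `numpy.random.default_rng`; identical parameters and seed give
  bit-identical traces, data and ground truth.
- Problem sizes in tests (16×16×8×100 default grid, 10⁴-voxel calibration
  batches) were chosen so the whole suite completes in seconds while
  keeping binomial/χ² error bars small enough for the stated tolerances.
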