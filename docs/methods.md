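# Methods

This note documents the models, numerical choices and design decisions
behind `cerebropdm`, and states precisely what the synthetic-data generator
does and does not emulate.

## 1. Laguerre-Volterra kernel estimation

**Model.** Flow velocity is a dual-input second-order Volterra series of BP
and end-tidal CO2 (see README for the expansion). Kernels are parameterized
on discrete orthonormal Laguerre functions b_j(m), j = 0..L−1, whose decay
is set by α ∈ (0, 1). The self-kernels kPP, kCC are symmetric, so only the
L(L+1)/2 coefficient pairs (j1, j2), j2 ≤ j1 are estimated (off-diagonal
basis products shared; the reconstructed kernel is symmetrized exactly).
The cross-kernel kPC has no symmetry and carries the full L×L coefficient
set. Total free parameters: 1 + 2L + L(L+1) + L² (66 at L = 5).

**Memory rule.** The kernel memory M is the smallest lag beyond which all
|b_j(m)| fall below a threshold ε, floored at L+1. The default ε = 2×10⁻⁵
makes the truncated basis orthonormal to better than 10⁻⁸ (a looser 10⁻⁴
leaves ≈1.4×10⁻⁸ of tail mass in the Gram matrix at α = 0.5, L = 5). At the
working point this gives M = 64 lags (64 s at 1 Hz).

**Estimation.** BP and CO2 are mean-removed (the constant k0 absorbs the
output mean), convolved with each basis function under a zero-prehistory
convention, and the first M−1 output samples (convolution burn-in) are
dropped. Coefficients solve the least-squares problem by LAPACK `lstsq`;
rank deficiency is an error, and fewer than 5 samples per parameter raises
an `IdentifiabilityWarning` (a 6-min record at L = 5 sits at ≈4.5). Product
columns are ordered lexicographically in (j1, j2) so coefficient vectors
are portable. Training NMSE is residual power over mean-removed output
power. Forward prediction is implemented twice — through the Laguerre
regressor and through lagged-input tensor contractions on the reconstructed
kernels — and the two paths agree to machine precision (tested).

## 2. Kernel spectra and VLF band power

First-order kernels are zero-padded to nfft = 1024 (≈0.001 Hz resolution at
1 Hz sampling, ≥30 bins below 0.03 Hz) and squared-magnitude spectra are
averaged over the band [0, 0.03) Hz, DC inclusive (the high-pass
preprocessing leaves negligible raw-signal power below 0.005 Hz; the band is
configurable and recorded in every output). Features are reported as log10
of the mean band power. Second-order kernels are summarized by the mean
squared magnitude of their 2-D DFT over the square f1, f2 ∈ [0, 0.03) Hz.

A non-obvious property that shaped the synthetic design: all discrete
Laguerre functions share the same spectral magnitude at every frequency
(they differ only by all-pass phase factors), so "slow" vs. "fast"
coefficients do not map onto VLF band power. The band power is a quadratic
form β'Q β whose eigenbasis (q1..q5 at L = 5) orders kernel shapes from
VLF-quiet (high-pass) to VLF-concentrated (slow); this eigenbasis is
exposed as `vlf_band_eigenbasis`.

## 3. Global PDMs and ANFs

Per treatment arm and input, the first-order kernel and the input-SD-scaled
columns of the second-order self-kernel of every subject × condition are
concatenated (pre blocks first) into Q, rows indexed by lag. The left
singular vectors of Q are the global PDMs, with a deterministic sign
convention (largest-magnitude element positive); H = 5 modes are kept by
default (selectable by BIC). Because every estimated kernel lies exactly in
the span of the L Laguerre functions, Q has rank ≤ L and the H = L modes
span that space exactly.

PDM filter outputs u_i(n) are causal convolutions of each (mean-removed)
input with its modes. Cross-terms u_{i,BP}·u_{j,CO2} are screened by the
Fisher-z (w-statistic) test on their correlation with the output: retained
iff |atanh r|·√(n−3) exceeds the two-sided normal quantile at the 99% level
(2.576). All cubic ANF polynomials of both inputs, retained cross-products
(each with its own coefficient) and a single global intercept are fitted in
one joint least-squares regression — the only reading under which the PDM
model "forms the system output". The ANF gain is the OLS slope of f_i
evaluated at the subject's own post-burn-in filter outputs, regressed on
those outputs: the gain is weighted by the subject's operating range rather
than a fixed abscissa.

## 4. Preprocessing

Chain (in this order, recorded in QC metadata): natural cubic-spline
resampling of beat/breath events to a uniform 1 Hz grid; iterative Grubbs
outlier removal at 0.95 significance (one sample at a time, flagged samples
replaced by spline interpolation over unflagged neighbors and not
re-tested — re-testing a replacement that remains the extremum would loop
forever); zero-phase (forward-backward) 5th-order Butterworth high-pass at
0.005 Hz; and a 5-sample trim at each end, honoring the protocol's literal
"filter length" trim (a config option allows longer trims).

**Known limitation.** A 0.005 Hz filter has a transient spanning roughly
200 s. On 6-min records the filter therefore does not commute with the
system convolution: applying it to all three channels perturbs the
input-output relation by ≈24% of flow RMS (≈5% of in-band power),
concentrated in the VLF — precisely the biomarker band — and inflates VLF
kernel-feature errors from ≈0.13 to ≈0.35 log10 units with occasional
≈1-unit outliers. The chain is appropriate for removing genuine baseline
wander from raw instrumented recordings, and its steady-state behavior is
verified on hour-long records; for drift-free data (such as the default
synthetic cohort) it should be skipped (`preprocess=False`), which is how
the cohort-level validation below is run. With the corruption layer enabled
and the full chain applied, the blockade arm still separates with median
LDA accuracy ≈0.94, but single-point outliers reduce the *complete*
separation rate to ≈36% of cohorts.

## 5. Synthetic cohort generator

The generator is the stand-in for the study's undeposited recordings. Per
arm (sympathetic blockade, placebo) it simulates 9 subjects × 2 conditions
of 6-min, 1 Hz records. Defaults, with units and rationale:

* **Inputs.** BP = 1/f VLF noise (exponent 1) + band-pass resonance at
  0.1 Hz (Mayer wave, bandwidth 0.06 Hz) + white noise, variance shares
  0.45/0.30/0.25, SD 3 mmHg around a 75 mmHg mean. CO2 = second-order
  low-pass noise (0.02 Hz corner, i.e. slow drifting CO2 dynamics) + 5%
  white, SD 1.5 mmHg around 38 mmHg. Realizations are random-phase
  syntheses of these fixed spectral envelopes, so each record carries the
  exact target spectrum (persistent vasomotor VLF power; a free-amplitude
  realization can have near-zero VLF excitation by chance, which makes the
  slow kernel coordinates unidentifiable). Inputs are exactly demeaned and
  scaled, so the estimator's mean-removal is a no-op and noise-free
  coefficient recovery is exact to machine precision.
* **Systems.** Per-subject coefficients are drawn around fixed templates in
  the VLF band eigenbasis. The BP template is high-pass-like (dominant
  VLF-quiet q1 component) with a moderate slow-mode (q5) coordinate;
  the CO2 template is low-pass-like. Inter-subject variability is
  anisotropic and bounded (signed uniform 0.85–1.15× magnitudes) along two
  VLF-quiet directions, chosen so the stacked-kernel SVD has a stable,
  interpretable mode order at n = 9 — mode 1 mean shape, mode 2 dominant
  shape variability, mode 3 the blockade displacement, mode 4 a weaker
  variability direction, mode 5 the residual of the 5-dim span. Gaussian
  jitter at this sample size concentrates a mode's variance in single
  subjects and destabilizes leave-one-out mode extraction; bounded
  magnitudes keep every subject's share below ~15%. Second-order
  coefficients are small (nonlinear flow contribution ~5–10% of linear).
* **Blockade effect** (sympathetic arm, post condition): the slow-mode
  (q5/q4) BP coordinates scale up by kP_vlf_scale_post × gain-shift factors
  (defaults 4.64 × 1.25 / 1.08, ≈1.5 log10 units of VLF kernel power), CO2
  slow-mode coordinates scale down by 0.20, with 5% lognormal per-subject
  spread of the excess; second-order self-terms carry only a modest
  sub-significance trend (×1.3 / ×0.8). Effect sizes were fixed once from a
  power analysis against the measured kernel-estimation noise of a 6-min
  record at the default 10 dB SNR, to reproduce the complete-separation
  regime reported for the real cohort on log-scale features. Both arms get
  a small pre-to-post coefficient drift (30% of inter-subject jitter,
  non-pharmacological time effects); the placebo arm gets nothing else.
* **Noise.** Output SNR 10 dB, defined on the mean-removed noiseless flow.
* **Corruption layer** (opt-in, `add_artifacts=True`): instrument baseline
  wander below 0.005 Hz plus sporadic 6–10 SD spikes on all channels, the
  inputs the preprocessing chain exists to clean.
* **Reproducibility.** One root seed; named substreams per subject,
  condition and role (coefficients, inputs, noise, artifacts). Coefficient
  substreams ignore the arm, so pre-condition systems are identical across
  arms at a given seed and the blockade effect is purely the post-condition
  rescaling. `out_of_basis_tail` adds a delayed flow component outside the
  Laguerre span for robustness studies.

**What passing tests show about real data — and what they do not.** The
generator's truth is exactly representable by the estimator, so recovery
and separation results validate the implementation and the statistical
power of the biomarkers under the modeled conditions; they do not show that
real cerebral hemodynamics are second-order Volterra systems, that real
effect sizes match the defaults, or that model mismatch (beyond the
optional out-of-basis tail) is harmless. The generator is a statistical
emulator, not a biophysical (Windkessel/ODE) model, and its flow-variance
changes under blockade are stylized.

## 6. Cohort-level analysis

* **LOSO validation.** For each held-out subject, global PDMs are extracted
  from the other N−1 subjects' kernels (both conditions) of the same arm,
  and the held-out subject's ANFs/gains are fitted with those modes; the
  biomarker table uses these held-out gains.
* **Mode stability.** On the default cohort, dropping any one subject
  changes none of the five blockade-arm BP modes by more than cosine 0.9
  (default seed: min cosine 0.985; ~85–90% of seeds pass). The CO2 and
  placebo stacks are stable only in their leading ~3 modes: their trailing
  singular values sit at the estimation-noise floor, an intrinsic n = 9
  limitation worth knowing before interpreting high-order modes of small
  cohorts.
* **BIC selection.** Cohort-summed Gaussian BIC, n ln(RSS/n) + k ln n per
  recording, with RSS from the subject-level PDM/ANF regression and k the
  total per-subject free-parameter count (kernel expansion + ANF
  regression); ties break toward smaller k. Unidentifiable grid points are
  skipped with a log record.
* **Separation.** Fisher LDA on two named features, classes pre vs. post
  within an arm; singular within-class scatter falls back to the class-mean
  difference direction (logged). Complete separation ⇔ every point on the
  correct side of the midpoint threshold.
* **2×2 statistics.** Paired t within arms; the condition × group
  interaction as a two-sample t on per-subject (post − pre) differences —
  the exact interaction contrast for the balanced repeated design, keeping
  the headline statistics free of mixed-model machinery.

## 7. Problem sizes used in validation

The test suite and `scripts/acceptance.py` use the study-scale conditions
throughout: 6-min (360-sample) records, 9 + 9 subjects, SNR 10 dB, with 25
simulated cohorts for separation rates, 50 records for kernel-accuracy
medians, and a few hundred replicates for the screening/power calibrations.
Representative recomputed values (seed 1): noise-free coefficient recovery
2×10⁻¹⁴; median BP-kernel NMSE at 10 dB ≈ 0.003; blockade complete
separation in 92% (gain plane) and 100% (VLF plane) of cohorts with placebo
at 0% and mean placebo LDA accuracy ≈0.59; null cross-term retention 0.8%
against the nominal 1%; interaction-test power within Monte-Carlo error of
the noncentral-t value.
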