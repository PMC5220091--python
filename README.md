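# cerebropdm

Nonlinear system identification of cerebral hemodynamics: Laguerre-Volterra
kernel estimation, global principal dynamic modes (PDMs), and functional
biomarkers of sympathetic cerebrovascular control.

## The problem

Cerebral blood flow is actively regulated against spontaneous fluctuations
in arterial blood pressure (BP) and arterial CO2. Whether that regulation
is intact — e.g. after stroke, traumatic brain injury or autonomic failure —
is hard to read off conventional linear transfer-function indices, because
the interesting physiology is nonlinear and concentrated at very low
frequencies (VLF, < 0.03 Hz). This package implements a modelling pipeline
for resting recordings of beat-to-beat mean BP (mmHg), breath-to-breath
end-tidal CO2 (mmHg) and transcranial-Doppler flow velocity in the middle
cerebral artery (MCAv, cm/s), and derives candidate biomarkers that
discriminate intact from pharmacologically blocked sympathetic control.

## The model

The flow output F(n) is a dual-input second-order Volterra series of the
BP input P(n) and CO2 input C(n):

    F(n) = k0 + Σ_m kP(m) P(n−m) + Σ_m kC(m) C(n−m)
         + Σ_{m1,m2} kPP(m1,m2) P(n−m1) P(n−m2)
         + Σ_{m1,m2} kCC(m1,m2) C(n−m1) C(n−m2)
         + Σ_{m1,m2} kPC(m1,m2) P(n−m1) C(n−m2) + ε(n)

Kernels are expanded on L discrete orthonormal Laguerre functions b_j(m)
with decay parameter α, and the expansion coefficients are estimated by
ordinary least squares; at the working point α = 0.5, L = 5 the regression
has 66 free parameters, matched to ~350 usable samples of a 6-min 1 Hz
record. First- and second-order self-kernels of all subjects are stacked
into a matrix Q whose left singular vectors are the cohort-level **global
PDMs** g_i — a common filter bank. Each subject's flow is then modelled as
a sum of cubic **associated nonlinear functions** (ANFs)
f_i(u) = a1 u + a2 u² + a3 u³ applied to the PDM filter outputs, plus
significance-screened cross-products between BP and CO2 branches.

Two biomarker planes are computed per subject and condition:

* log10 mean spectral power of kP and kC over the < 0.03 Hz band,
* the slopes ("gains") of the best linear fits to the ANFs of the 3rd and
  4th global BP modes.

A Fisher linear discriminant separates pre- from post-treatment points in
each plane; paired t-tests and a condition-by-group difference-in-
differences t-test provide the 2x2 statistics.

Because the original cohort recordings are not publicly deposited, the
package includes a first-class synthetic-cohort generator with fully known
ground truth (see `docs/methods.md`) that emulates the study design: two
arms (sympathetic blockade / placebo) of 9 subjects, 6-min 1 Hz records,
and a blockade effect that raises VLF BP-kernel power, lowers VLF
CO2-kernel power and shifts the slow-mode ANF gains.

## Worked example

```python
import cerebropdm as c

cohort = c.simulate_cohort(c.SimulationConfig(seed=1))
res = c.LaguerreVolterraModel.from_recording(cohort.recordings[0]).fit()
print(res.summary())
```

```
Laguerre-Volterra model (dual input, second order)
====================================================
samples (post burn-in):    297
free parameters:            66
alpha / L / M:          0.5 / 5 / 64
training NMSE:             0.0670
condition number:             693
k0 (constant):            65.3062

first-order coefficients (j = 0..L-1):
  beta_P: [0.942  1.6218 1.7336 0.0755 0.0621]
  beta_C: [ 0.4732 -0.1614  0.0678  0.1561  0.137 ]
```

The training NMSE of 0.067 says the 66-parameter model explains ~93% of the
mean-removed flow variance (the record was simulated at 10 dB output SNR,
so ~0.09 is the noise floor); `k0` absorbs the 65 cm/s mean flow velocity.
The cohort-level analysis — kernels, spectra, group PDMs, leave-one-
subject-out (LOSO) ANF gains, separation and statistics — runs in one call:

```python
study = c.run_study(cohort.recordings, preprocess=False)  # records are drift-free
print(study.summary())
```

```
Cerebral-hemodynamics PDM biomarker study
====================================================
recordings analyzed:   36
hyperparameters:       alpha=0.5, L=5, M=64, H=5, ANF order=3
VLF band:              (0.0, 0.03) Hz (nfft=1024)

pre/post separation (Fisher LDA):
  placebo      kP_vlf_logpower+kC_vlf_logpower          accuracy=0.556 complete=False
  placebo      gain_pdm3_bp+gain_pdm4_bp                accuracy=0.722 complete=False
  sympathetic  kP_vlf_logpower+kC_vlf_logpower          accuracy=1.000 complete=True
  sympathetic  gain_pdm3_bp+gain_pdm4_bp                accuracy=1.000 complete=True

paired / interaction tests:
  kP_vlf_logpower        t_symp=+19.39 (p=5.2e-08)  t_plac=+0.16 (p=0.87)  interaction t=+11.97 (p=2.1e-09)
  kC_vlf_logpower        t_symp=-4.05 (p=0.0037)  t_plac=+0.76 (p=0.47)  interaction t=-3.81 (p=0.0015)
  gain_pdm3_bp           t_symp=+31.21 (p=1.2e-09)  t_plac=-2.37 (p=0.045)  interaction t=+26.46 (p=1.2e-14)
  gain_pdm4_bp           t_symp=+0.13 (p=0.9)  t_plac=-1.86 (p=0.1)  interaction t=+0.88 (p=0.39)
```

The blockade arm separates completely in both biomarker planes while the
placebo arm stays near chance — the qualitative signature the biomarkers
are designed to detect.

A command-line interface mirrors the library
(`cerebropdm simulate / kernels / run-all / select`); raw recordings are
exchanged as per-subject CSV files (`time_s, bp_mmHg, mcav_cm_s,
petco2_mmHg`) with a cohort manifest, so real and synthetic data are
interchangeable. Recordings with baseline wander and measurement spikes
should first pass the preprocessing chain (cubic-spline resampling to 1 Hz,
iterative Grubbs artifact removal, zero-phase 0.005 Hz high-pass, 5-sample
edge trim), which `run_study` applies by default.

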