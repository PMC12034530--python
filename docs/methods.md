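# Methods

This note documents the models behind `nirsfusion`, the defaults they use,
and the design choices made where the underlying study left the method
open.

## Signal model and preprocessing

Raw data are light intensities I(λ, t) at 730 and 850 nm per
source–detector channel, sampled at 20 Hz. Optical density change is
ΔOD = −ln(I/I₀), with I₀ the mean intensity over a baseline window (whole
recording by default; a pre-stimulus window can be supplied, and an
additive OD offset is harmless downstream because the GLM carries a
constant regressor and the band-pass removes DC). The modified
Beer–Lambert law relates OD to chromophore changes,

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · L · DPF,

inverted per channel as a 2×2 linear solve. Defaults: differential
pathlength factor DPF = 6 (wavelength-independent, as a single value was
specified); source–detector separation L = 30 mm per channel (a standard
adult prefrontal montage spacing — the instrument's true separations were
not reported), configurable per channel through the montage; extinction
coefficients at 730/850 nm from a standard spectra compilation
(cm⁻¹/µM: 730 nm → HbO 3.90e-4, HbR 1.1022e-3; 850 nm → HbO 1.058e-3,
HbR 6.9132e-4), overridable via config. OD is defined with the natural
logarithm; since the same extinction table is used in the forward and
inverse directions, the convention cancels in round trips and only scales
β by a constant shared across conditions.

The preprocessing chain is fixed to Exclude → Motion → Filter → Hemo; a
config requesting another order is rejected.

**Motion artifacts.** The detection rule in the source study ("range in a
0.5 s window exceeding six times …") is ambiguous; it is implemented in
the Homer-style reading: a sliding 0.5 s window is flagged when its
max − min exceeds `std_thr = 6` times a standard-deviation reference
(whole-channel SD by default, a moving SD optionally), applied to raw
intensity, or when its max − min on optical density exceeds
`amp_thr = 0.5`. Flags are unions of whole windows. This is a documented
interpretation, not a claim of bit-compatibility with the vendor software.
Correction is spline-based by default (hard removal is a config option):
within each flagged segment a cubic spline through dense (~0.05 s) knots
models the artifact trend — dense knots are needed so that 0.1–0.3 s
spikes are tracked, not only slow baseline shifts — the trend is
subtracted, and the residual is re-levelled onto the line joining the
neighbouring clean samples (one-sided at series boundaries). Although the
study describes flagged data as "removed", spline correction preserves the
timeline that the block-design GLM and the per-condition connectivity
windows rely on, which is why it is the default.

**Filtering.** Zero-phase band-pass 0.01–0.2 Hz, realized as a 3rd-order
Butterworth in second-order sections applied forward–backward
(`sosfiltfilt`). Measured behaviour (asserted in tests): gain within 5% of
unity at 0.05 Hz, ≥ 20 dB attenuation at the 1.2 Hz cardiac line and at
0.001 Hz drift, zero group delay. HbO feeds all downstream analysis (the
study's GLM is stated on oxyhemoglobin); HbR is carried through and
selectable.

## Functional connectivity

Per condition, samples of all blocks of that condition are concatenated
(the three gray blocks of the long-block protocol pool into one estimate,
matching the one-value-per-participant reporting), the 14×14 Pearson
matrix is computed, and r̄ is the signed mean of the 91 off-diagonal pairs
— no absolute value, no Fisher z before averaging (z-averaging exists as
an option but is off, since the summary statistic is defined on raw r).

## GLM

The double-gamma HRF uses the canonical parameters a₁=6, b₁=1, a₂=16,
b₂=1, c=1/6 (the study invokes "a standard HRF" without numbers): the
positive lobe is a gamma density peaking at (a₁−1)b₁ = 5 s and
integrating to 1, minus a c-scaled undershoot. Condition regressors are
unit boxcars over each condition's blocks convolved with the HRF; the gray
baseline is the implicit reference (the study reports β only for the two
stimulus conditions). Constant and linear drift columns (Legendre basis)
are included — not mentioned in the study but necessary for a sane fit —
and the drift order is configurable. Estimation is plain per-channel OLS
(no prewhitening, matching the stated model). When the data have been
band-pass filtered, the same zero-phase filter can be applied to the
condition regressors (`bandpass=` in `build_design_matrix`); this is
standard temporal-filtering practice and is what makes the noiseless
round-trip recover injected amplitudes to 1e-6 rather than a
filter-attenuation-biased value. β carries the units of Y (µM here); the
published β magnitudes reflect the vendor software's internal scaling, so
no unit-level match of raw-data β values is claimed — the published
coefficient tables are shipped as fixtures and are the ground truth for
the statistics layer.

## Statistics

* **Friedman:** average within-subject ranks, χ²_F without the
  tie-correction factor (as the source formula is printed; a corrected
  variant sits behind a flag), p from the χ²(k−1) survival function.
* **Exact Wilcoxon:** zero differences dropped, average ranks on ties,
  W = min(W⁺, W⁻). The exact two-sided p enumerates all 2ⁿ sign
  assignments via a subset-sum dynamic program on doubled ranks (exact up
  to n = 25, normal approximation with tie correction beyond);
  p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))). At the study's n = 12 this
  reproduces every published corrected p-value exactly, which is why the
  exact (not approximate) test is the default.
* **BH-FDR:** step-up with critical values (i/m)·α, plus the equivalent
  monotone adjusted p-values; the significance set equals
  {adjusted p ≤ α} (property-tested).
* **Effect size:** paired Cohen's d with the population (÷n) SD of
  differences — this convention reproduces the published d values
  (sample-SD gives e.g. 1.23 instead of 1.28 on the key channel), whereas
  descriptive SDs of printed tables use the sample (÷(n−1)) convention;
  both conventions are verified against the fixtures by recomputation.
* **Power:** the study does not name its power model; a two-sided paired
  t-test via the noncentral t distribution (df = n−1, ncp = d√n) is used
  because it reproduces the published 0.92/0.98/0.98 within ±0.01. Two
  published cells are reproducible only to that tolerance rather than at
  printed precision (the CH14 effect size computes to 1.356, printing as
  1.36 vs the published 1.35, and its power to 0.989 vs the published
  0.98), so the golden-value check compares d/power with |Δ| ≤ 0.015 and
  everything else at printed precision. The study's Friedman post-hoc
  power (0.88) has no stated method and is not reproduced.
* Reported roundings use half-up ties (one published reaction-time mean,
  1.125 → 1.13, is only consistent with half-up). Four of the twelve
  published reaction-time SDs are inconsistent with their own printed
  per-trial values under either SD convention; the fixtures keep the
  printed numbers verbatim and only the means are asserted.

## Synthetic sessions

The generator emulates the two experimental designs: a single-trial
long-block protocol (five 90 s blocks, gray/fusion/gray/rivalry/gray) and
eight counterbalanced trials of 10 s blocks in which fusion and rivalry
each occur once per trial in seeded random order. Per channel, true HbO is

    Σ_cond β_cond · (boxcar ⊛ HRF) + λ_cond(t) · latent(t) + physio + drift + noise,

with HbR = −⅓·HbO. The shared latent drive is low-pass-filtered
(0.01–0.15 Hz) unit-SD Gaussian noise scaled to 0.5 µM and mixed with a
condition-dependent weight λ — the simplest mechanism that makes the mean
connectivity strength controllably condition-ordered. Defaults encode the
study's observed structure: λ fusion/rivalry/gray = 0.8/0.4/0.1, response
amplitudes β fusion/rivalry = 1.0/0.5 µM (typical evoked-HbO magnitudes),
white noise SD 0.3 µM, cardiac/respiratory/Mayer sinusoids at
1.2/0.3/0.1 Hz with amplitudes 0.2/0.1/0.1 µM and per-channel random
phase, linear drift 0.005 µM/s, motion artifacts at 0.5/min (spikes
±10·SD(OD) for 0.1–0.3 s; baseline shifts ±5·SD(OD) persisting to the end
of the enclosing block — the two shapes exercise both detection rules).
Optional keypress events with Gaussian latency model the rivalry-detection
task.

What the generator does *not* emulate: optical photon transport (the
forward model is the Beer–Lambert law only), instrument-specific baseline
intensities and separations, superficial/systemic physiology beyond
sinusoids, HbR dynamics independent of HbO, or perceptual variability in
rivalry onset. Passing tests therefore demonstrate that the pipeline
recovers the structure this model injects at realistic SNR — not that the
published group-level tables could be regenerated from the instrument's
raw recordings, which would require the vendor's exact settings and the
external data deposit and is explicitly out of scope.

## Numerical and testing choices

Problem sizes keep the default suite fast while leaving Monte-Carlo
margins comfortable: 20-seed checks for orderings (19/20 required),
50-seed checks for estimator bias (<10% asserted, ~1–2% observed), 500
global-null replicates for false-positive control (bound 0.07 against a
true rate ≈ 0.048, computed exactly from the discrete null), 2000
replicates for test size. Exact-test null distributions are cached by rank
multiset. Degenerate inputs: constant channels cannot trigger the
SD-based motion rule (guarded at SD < 1e-12); all-zero paired differences
raise rather than return a p-value; zero-variance channels abort the
correlation with the offending index named. Determinism: every stochastic
component takes a single integer seed through `numpy.random.default_rng`;
identical inputs give bit-identical sessions.

## Known limitations

* The motion-artifact rule is an interpretation of an ambiguous
  description (see above); thresholds match the stated values.
* No short-separation regression, PCA/ICA or wavelet denoising — the
  study used none.
* No SNIRF reader; plain CSV/TSV/JSON are the interchange formats.
* Graph-theoretic connectivity metrics beyond r̄ are out of scope.
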