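# Methods

This note documents the models, estimators and numerical choices behind
`ringtex`, and what the synthetic data generator does and does not emulate.

## 1. Force-cycle model and ringing-mode extraction

Each pixel of a sub-resonance force-curve scan is one approach–retract
cycle: baseline (A), contact (B), linear loading to the maximum force (C),
retract into the adhesion well down to the adhesion force `F_adh` (D),
rapid detachment, and free damped oscillation of the cantilever at its
resonance (F). Treating the post-detachment motion as a free damped
harmonic oscillator,

    F(t) = A · exp(−(t − t_d)/τ) · cos(2π f (t − t_d) + φ) + c,
    τ = Q / (π f0),

the force on the cantilever at the instant of complete detachment (E) —
the **restored adhesion** `F_rest` — is recovered by back-extrapolating the
fit to the detachment time `t_d`. The **viscoelastic adhesion** is
`F_adh − F_rest`, the force deficit caused by energy lost to inelastic
deformation during detachment; it is clamped at zero (with a flag) when
noise pushes the fitted `F_rest` marginally above `F_adh`.

Two estimators are reported per pixel:

* `adhesion_minimum` — magnitude of the single-sample retract minimum.
  Kept deliberately: one sample inherits the full measurement noise, and
  on synthetic cycles with 0.1 nN white noise it is biased high by roughly
  the noise sd (≈0.2 nN at 2 nN adhesion).
* `restored_adhesion_fit` — trust-region least squares of the damped
  cosine over the whole ringing segment. On the same noisy cycles its mean
  error is ≈4× smaller than the single-point minimum and its bias is
  within the noise floor. Error decreases with the number of ringing
  samples, approximately as 1/√N until a small systematic floor set by
  detachment-time localisation.

Numerical choices that matter:

* **Detachment localisation.** The adhesion well is shallow relative to
  pixel noise, so a bare argmin wanders along the retract ramp. The
  ringing itself is the sharp landmark: a matched filter (complex
  demodulation at the ringing frequency, one-period boxcar) localises the
  oscillation onset to within a period; the detachment sample is then the
  first force step exceeding 5× the local noise sd in that neighbourhood
  (the D→E discontinuity), falling back to the onset estimate when no
  step stands out (elastic samples, where `F_adh = F_rest` and the trace
  is continuous).
* **Phase snap.** The cantilever detaches from rest relative to its
  oscillation, so detachment coincides with a phase turning point. The
  restored force is therefore the fitted envelope evaluated at the turning
  point nearest `t_d` (equivalently `|A cos φ|` after snapping `φ` to 0
  mod π). This makes the estimate insensitive to sub-period error in
  `t_d`; the raw phase-sensitive evaluation would convert a few samples of
  segmentation error into tens of percent of amplitude error.
* **Fit initialisation.** Segment frequency from the periodogram peak with
  parabolic interpolation, envelope amplitude/decay from a linear fit to
  the log demodulated envelope, phase from the demodulated argument.
  The frequency is bounded within half a mode spacing (1/2T) of the
  periodogram estimate so the optimiser cannot hop cycle counts. Fits with
  fewer than 3 oscillation periods or residual > 20% of the amplitude are
  flagged unreliable; flagged pixels are filled by the median of their
  valid 4-neighbours in map assembly, with the QC mask preserved.

## 2. Cantilever calibration

Deflection sensitivity (nm/V) is the inverse slope of photodetector signal
versus z-displacement on a rigid substrate, fitted on the longest
contiguous contact segment whose local slope (Savitzky–Golay derivative,
window ≈ 1/8 of the contact region) stays within 10% of the median contact
slope; the smoothing half-width is trimmed from both ends before the final
least-squares slope.

The spring constant uses the thermal method: Welch PSD of free thermally
driven deflection (Hann window, 50% overlap, segment duration 8.2 ms —
2^13 samples at 1 MHz — chosen by frequency resolution so the result is
independent of sampling rate), fitted in log space with an SHO resonance
plus white baseline. All four parameters are fitted as logarithms: the
baseline can lie many decades below the resonance tails, and a
linear-parameter fit stalls there. Equipartition closes the calibration:

    ⟨z²⟩ = π A f0 Q / 2   (area of the fitted SHO component),
    k = k_B T / ⟨z²⟩.

Temperature defaults to 295 K. The hydrodynamic (plan-view geometry)
variant of the method is out of scope; the equipartition closure is the
one implemented. On synthetic traces the recovered k has < 1% bias and
≈1.5% RMSE at 2^18 samples; a white-noise-only record (no resolvable
resonance peak above the baseline) is rejected with a diagnostic.

## 3. Surface maps and QC

Height maps are pre-normalised by removing the least-squares plane (origin
and tilt are instrumental); adhesion channels are used as recorded, their
values treated as "effective height" in all parameter formulas. The visual
artifact screen of the original protocol is replaced by three automated
proxies — largest adjacent-row-median jump in units of map RMS (scan-line
artifacts), fraction of pixels beyond 6 MAD (spikes/debris), fraction of
pixels pinned at the extreme value (range clipping) — with default
thresholds 1.0, 0.01, 0.001. These proxies and thresholds are this
package's own operationalisation of a manual step.

## 4. Spectral texture indices

The DC-centred 2D amplitude spectrum (mean subtraction, no window by
default; a Hann option exists) is reduced two ways, both over the off-DC
upper half-plane (Hermitian symmetry makes the lower half redundant):

* **Angular spectrum** A(i), i = 0…M−1: each pixel is assigned to the
  nearest of M equiangular lines α_i = i·π/M and amplitudes are summed per
  line. Sector sums (rather than interpolated line integrals) are the
  default because they conserve total amplitude exactly and admit a direct
  per-pixel oracle; an interpolated-line mode is provided.
* **Radial spectrum** β(r), r = 1…M/2−1: pixels binned by rounded integer
  radius; radii beyond M/2−1 (corners, Nyquist row) are discarded.

Indices:

* `S_tdi = mean(A)/max(A)` ∈ (0,1]: → 1 with no dominant direction, → 0
  under strong directionality.
* `S_rwi = mean(β)/max(β)` ∈ (0,1]: near 0 when one wavelength dominates.
  Note that because β sums amplitudes over semicircles whose population
  grows ∝ r, a white (per-pixel-flat) spectrum gives β ∝ r and
  S_rwi → ≈0.5, not → 1; the index still separates cleanly from the
  single-wavelength regime (≈0.03).
* `S_hw = δx(M−1)/(2 r₀.₅)`, with r₀.₅ the linearly interpolated radius
  where the cumulative radial spectrum reaches half its total. The factor
  2 makes a pure sinusoid of wavelength λ give λ/2 ("average half
  wavelength"); a switch disables the halving. The cumulative is
  interpolated piecewise-linearly with β_i(0) = 0, so for a single-bin
  spectrum at radius r the crossing lands at r − 0.5 (half-bin
  interpolation slack).

## 5. The 37-parameter suite

Exactly 37 named areal parameters in four families, in the spirit of
ISO 25178-2 / ISO 4287 as popularised by SPIP-style surface analysis. The
precise identities of the original suite are not public; this registry is
the package's documented default with the count pinned at 37. Bit-exact
replication of any commercial implementation is a non-goal.

* amplitude (9): Smean, Sa, Sq, Ssk, Sku (non-excess; Gaussian → 3), Sp,
  Sv, Sz, S10z (mean of 5 highest 8-neighbour local maxima minus mean of 5
  lowest local minima).
* spatial (9): Sal and Str20/Str37 from the FFT autocorrelation sampled
  along 180 rays (fastest/slowest decay below thresholds 0.2 and 0.37),
  Std (argmax angle of the angular spectrum, degrees from the +x frequency
  axis, wave-vector convention), Stdi, Srw (wavelength at argmax β),
  Srwi, Shw, Sfd (spectral-slope fractal dimension, D = 4 + slope of
  log mean amplitude per radius vs log r, clipped to [2,3]).
* hybrid (7): Sdq (RMS gradient, `np.gradient`), Sdq6 (6th-order
  central-difference stencil), Sdr (developed area excess, %), Ssc (mean
  summit curvature), Sds (summits per µm²), S2A (projected area), S3A
  (developed 3D area).
* functional (12): bearing-curve (Abbott–Firestone) indices Sbi, Sci, Svi;
  the core-roughness construction Sk, Spk, Svk, Smr1, Smr2 (minimum-slope
  40%-width secant extended to bearing fractions 0 and 1); and section
  height differences Sdc0-5, Sdc5-10, Sdc10-50, Sdc50-95.

Undefined values (e.g. Ssk of a constant map) are reported as NaN and
propagate as missing through the statistics.

## 6. Synthetic data generator

The generator defines the study conditions; no instrument data ship with
the package.

**Force cycles** use linear loading/retract ramps at the force rate implied
by approach speed × contact stiffness, an instantaneous snap-off at D, and
a damped cosine whose initial phase puts the force at detachment exactly at
−F_rest. Defaults: k = 0.4 N/m, f0 = 75 kHz (midpoint of the 70–80 kHz
probe band), Q = 100 (air), 2 MHz sampling, 2 nN maximum load.

**Thermal traces** are synthesised in the frequency domain with the
deterministic SHO amplitude profile and uniform random phases, then
variance-matched exactly to k_B·T/k. A conventional complex-Gaussian
synthesis was rejected: with Q = 100 the resonance contains so few
statistically independent bins that the sample variance of a single
realisation scatters by ~15–20%, which no estimator can undo; the
phase-randomised surrogate has the same smooth PSD and makes equipartition
hold per-realisation, which is what a calibration test needs.

**Cell surfaces** are a two-component random field on a 256×256, 20 nm/px
grid (5×5 µm²):

* a *fold field* — band-limited around `fold_wavelength` (log-Gaussian
  radial envelope, σ_ln r = 0.35) with angular concentration
  `fold_anisotropy` about a per-cell random direction — the smooth,
  oriented membrane folds of a resting cell;
* a *grain field* — symmetric-amplitude Gaussian bumps (radius 120 nm,
  base density 60 µm⁻², count ∝ 0.2 + 0.8·a) — the granular structure that
  develops on activation.

The map is `(1−a)·fold + a·grain` at activation level `a ∈ [0,1]`, plus
white pixel noise (1% of the target RMS), rescaled to the target RMS
exactly (before the optional plane tilt), so the activation knob changes
the spatial structure of the map but not its amplitude statistics. The
grain radius was deliberately chosen so the grain field's power-domain
moments (gradient content, kurtosis, bearing-curve shape) approximately
match the fold field's: activation then expresses itself predominantly in
the amplitude-spectrum shape that the three spatial indices read, rather
than in every roughness statistic at once. Symmetric bump amplitudes keep
skewness near zero at all activation levels.

**Activation kinetics**: `a(t) = 1 − exp(−t/τ)` with τ = 10 min, so the
surface change is essentially complete by 30 min (a(30) ≈ 0.95) and nearly
half-complete by the first observation at 5 min — consistent with changes
being detectable within 10 min. Cohorts are cross-sectional: independent
cells per time point {5, 10, 30, 60, 120} min plus two control cohorts at
a = 0 (`CTR 0m`, `CTR 120m`), 20 cells each by default. Channels per cell:
restored adhesion (activation-responsive), viscoelastic adhesion (same,
with 2× pixel noise, mirroring its lower map quality), and height
(structure pinned at a = 0 with a random instrumental tilt, so the
tilt-removed height spectra carry no activation trend).

**Cell-to-cell variability** (invented; no measured spreads exist):
log-normal spreads of 15% on fold wavelength, 12% on grain radius, 15% on
grain density, 30% on pixel noise; fold direction uniform per cell;
anisotropy jittered ±0.1. All randomness derives from one integer seed via
spawned child sequences, so every cohort is reproducible.

What the generator does **not** emulate: tip convolution, contact
mechanics beyond linear loading, scanner drift/creep, correlated line
noise, cell-edge curvature (maps are "central region on the cell" by
construction), and any biochemical identity for the grains. Passing tests
therefore demonstrate correctness of the estimators and statistics under
this model, not instrument fidelity.

## 7. Activation statistics

The screen computes, per (parameter, channel), the Spearman rank
correlation of per-cell values against activation time over the activated
cohorts only, Benjamini–Hochberg-adjusted across all parameter×channel
tests jointly, and selects pairs with adjusted p < 0.05, |ρ| ≥ 0.5 and a
stable control pair (Mann–Whitney p ≥ 0.05 and |standardised mean
difference| < 0.5 between `CTR 0m` and `CTR 120m`). The ρ-gate, FDR level
and the stability rule are this package's operationalisation of "found to
correlate"; all three are configurable.

A known limitation, measured on the default conditions and worth stating
plainly: because the activation response of the spatial indices is largely
complete by the first observed time point (5 min), their rank correlation
*within* the 5–120 min window is modest (ρ ≈ 0.2–0.5), while statistics of
the mixture's power spectrum (texture aspect ratios Str20/Str37 and
relatives) necessarily sweep their full range inside the window — the fold
weight (1−a) vanishes at full activation, so every fold/grain-contrasting
statistic must transition somewhere in it. Under this generator the screen
therefore selects a superset/subset of the three spatial indices rather
than exactly that trio; the trend *directions* (S_hw down, S_rwi and S_tdi
up from control to full activation), the emptiness of the height-channel
screen, and the permutation-null behaviour (no selections at FDR 0.05 in
≥95% of label permutations) all hold. The corresponding acceptance test
asserts the strict trio selectivity and is expected to fail; it is kept
strict rather than weakened.

**Activation-level estimation** inverts isotonic (monotone) regressions of
S_rwi (increasing) and S_hw (decreasing) against the latent level, fitted
on a training series for the restored-adhesion channel only; per-parameter
inverted levels are combined by inverse-variance weights estimated from
200 bootstrap resamples of the calibration cells, which also give the
interval. S_tdi is excluded from the estimator: near saturation it is
non-monotone (lower at 120 min than at 60 min), so it cannot be inverted,
though it remains in the screen. Queries outside the calibration range are
clamped and flagged as extrapolated.

## 8. Problem sizes used in the checks

Unit tests run on 64-px surfaces and short traces; the acceptance checks
use the full study conditions (256×256 maps, 20 cells per cohort, 2^18
thermal samples, 100-seed noise ensembles, 1000-surface index sweeps).
These sizes were chosen so the whole suite completes in minutes on one
core while keeping every statistical tolerance at the scale it was derived
for.
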