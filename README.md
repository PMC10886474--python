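# ringtex

Ringing-mode AFM force-curve extraction and 2D-Fourier surface-texture
analysis of cell-surface maps, with a synthetic-data generator that stands
in for instrument data.

## The problem

Sub-resonance ("HybriD"-style) AFM imaging records a full approach–retract
force cycle at every pixel. The conventional adhesion map takes one data
point per pixel — the retract minimum — and inherits the full measurement
noise. Ringing mode instead fits the cantilever's free damped oscillation
after the tip detaches: modelling the post-detachment motion as a damped
harmonic oscillator

    F(t) = A e^{−(t−t_d)/τ} cos(2π f (t−t_d) + φ),   τ = Q/(π f₀),

and back-extrapolating to the detachment instant recovers the **restored
adhesion** F_rest (the force at complete detachment), with the whole
ringing segment averaging the noise away. The difference
F_adh − F_rest is the **viscoelastic adhesion**, the signature of energy
lost to inelastic deformation during detachment.

On the resulting maps (adhesion values treated as *effective height*), the
surface texture is summarised by a 37-parameter areal suite in the spirit
of ISO 25178-2/ISO 4287, including three spatial indices built from the
DC-centred 2D Fourier amplitude spectrum:

* **S_tdi** = mean/max of the angular spectrum (amplitude sums along M
  equiangular radial lines) — texture direction index, → 1 when no
  direction dominates;
* **S_rwi** = mean/max of the radial spectrum (amplitude sums over
  concentric semicircles) — radial wave index, → 0 when one wavelength
  dominates;
* **S_hw** = δx(M−1)/(2 r₀.₅) — average half wavelength, with r₀.₅ the
  radius where the integral radial spectrum reaches half its total.

The pipeline quantifies how these parameters track the activation state of
neutrophil-like cells: on activation the membrane develops a granular
structure, so S_hw falls while S_rwi and S_tdi rise in the adhesion
channels, and monotone calibration curves invert the indices into an
activation level in [0, 1]. All of this runs on synthetic data with known
ground truth: simulated force cycles, thermally driven cantilever noise for
calibration, and fold+grain random-field cell surfaces whose RMS is pinned
so only the spatial structure responds to the activation knob.

Audience: AFM/biophysics researchers and method developers who want a
tested, scriptable reference implementation of ringing-mode extraction and
spectral surface-texture statistics.

## Worked example

```python
from ringtex import (RingingConfig, ContactScenario, generate_force_curve,
                     extract_features, SurfaceConfig, generate_surface,
                     amplitude_spectrum, angular_spectrum, radial_spectrum,
                     s_tdi, s_rwi, s_hw, parameter_suite)

cfg = RingingConfig()                      # 0.4 N/m, 75 kHz, Q = 100
scen = ContactScenario(adhesion_force_nN=2.0, restored_force_nN=1.5,
                       noise_sd_nN=0.1)
trace = generate_force_curve(cfg, scen, seed=7)
feats = extract_features(trace, cfg)
print(f"adhesion (min):      {feats.adhesion:.3f} nN")
print(f"restored adhesion:   {feats.restored_adhesion:.3f} nN")
print(f"viscoelastic:        {feats.viscoelastic_adhesion:.3f} nN")

resting = generate_surface(SurfaceConfig(activation_level=0.0), seed=1)
activated = generate_surface(SurfaceConfig(activation_level=1.0), seed=1)
for name, smap in [("resting", resting), ("activated", activated)]:
    spec = amplitude_spectrum(smap)
    angular_spectrum(spec); radial_spectrum(spec)
    print(f"{name:9s}  S_tdi={s_tdi(spec):.3f}  S_rwi={s_rwi(spec):.3f}  "
          f"S_hw={s_hw(spec):.0f} nm")
```

prints

```
adhesion (min):      2.185 nN
restored adhesion:   1.504 nN
viscoelastic:        0.681 nN
resting    S_tdi=0.021  S_rwi=0.034  S_hw=471 nm
activated  S_tdi=0.072  S_rwi=0.089  S_hw=319 nm
```

The single-point adhesion minimum overshoots the true 2.0 nN by about the
noise sd, while the ringing fit recovers the true restored adhesion
(1.5 nN) to 0.3% from the same noisy cycle — the reason ringing-mode maps
are cleaner. Between the resting and fully activated surface (same seed,
same RMS), the dominant direction and wavelength wash out (S_tdi and S_rwi
rise) and spectral weight moves to finer scales (S_hw falls from 471 nm to
319 nm).

## Command line

```bash
ringtex --config demo.toml --out-dir out all
```

runs the full synthetic study (simulate the activation series → compute 37
parameters per map/channel → correlation screen with BH-FDR and control
stability → fit the activation calibration and estimate each cell's level
→ thermal spring-constant calibration), writing GSF/CSV maps, tidy CSV
tables, a key-value calibration report, trend plots and a structured log.
Individual stages are available as subcommands (`simulate-curves`,
`simulate-series`, `calibrate`, `extract`, `qc`, `params`, `screen`,
`estimate`). Outputs are byte-identical for a fixed seed.

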