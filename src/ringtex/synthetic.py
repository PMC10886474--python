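"""Synthetic force curves, thermal-noise traces and neutrophil-like surfaces.

Every downstream stage of the pipeline is exercised on data from this
module, with the generating parameters serving as ground truth:

* :func:`generate_force_curve` builds one sub-resonance force cycle —
  baseline, linear loading to the maximum force, retract into an adhesion
  well, instantaneous snap-off at the adhesion force, then a damped cosine
  at the cantilever resonance whose back-extrapolated force at the
  detachment instant equals the restored adhesion;
* :func:`generate_thermal_trace` produces thermally driven cantilever
  deflection whose PSD follows the simple-harmonic-oscillator response and
  whose variance obeys equipartition, <z^2> = k_B T / k;
* :func:`generate_surface` mixes an oriented long-wavelength "membrane
  fold" field with an isotropic granular field under an activation-level
  knob in [0, 1], with the RMS amplitude pinned so activation changes the
  *spatial structure* of the map, not its amplitude;
* :func:`generate_activation_series` assembles a cross-sectional study:
  cohorts of simulated cells at activation times 5-120 min plus two
  unactivated control groups, with documented cell-to-cell variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .extraction import ForceTrace
from .maps import SurfaceMap

__all__ = [
    "BOLTZMANN_NN_NM",
    "RingingConfig",
    "ContactScenario",
    "SurfaceConfig",
    "SeriesRecord",
    "generate_force_curve",
    "generate_thermal_trace",
    "generate_surface",
    "activation_level",
    "generate_activation_series",
]

# Boltzmann constant in nN*nm/K (1.380649e-23 J/K = 1.380649e-2 nN*nm/K... )
# 1 J = 1e9 nN * 1e9 nm / 1e18 = 1 nN*nm*1e18; so k_B = 1.380649e-23 J/K
# = 1.380649e-5 nN*nm/K.  Spelled out to avoid unit slips:
BOLTZMANN_J_K = 1.380649e-23
BOLTZMANN_NN_NM = BOLTZMANN_J_K * 1e18  # nN*nm per K


@dataclass(frozen=True)
class RingingConfig:
    """Cantilever and acquisition parameters.

    Defaults follow a typical soft imaging probe: nominal spring constant
    0.4 N/m and resonance 70-80 kHz (75 kHz is used as the midpoint).
    ``sampling_rate_hz`` must resolve the ringing: at least 10 samples per
    resonance period.
    """

    spring_constant_n_m: float = 0.4
    resonance_freq_hz: float = 75e3
    quality_factor: float = 100.0
    sampling_rate_hz: float = 2e6
    deflection_sensitivity_nm_v: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "spring_constant_n_m",
            "resonance_freq_hz",
            "quality_factor",
            "sampling_rate_hz",
            "deflection_sensitivity_nm_v",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sampling_rate_hz < 10.0 * self.resonance_freq_hz:
            raise ValueError(
                "sampling_rate_hz must be at least 10x resonance_freq_hz to "
                f"resolve ringing (got {self.sampling_rate_hz:g} Hz for "
                f"f0 = {self.resonance_freq_hz:g} Hz)"
            )

    # spec alias used by the fitting code
    @property
    def resonance_freq(self) -> float:
        return self.resonance_freq_hz

    @property
    def ring_decay_time_s(self) -> float:
        """Amplitude decay time tau = Q / (pi f0) of the free oscillation."""
        return self.quality_factor / (math.pi * self.resonance_freq_hz)


@dataclass(frozen=True)
class ContactScenario:
    """Per-pixel tip-sample interaction parameters (forces in nN)."""

    adhesion_force_nN: float = 2.0
    restored_force_nN: float = 1.5
    max_load_nN: float = 2.0
    contact_stiffness_n_m: float = 0.05
    approach_speed_nm_s: float = 30e3
    noise_sd_nN: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.restored_force_nN <= self.adhesion_force_nN:
            raise ValueError("need 0 <= restored_force <= adhesion_force")
        if not self.max_load_nN > 0:
            raise ValueError("max_load must be positive")
        if self.contact_stiffness_n_m <= 0 or self.approach_speed_nm_s <= 0:
            raise ValueError("contact stiffness and approach speed must be positive")
        if self.noise_sd_nN < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_force_curve(
    config: RingingConfig,
    scenario: ContactScenario,
    seed: int,
    baseline_s: float = 100e-6,
    n_ring_periods: float = 20.0,
) -> ForceTrace:
    """One synthetic force cycle with ground truth in ``trace.meta``.

    Loading and retract are linear ramps at the force rate implied by the
    approach speed and contact stiffness; the snap-off at point D is
    instantaneous, and the subsequent ringing is
    ``-F_rest exp(-(t - t_d)/tau) cos(2 pi f0 (t - t_d))`` about the
    baseline, so the damped-oscillator back-extrapolation at ``t_d``
    recovers exactly the restored force.  Gaussian noise of the configured
    sd is added to the whole trace.
    """
    fs = config.sampling_rate_hz
    dt = 1.0 / fs
    rate_nN_s = scenario.approach_speed_nm_s * scenario.contact_stiffness_n_m
    n_base = max(int(round(baseline_s * fs)), 16)
    n_load = max(int(round(scenario.max_load_nN / rate_nN_s * fs)), 8)
    n_retract = max(
        int(round((scenario.max_load_nN + scenario.adhesion_force_nN) / rate_nN_s * fs)),
        8,
    )
    n_ring = max(int(round(n_ring_periods / config.resonance_freq_hz * fs)), 8)

    force = np.concatenate(
        [
            np.zeros(n_base),
            np.linspace(0.0, scenario.max_load_nN, n_load, endpoint=False)
            + scenario.max_load_nN / n_load,
            np.linspace(
                scenario.max_load_nN,
                -scenario.adhesion_force_nN,
                n_retract,
            ),
            np.zeros(n_ring),
        ]
    )
    i_contact = n_base
    i_max = n_base + n_load - 1
    i_det = n_base + n_load + n_retract - 1  # point D, last retract sample
    tau = config.ring_decay_time_s
    if scenario.adhesion_force_nN == 0.0 or scenario.restored_force_nN == 0.0:
        ring = np.zeros(n_ring)
    else:
        t_rel = dt * np.arange(1, n_ring + 1)
        ring = (
            -scenario.restored_force_nN
            * np.exp(-t_rel / tau)
            * np.cos(2 * math.pi * config.resonance_freq_hz * t_rel)
        )
    force[i_det + 1 :] = ring

    rng = np.random.default_rng(seed)
    if scenario.noise_sd_nN > 0:
        force = force + rng.normal(0.0, scenario.noise_sd_nN, force.size)
    time = dt * np.arange(force.size)
    meta = {
        "truth": {
            "adhesion_nN": scenario.adhesion_force_nN,
            "restored_nN": scenario.restored_force_nN,
            "viscoelastic_nN": scenario.adhesion_force_nN - scenario.restored_force_nN,
            "max_load_nN": scenario.max_load_nN,
            "i_contact": i_contact,
            "i_max": i_max,
            "i_detach": i_det,
            "detachment_time_s": float(time[i_det]),
            "f0_hz": config.resonance_freq_hz,
            "q": config.quality_factor,
        },
        "approach_speed_nm_s": scenario.approach_speed_nm_s,
    }
    return ForceTrace(time_s=time, force_nN=force, meta=meta)


def generate_thermal_trace(
    config: RingingConfig,
    temperature_k: float = 295.0,
    duration_s: float | None = None,
    seed: int = 0,
) -> ForceTrace:
    """Thermally driven cantilever deflection with an SHO spectrum.

    The deflection PSD follows the simple-harmonic-oscillator response at
    the configured resonance and quality factor; the trace is synthesised
    in the frequency domain (deterministic SHO amplitude profile, uniform
    random phases) and variance-matched so the sample variance equals the
    equipartition value k_B T / k exactly.  ``trace.deflection_nm`` holds
    the deflection; ``force_nN`` is the elastic restoring force k z.

    T = 0 returns an identically zero trace.
    """
    if temperature_k < 0:
        raise ValueError("temperature must be non-negative")
    fs = config.sampling_rate_hz
    if duration_s is None:
        duration_s = 2**18 / fs
    n = int(round(duration_s * fs))
    if n < 2**16:
        raise ValueError("need at least 2^16 samples; increase duration")
    time = np.arange(n) / fs
    if temperature_k == 0.0:
        z = np.zeros(n)
    else:
        rng = np.random.default_rng(seed)
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        u = freqs / config.resonance_freq_hz
        resp = 1.0 / np.sqrt((1.0 - u**2) ** 2 + (u / config.quality_factor) ** 2)
        resp[0] = 0.0  # no DC offset
        # phase-randomized synthesis: deterministic SHO amplitude profile with
        # uniform random phases, so the realized spectrum is the smooth SHO
        # curve rather than a ragged chi-squared draw around it
        bins = resp * np.exp(2j * math.pi * rng.random(resp.size))
        z = np.fft.irfft(bins, n)
        target_var = BOLTZMANN_NN_NM * temperature_k / config.spring_constant_n_m  # nm^2
        z *= math.sqrt(target_var) / z.std()
    force = config.spring_constant_n_m * z  # nN (k in N/m = nN/nm)
    return ForceTrace(
        time_s=time,
        force_nN=force,
        deflection_nm=z,
        meta={
            "temperature_k": temperature_k,
            "truth": {
                "spring_constant_n_m": config.spring_constant_n_m,
                "f0_hz": config.resonance_freq_hz,
                "q": config.quality_factor,
            },
        },
    )


@dataclass(frozen=True)
class SurfaceConfig:
    """Generative model of one cell-surface map.

    The map is a weighted mixture of two unit-variance random fields:

    * a **fold field** (weight ``1 - activation_level``): band-limited
      around ``fold_wavelength_nm`` with an angular concentration set by
      ``fold_anisotropy`` around a per-map dominant direction — the smooth,
      oriented membrane folds of a resting cell;
    * a **grain field** (weight ``activation_level``): isotropic Gaussian
      bumps of radius ``grain_radius_nm`` at areal density
      ``grain_density_um2 * (0.2 + 0.8 * activation_level)``, with
      symmetric (+/-) amplitudes — the granular structure that develops on
      activation.

    White pixel noise of sd ``noise_sd`` (channel units) is added, and the
    combined field is rescaled so its RMS equals ``target_rms`` exactly
    before the optional plane tilt is applied; amplitude parameters are
    thereby held fixed across activation levels and only the spatial
    structure responds to the activation knob.
    """

    grid_size: int = 256
    pixel_pitch_nm: float = 20.0
    activation_level: float = 0.0
    grain_radius_nm: float = 120.0
    grain_density_um2: float = 60.0
    fold_wavelength_nm: float = 1200.0
    fold_anisotropy: float = 0.8
    fold_direction_rad: float = 0.0
    plane_tilt: tuple[float, float] = (0.0, 0.0)
    target_rms: float = 1.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.grid_size % 2 != 0 or self.grid_size < 32:
            raise ValueError("grid_size must be even and >= 32")
        if self.pixel_pitch_nm <= 0:
            raise ValueError("pixel_pitch_nm must be positive")
        if not 0.0 <= self.activation_level <= 1.0:
            raise ValueError("activation_level must lie in [0, 1]")
        if not 0.0 <= self.fold_anisotropy <= 1.0:
            raise ValueError("fold_anisotropy must lie in [0, 1]")
        if self.target_rms <= 0:
            raise ValueError("target_rms must be positive")
        if self.grain_radius_nm < self.pixel_pitch_nm:
            raise ValueError("grain_radius_nm below pixel_pitch_nm is unresolvable")
        if not 0.0 <= self.noise_sd < self.target_rms:
            raise ValueError("noise_sd must be non-negative and below target_rms")


def _fold_field(config: SurfaceConfig, rng: np.random.Generator) -> np.ndarray:
    """Oriented band-limited random field, unit variance."""
    m = config.grid_size
    extent = m * config.pixel_pitch_nm
    r0 = extent / config.fold_wavelength_nm  # dominant radius in freq pixels
    c = m // 2
    dy, dx = np.mgrid[-c : m - c, -c : m - c].astype(float)
    r = np.hypot(dy, dx)
    with np.errstate(divide="ignore"):
        radial = np.exp(-((np.log(np.maximum(r, 1e-12) / r0)) ** 2) / (2 * 0.35**2))
    radial[c, c] = 0.0
    theta = np.arctan2(dy, dx)
    d = np.abs(((theta - config.fold_direction_rad) + math.pi / 2) % math.pi - math.pi / 2)
    sigma_theta = 0.25
    angular = (1.0 - config.fold_anisotropy) + config.fold_anisotropy * np.exp(
        -(d**2) / (2 * sigma_theta**2)
    )
    amp = radial * angular
    phase = rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m))
    f = np.fft.ifft2(np.fft.ifftshift(amp * phase)).real
    sd = f.std()
    return f / sd if sd > 0 else f


def _grain_field(
    config: SurfaceConfig, rng: np.random.Generator, n_grains: int
) -> np.ndarray:
    """Isotropic field of symmetric Gaussian bumps, unit variance."""
    m = config.grid_size
    spikes = np.zeros((m, m))
    if n_grains > 0:
        rows = rng.integers(0, m, n_grains)
        cols = rng.integers(0, m, n_grains)
        amps = rng.standard_normal(n_grains)
        np.add.at(spikes, (rows, cols), amps)
    sigma_px = config.grain_radius_nm / config.pixel_pitch_nm
    f = ndimage.gaussian_filter(spikes, sigma_px, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def grain_count(config: SurfaceConfig) -> int:
    """Number of grains placed at the configured activation level."""
    area_um2 = (config.grid_size * config.pixel_pitch_nm * 1e-3) ** 2
    return int(
        round(
            config.grain_density_um2
            * area_um2
            * (0.2 + 0.8 * config.activation_level)
        )
    )


def generate_surface(
    config: SurfaceConfig, seed: int, channel: str = "", provenance: str = ""
) -> SurfaceMap:
    """One synthetic cell-surface map under the fold + grain mixture model."""
    rng = np.random.default_rng(seed)
    a = config.activation_level
    fold = _fold_field(config, rng)
    grain = _grain_field(config, rng, grain_count(config))
    structure = (1.0 - a) * fold + a * grain
    sd = structure.std()
    if sd == 0:
        raise ValueError("degenerate surface: zero structure variance")
    structure_rms = math.sqrt(max(config.target_rms**2 - config.noise_sd**2, 0.0))
    field_ = structure / sd * structure_rms
    if config.noise_sd > 0:
        field_ = field_ + rng.normal(0.0, config.noise_sd, field_.shape)
    field_ -= field_.mean()
    field_ *= config.target_rms / field_.std()  # exact RMS pin
    gx, gy = config.plane_tilt
    if gx or gy:
        m = config.grid_size
        y, x = np.mgrid[0:m, 0:m].astype(float) * config.pixel_pitch_nm
        field_ = field_ + gx * x + gy * y
    return SurfaceMap(
        values=field_,
        pixel_pitch_nm=config.pixel_pitch_nm,
        channel=channel,
        provenance=provenance or f"synthetic seed={seed}",
    )


def activation_level(t_min: float, tau_min: float = 10.0) -> float:
    """Saturating activation kinetics: level(t) = 1 - exp(-t / tau).

    With the default tau = 10 min the level reaches 95% by 30 min, matching
    the observation that surface changes complete within the first half
    hour and plateau thereafter.
    """
    if t_min < 0:
        raise ValueError("time must be non-negative")
    return 1.0 - math.exp(-t_min / tau_min)


@dataclass
class SeriesRecord:
    """One channel map of one simulated cell at one time point."""

    group: str
    time_min: float
    level: float
    cell_id: str
    channel: str
    map: SurfaceMap


# Documented cell-to-cell variability (invented; no measured spreads exist
# for these quantities).  Log-normal sigmas for strictly positive
# parameters, plus a uniform random fold direction per cell.
CELL_SPREADS = {
    "fold_wavelength_nm": 0.15,
    "grain_radius_nm": 0.12,
    "grain_density_um2": 0.15,
    "noise_sd": 0.30,
}

DEFAULT_TIMES_MIN = (5.0, 10.0, 30.0, 60.0, 120.0)
CHANNELS = ("height", "restored adhesion", "viscoelastic adhesion")


def _cell_config(
    base: SurfaceConfig, level: float, rng: np.random.Generator
) -> SurfaceConfig:
    changes: dict = {"activation_level": level}
    for name, sigma in CELL_SPREADS.items():
        changes[name] = getattr(base, name) * float(rng.lognormal(0.0, sigma))
    changes["noise_sd"] = min(changes["noise_sd"], 0.9 * base.target_rms)
    changes["fold_direction_rad"] = float(rng.uniform(0.0, math.pi))
    changes["fold_anisotropy"] = float(
        np.clip(base.fold_anisotropy + rng.uniform(-0.1, 0.1), 0.0, 1.0)
    )
    return replace(base, **changes)


def generate_activation_series(
    times_min=DEFAULT_TIMES_MIN,
    n_cells: int = 20,
    base: SurfaceConfig | None = None,
    tau_min: float = 10.0,
    seed: int = 0,
    channels=CHANNELS,
) -> list[SeriesRecord]:
    """Cross-sectional activation study with ground-truth levels.

    For each activation time t in ``times_min`` a fresh cohort of
    ``n_cells`` simulated cells is generated at activation level
    ``1 - exp(-t/tau)``; two control cohorts at level 0 are added under the
    labels ``CTR 0m`` and ``CTR 120m``.  Three channels are produced per
    cell:

    * ``restored adhesion`` — the activation-responsive channel (nN scale);
    * ``viscoelastic adhesion`` — also activation-responsive but noisier
      (2x the pixel noise), mirroring its lower map quality;
    * ``height`` — structure held at activation level 0 with a random
      instrumental plane tilt, so its tilt-removed spectra carry no
      activation trend.

    Cell-to-cell variability follows :data:`CELL_SPREADS`; every cell uses
    an independent child seed spawned deterministically from ``seed``.
    """
    if len(times_min) == 0:
        raise ValueError("times_min must be non-empty")
    if n_cells < 3:
        raise ValueError("need at least 3 cells per group")
    if base is None:
        base = SurfaceConfig()
    groups = [("CTR 0m", 0.0, 0.0), ("CTR 120m", 120.0, 0.0)]
    for t in times_min:
        groups.append((f"ACT {t:g}m", float(t), activation_level(t, tau_min)))

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(groups) * n_cells)
    records: list[SeriesRecord] = []
    idx = 0
    for group, t, level in groups:
        for c in range(n_cells):
            rng = np.random.default_rng(children[idx])
            idx += 1
            cell_id = f"{group}/cell{c:02d}"
            cfg = _cell_config(base, level, rng)
            sub = np.random.SeedSequence(
                entropy=int(rng.integers(0, 2**31))
            ).spawn(len(channels))
            for k, ch in enumerate(channels):
                ch_rng_seed = sub[k]
                if ch == "height":
                    ch_cfg = replace(
                        cfg,
                        activation_level=0.0,
                        target_rms=60.0,  # nm-scale topography
                        noise_sd=min(cfg.noise_sd * 60.0, 0.9 * 60.0),
                        plane_tilt=(
                            float(rng.normal(0.0, 0.02)),
                            float(rng.normal(0.0, 0.02)),
                        ),
                    )
                elif ch == "viscoelastic adhesion":
                    ch_cfg = replace(
                        cfg, noise_sd=min(2.0 * cfg.noise_sd, 0.9 * cfg.target_rms)
                    )
                else:
                    ch_cfg = cfg
                smap = generate_surface(
                    ch_cfg,
                    seed=ch_rng_seed,
                    channel=ch,
                    provenance=cell_id,
                )
                records.append(
                    SeriesRecord(
                        group=group,
                        time_min=t,
                        level=level,
                        cell_id=cell_id,
                        channel=ch,
                        map=smap,
                    )
                )
    return records
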