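"""Per-pixel force-curve feature extraction, including ringing-mode adhesion.

Each pixel of a sub-resonance force-curve scan records one full
approach-retract cycle: baseline (A), first contact (B), loading to the
maximum force (C), retract into the adhesion well down to the adhesion
force (D), rapid detachment, and free damped oscillation of the cantilever
at its resonance (F, the "ringing" segment).

Two adhesion estimates are produced per pixel:

* the conventional single-point estimate — the magnitude of the retract
  minimum (point D), deliberately noise-sensitive since it rides on one
  sample;
* the **restored adhesion** — the force on the cantilever at the instant of
  complete detachment (point E), recovered by fitting a damped cosine
  ``A exp(-(t - t_d)/tau) cos(2 pi f (t - t_d) + phi) + c`` to the ringing
  segment and back-extrapolating to the detachment time ``t_d``.  Because
  the whole ringing segment enters the fit, this estimate averages out
  white noise that the single-point minimum cannot.

Their difference, the **viscoelastic adhesion** F_adh - F_rest, measures the
energy lost to inelastic deformation of the sample during detachment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .maps import SurfaceMap

__all__ = [
    "ForceTrace",
    "CycleSegments",
    "CurveFeatures",
    "segment_cycle",
    "adhesion_minimum",
    "restored_adhesion_fit",
    "viscoelastic_adhesion",
    "process_grid",
]


@dataclass
class ForceTrace:
    """Uniformly sampled force (and optionally deflection) versus time."""

    time_s: np.ndarray
    force_nN: np.ndarray
    deflection_nm: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.time_s.shape != self.force_nN.shape or self.time_s.ndim != 1:
            raise ValueError("time and force must be equal-length 1D arrays")
        dt = np.diff(self.time_s)
        if dt.size:
            if dt.min() <= 0:
                raise ValueError("time must be strictly increasing")
            if (dt.max() - dt.min()) / dt.mean() > 1e-6:
                raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt


@dataclass
class CycleSegments:
    """Index slices of one force cycle; ``no_contact`` marks an empty cycle."""

    baseline: slice
    loading: slice
    retract: slice
    ringing: slice
    detachment_index: int | None
    baseline_force: float
    noise_sd: float
    no_contact: bool = False

    @property
    def detachment_time(self) -> float | None:
        return self._detachment_time

    _detachment_time: float | None = None


@dataclass
class CurveFeatures:
    """Per-pixel scalar features of one force cycle (all forces in nN)."""

    adhesion: float
    restored_adhesion: float
    viscoelastic_adhesion: float
    max_load: float
    deformation_nm: float
    detachment_time_s: float
    fit_residual: float
    unreliable: bool = False
    no_contact: bool = False
    clamped: bool = False


def _noise_floor(force: np.ndarray, sd: float) -> float:
    span = float(force.max() - force.min())
    return max(sd, 1e-6 * span, 1e-12)


def _detachment_index(
    trace: ForceTrace, f: np.ndarray, i_max: int, i_min: int, floor: float
) -> int:
    """Locate the detachment sample (point D) at the end of the adhesion well.

    The well bottom is shallow relative to measurement noise, so a bare
    argmin wanders along the retract ramp.  The post-detachment ringing is
    the sharp landmark instead: complex demodulation at the ringing
    frequency gives a rolling oscillation amplitude that switches on at
    detachment, localising it to within a period; the sample is then
    refined to the largest positive force step (the D->E discontinuity,
    when present) in that neighbourhood.
    """
    n = f.size
    # ringing frequency from the spectrum of the trailing quarter
    tail = f[max(i_min, n - (n - i_min) // 2) :]
    freqs = np.fft.rfftfreq(tail.size, trace.dt)
    spec = np.abs(np.fft.rfft(tail - tail.mean()))
    f0 = float(freqs[1 + np.argmax(spec[1:])]) if tail.size > 8 else 0.0
    lo = max(i_min - 400, i_max)
    if f0 > 0:
        period = max(int(round(1.0 / (f0 * trace.dt))), 4)
        seg = f[lo:n]
        if seg.size > 2 * period:
            carrier = np.exp(-2j * math.pi * f0 * trace.dt * np.arange(period))
            amp = np.abs(np.convolve(seg, carrier[::-1], mode="valid")) * 2.0 / period
            ring_level = float(np.median(amp[-max(amp.size // 4, 1) :]))
            # demodulated amplitude of white noise scales as sigma/sqrt(P)
            noise_level = 2.0 * floor / math.sqrt(period)
            if ring_level > 6.0 * noise_level:
                onset = np.nonzero(amp >= 0.5 * ring_level)[0]
                if onset.size:
                    c = lo + int(onset[0]) + period // 2
                    a, b = max(c - period, i_max), min(c + period // 2, n - 1)
                    steps = np.diff(f[a : b + 1])
                    big = np.nonzero(steps > 5.0 * floor)[0]
                    if big.size:
                        # first discontinuity above noise: the D->E jump
                        return a + int(big[0])
                    return c
    # no resolvable ringing: fall back to the largest step after the well
    hi = min(i_min + 400, n - 1)
    steps = np.diff(f[max(i_min - 5, i_max) : hi + 1])
    if steps.size:
        return max(i_min - 5, i_max) + int(np.argmax(steps))
    return i_min


def segment_cycle(trace: ForceTrace) -> CycleSegments:
    """Split one cycle into baseline, loading, retract and ringing segments.

    The baseline level and noise sd are estimated from the leading 1% of
    samples.  Contact requires the force to exceed baseline + 5 sigma (with
    a small floor for noiseless traces); otherwise the cycle is flagged
    ``no_contact``.  The detachment instant is the terminal discontinuity
    of the adhesion well: the retract minimum is located on a lightly
    smoothed copy of the trace (so a single noise spike cannot claim it)
    and refined to the sample preceding the largest positive force step in
    its neighbourhood.
    """
    f = trace.force_nN
    n = f.size
    nb = max(n // 100, 8)
    base = float(np.mean(f[:nb]))
    sd = float(np.std(f[:nb]))
    floor = _noise_floor(f, sd)
    thresh = base + 5.0 * floor

    above = np.nonzero(f > thresh)[0]
    if above.size == 0:
        return CycleSegments(
            baseline=slice(0, n),
            loading=slice(n, n),
            retract=slice(n, n),
            ringing=slice(n, n),
            detachment_index=None,
            baseline_force=base,
            noise_sd=sd,
            no_contact=True,
        )
    i_contact = int(above[0])
    i_max = int(np.argmax(f))

    w = 5  # smoothing width: well below a ringing period, above spike width
    kernel = np.ones(w) / w
    fsm = np.convolve(f, kernel, mode="same")
    tail = fsm[i_max:]
    i_min = i_max + int(np.argmin(tail))
    has_adhesion = fsm[i_min] < base - 5.0 * floor
    if has_adhesion:
        i_det = _detachment_index(trace, f, i_max, i_min, floor)
        ringing = slice(i_det + 1, n)
    else:
        # no adhesion well: D is the return to baseline, no ringing
        back = np.nonzero(f[i_max:] <= base + 5.0 * floor)[0]
        i_det = i_max + int(back[0]) if back.size else n - 1
        ringing = slice(n, n)

    seg = CycleSegments(
        baseline=slice(0, i_contact),
        loading=slice(i_contact, i_max + 1),
        retract=slice(i_max + 1, i_det + 1),
        ringing=ringing,
        detachment_index=i_det,
        baseline_force=base,
        noise_sd=sd,
    )
    seg._detachment_time = float(trace.time_s[i_det])
    return seg


def adhesion_minimum(trace: ForceTrace, segments: CycleSegments | None = None) -> float:
    """Single-sample adhesion estimate: magnitude of the retract minimum.

    This is the conventional one-data-point-per-pixel estimate; it is kept
    for comparison precisely because a single sample inherits the full
    measurement noise (and is biased high by it).
    """
    if segments is None:
        segments = segment_cycle(trace)
    if segments.no_contact:
        return math.nan
    retract = trace.force_nN[segments.retract]
    if retract.size == 0:
        return 0.0
    depth = segments.baseline_force - float(retract.min())
    return max(depth, 0.0)


def _demod_init(
    t: np.ndarray, y: np.ndarray, t_d: float, f_guess: float, dt: float
) -> tuple[float, float, float, float]:
    """Initial (A, tau, f, phi) for the damped-cosine fit by demodulation.

    The segment frequency is refined from the periodogram peak (parabolic
    interpolation); complex demodulation at that frequency followed by a
    one-period boxcar gives the analytic envelope, whose log is fitted
    linearly for the amplitude and decay time, and whose initial argument
    gives the phase at ``t_d``.
    """
    n = y.size
    yc = y - y.mean()
    spec = np.abs(np.fft.rfft(yc))
    freqs = np.fft.rfftfreq(n, dt)
    k = 1 + int(np.argmax(spec[1:]))
    if 1 <= k < spec.size - 1 and spec[k] > 0:
        denom = spec[k - 1] - 2 * spec[k] + spec[k + 1]
        shift = 0.5 * (spec[k - 1] - spec[k + 1]) / denom if denom != 0 else 0.0
        f_est = float((k + np.clip(shift, -0.5, 0.5)) / (n * dt))
    else:
        f_est = f_guess
    period = max(int(round(1.0 / (f_est * dt))), 2)
    z = yc * np.exp(-2j * math.pi * f_est * (t - t_d))
    w = np.convolve(z, np.ones(period) / period, mode="valid")
    env = 2.0 * np.abs(w)
    ok = env > 0.05 * env.max()
    if ok.sum() >= 4:
        tt = t[: w.size][ok] - t_d
        slope, intercept = np.polyfit(tt, np.log(env[ok]), 1)
        a0 = float(np.exp(intercept))
        tau0 = float(-1.0 / slope) if slope < 0 else float(t[-1] - t_d)
    else:
        a0, tau0 = float(env.max()), float(t[-1] - t_d)
    phi0 = float(np.angle(w[0]))
    return a0, tau0, f_est, phi0


def restored_adhesion_fit(
    trace: ForceTrace,
    config=None,
    segments: CycleSegments | None = None,
) -> tuple[float, float, bool]:
    """Back-extrapolate the ringing segment to the detachment instant.

    Fits ``A exp(-(t - t_d)/tau) cos(2 pi f (t - t_d) + phi) + c`` to the
    ringing segment by trust-region least squares, initialised from the
    configured resonance frequency (when given) and the log-envelope slope.
    Returns ``(restored_adhesion, fit_residual_rms, unreliable)`` where
    restored adhesion is ``|A cos(phi)|``, the fitted force magnitude at
    ``t_d`` (point E).  The result is flagged unreliable when fewer than
    three oscillation periods are available or the residual exceeds 20% of
    the fitted amplitude.
    """
    if segments is None:
        segments = segment_cycle(trace)
    if segments.no_contact or segments.detachment_index is None:
        return math.nan, math.nan, True
    ring = segments.ringing
    y = trace.force_nN[ring] - segments.baseline_force
    t = trace.time_s[ring]
    t_d = trace.time_s[segments.detachment_index]
    if y.size < 8:
        return math.nan, math.nan, True

    f0 = None
    if config is not None:
        f0 = getattr(config, "resonance_freq_hz", None) or getattr(
            config, "resonance_freq", None
        )
    if f0 is None:
        # dominant frequency of the segment from the periodogram
        freqs = np.fft.rfftfreq(y.size, trace.dt)
        spec = np.abs(np.fft.rfft(y - y.mean()))
        f0 = float(freqs[1 + np.argmax(spec[1:])]) if y.size > 4 else 1.0 / (t[-1] - t[0])
    n_periods = (t[-1] - t_d) * f0
    if n_periods < 3.0:
        return math.nan, math.nan, True

    if np.all(y == 0.0):
        return 0.0, 0.0, False
    a_init, tau_init, f_init, phi_init = _demod_init(t, y, t_d, f0, trace.dt)
    if a_init == 0.0:
        return 0.0, 0.0, False

    def model(p, tt):
        a, tau, f, phi, c = p
        return a * np.exp(-(tt - t_d) / tau) * np.cos(2 * math.pi * f * (tt - t_d) + phi) + c

    # frequency bounded to half the mode spacing 1/T around the periodogram
    # estimate, so the optimiser cannot hop to an aliased cycle count
    df = 0.5 / (t[-1] - t_d)
    p0 = [a_init, tau_init, f_init, phi_init, 0.0]
    try:
        best = least_squares(
            lambda p: model(p, t) - y,
            p0,
            bounds=(
                [0.0, trace.dt, f_init - df, phi_init - math.pi, -np.inf],
                [np.inf, np.inf, f_init + df, phi_init + math.pi, np.inf],
            ),
            x_scale=[max(a_init, 1e-12), max(tau_init, trace.dt), f_init, 1.0, max(a_init, 1e-12)],
            method="trf",
        )
    except ValueError:
        return math.nan, math.nan, True
    a, tau, f, phi, c = best.x
    # The cantilever is released from rest relative to its oscillation, so
    # detachment coincides with a phase turning point; evaluate |A cos(phi)|
    # after snapping the detachment instant to the nearest turning point of
    # the fitted oscillation (phi -> 0 mod pi).  This makes the estimate an
    # envelope back-extrapolation, insensitive to sub-period segmentation
    # error in t_d.
    delta = (phi + math.pi / 2) % math.pi - math.pi / 2
    t_snap = -delta / (2 * math.pi * f)
    restored = abs(a * math.exp(-t_snap / tau))
    residual = float(np.sqrt(2.0 * best.cost / y.size))
    unreliable = a > 0 and residual > 0.2 * a
    return float(restored), residual, bool(unreliable)


def viscoelastic_adhesion(adhesion: float, restored: float) -> tuple[float, bool]:
    """Difference F_adh - F_rest, clamped at zero.

    Under noise the fitted restored adhesion can slightly exceed the
    adhesion minimum; the negative difference is unphysical and is clamped
    to 0, with the clamp reported so callers can count occurrences.
    """
    diff = adhesion - restored
    if diff < 0.0:
        return 0.0, True
    return diff, False


def extract_features(trace: ForceTrace, config=None) -> CurveFeatures:
    """All per-pixel features of one cycle (adhesion, restored, max load, ...)."""
    seg = segment_cycle(trace)
    if seg.no_contact:
        return CurveFeatures(
            adhesion=math.nan,
            restored_adhesion=math.nan,
            viscoelastic_adhesion=math.nan,
            max_load=math.nan,
            deformation_nm=math.nan,
            detachment_time_s=math.nan,
            fit_residual=math.nan,
            no_contact=True,
        )
    f_adh = adhesion_minimum(trace, seg)
    if seg.ringing.start >= seg.ringing.stop:
        # zero-adhesion cycle: nothing rings, both adhesions vanish
        f_rest, resid, unreliable = 0.0, 0.0, False
    else:
        f_rest, resid, unreliable = restored_adhesion_fit(trace, config, seg)
    if math.isnan(f_rest):
        f_visc, clamped = math.nan, False
    else:
        f_visc, clamped = viscoelastic_adhesion(f_adh, f_rest)
    max_load = float(trace.force_nN[seg.loading].max() - seg.baseline_force)
    speed = trace.meta.get("approach_speed_nm_s")
    if speed is not None and seg.loading.stop > seg.loading.start:
        dt_load = trace.time_s[seg.loading.stop - 1] - trace.time_s[seg.loading.start]
        deformation = float(speed * dt_load)
    else:
        deformation = math.nan
    return CurveFeatures(
        adhesion=f_adh,
        restored_adhesion=f_rest,
        viscoelastic_adhesion=f_visc,
        max_load=max_load,
        deformation_nm=deformation,
        detachment_time_s=seg.detachment_time if seg.detachment_time is not None else math.nan,
        fit_residual=resid,
        unreliable=unreliable,
        clamped=clamped,
    )


_CHANNELS = (
    "height",
    "adhesion",
    "restored adhesion",
    "viscoelastic adhesion",
    "max load",
    "deformation",
)


def process_grid(
    traces: list[list[ForceTrace]],
    config=None,
    pixel_pitch_nm: float = 20.0,
) -> tuple[dict[str, SurfaceMap], np.ndarray]:
    """Assemble per-channel maps from a rectangular grid of force cycles.

    Returns ``(maps, qc_mask)`` where ``maps`` holds one
    :class:`~ringtex.maps.SurfaceMap` per channel and ``qc_mask`` marks
    pixels whose cycle was flagged (no contact, or an unreliable ringing
    fit).  Flagged pixels are filled with the median of their valid
    4-neighbours so a handful of bad cycles does not corrupt the texture
    statistics; the mask preserves which values are interpolated.

    The height channel is taken from per-trace metadata (``height_nm``)
    when present — topography requires the z-piezo record, which a bare
    force-time trace does not carry.
    """
    n_rows = len(traces)
    if n_rows == 0 or any(len(row) != len(traces[0]) for row in traces):
        raise ValueError("trace grid must be rectangular and non-empty")
    n_cols = len(traces[0])

    grids = {ch: np.full((n_rows, n_cols), np.nan) for ch in _CHANNELS}
    qc = np.zeros((n_rows, n_cols), dtype=bool)
    for i, row in enumerate(traces):
        for j, tr in enumerate(row):
            feats = extract_features(tr, config)
            qc[i, j] = feats.no_contact or feats.unreliable
            grids["height"][i, j] = tr.meta.get("height_nm", np.nan)
            grids["adhesion"][i, j] = feats.adhesion
            grids["restored adhesion"][i, j] = feats.restored_adhesion
            grids["viscoelastic adhesion"][i, j] = feats.viscoelastic_adhesion
            grids["max load"][i, j] = feats.max_load
            grids["deformation"][i, j] = feats.deformation_nm

    for ch, g in grids.items():
        bad = qc | ~np.isfinite(g)
        if bad.all():
            g[:] = 0.0
            continue
        fill = np.array(g)
        for i, j in zip(*np.nonzero(bad)):
            neigh = []
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < n_rows and 0 <= jj < n_cols and not bad[ii, jj]:
                    neigh.append(g[ii, jj])
            fill[i, j] = np.median(neigh) if neigh else np.nanmedian(g[~bad])
        grids[ch] = fill

    maps = {
        ch: SurfaceMap(g, pixel_pitch_nm, channel=ch) for ch, g in grids.items()
    }
    return maps, qc
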