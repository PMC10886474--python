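"""Cantilever calibration: deflection sensitivity and thermal spring constant.

The deflection sensitivity (nm/V) is the inverse slope of the
photodetector signal against z displacement while the tip is pressed on a
rigid (non-deforming) substrate.  The spring constant comes from the
thermal method: the power spectral density of free thermally driven
deflection is fitted with a simple-harmonic-oscillator (SHO) response plus
a white baseline, and equipartition closes the calibration,
``k = k_B T / <z^2>`` with ``<z^2>`` the area under the fitted SHO
component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import least_squares

from .extraction import ForceTrace
from .synthetic import BOLTZMANN_NN_NM

__all__ = [
    "CalibrationResult",
    "fit_deflection_sensitivity",
    "fit_spring_constant_psd",
]


@dataclass(frozen=True)
class CalibrationResult:
    deflection_sensitivity_nm_v: float
    spring_constant_n_m: float
    fit_quality: float  # coefficient of determination of the PSD fit (log space)
    resonance_freq_hz: float
    q_factor: float

    def __post_init__(self) -> None:
        if self.spring_constant_n_m <= 0:
            raise ValueError("spring constant must be positive")
        if not 0.0 <= self.fit_quality <= 1.0:
            raise ValueError("fit_quality must lie in [0, 1]")


def fit_deflection_sensitivity(
    z_nm: np.ndarray, deflection_v: np.ndarray
) -> float:
    """Sensitivity (nm/V) from a contact ramp on a rigid substrate.

    The contact region is taken as samples where the deflection exceeds
    10% of its range above the baseline (median of the lowest quartile).
    Within it, local slopes d(signal)/dz are computed and the fitted
    segment is the longest contiguous run whose local slope stays within
    10% of the median contact slope; the sensitivity is the inverse of the
    least-squares slope over that segment.
    """
    z = np.asarray(z_nm, dtype=float)
    v = np.asarray(deflection_v, dtype=float)
    if z.shape != v.shape or z.ndim != 1 or z.size < 8:
        raise ValueError("need equal-length 1D arrays of at least 8 samples")
    base = np.median(np.sort(v)[: max(v.size // 4, 2)])
    span = v.max() - base
    if span <= 0:
        raise ValueError("no contact region found: deflection never rises")
    contact = np.nonzero(v > base + 0.1 * span)[0]
    if contact.size < 4:
        raise ValueError("no contact region found: fewer than 4 contact samples")
    i0, i1 = contact[0], contact[-1] + 1
    dz = np.diff(z[i0:i1])
    if np.any(dz == 0):
        raise ValueError("z must be strictly monotone over the contact region")
    # local slopes from a Savitzky-Golay derivative, so per-sample noise
    # does not swamp the 10%-of-median run criterion
    seg = v[i0:i1]
    w = min(max(2 * (seg.size // 8) + 1, 5), seg.size - (seg.size + 1) % 2)
    if w >= 5 and seg.size > w:
        local = signal.savgol_filter(seg, w, 1, deriv=1, delta=float(np.mean(dz)))[:-1]
    else:
        local = np.diff(seg) / dz
    med = np.median(local)
    if med == 0:
        raise ValueError("flat contact response; cannot calibrate")
    ok = np.abs(local - med) <= 0.1 * abs(med)
    # longest contiguous run of near-median slope
    best_start, best_len, start = 0, 0, None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if best_len < 3:
        raise ValueError("no stable linear contact segment found")
    # trim the smoothing half-width at both ends: those local slopes mix in
    # samples from outside the run (e.g. the contact onset)
    margin = w // 2 if best_len > 2 * (w // 2) + 3 else 0
    sl = slice(i0 + best_start + margin, i0 + best_start + best_len + 1 - margin)
    slope = np.polyfit(z[sl], v[sl], 1)[0]  # V per nm
    return float(1.0 / slope)


def _sho_psd(p: np.ndarray, f: np.ndarray) -> np.ndarray:
    a, f0, q, b = p
    u = f / f0
    return a / ((1.0 - u**2) ** 2 + (u / q) ** 2) + b


def fit_spring_constant_psd(
    trace: ForceTrace,
    temperature_k: float = 295.0,
    segment_length: int | None = None,
) -> CalibrationResult:
    """Thermal (PSD) spring-constant calibration of a free deflection record.

    A Welch PSD (Hann window, 50% overlap) of ``trace.deflection_nm`` is
    fitted in log space with an SHO resonance plus a white baseline.  The
    segment length defaults to the power of two giving ~122 Hz resolution
    (8.2 ms segments, 2^13 samples at 1 MHz), which resolves the resonance
    peak of soft imaging cantilevers independently of the sampling rate.  The deflection variance is the
    analytic area of the fitted SHO component, ``<z^2> = pi A f0 Q / 2``,
    and ``k = k_B T / <z^2>``.

    Raises if the temperature is non-positive or the resonance peak does
    not rise above the baseline (e.g. a white-noise-only record).
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    z = trace.deflection_nm
    if z is None:
        raise ValueError("trace carries no deflection record")
    fs = trace.sampling_rate
    if segment_length is None:
        segment_length = 2 ** int(round(math.log2(fs * 8.192e-3)))
    nper = min(segment_length, z.size)
    freqs, psd = signal.welch(z, fs=fs, nperseg=nper, noverlap=nper // 2)
    freqs, psd = freqs[1:], psd[1:]  # drop DC

    baseline = float(np.median(psd))
    i_peak = int(np.argmax(psd))
    if psd[i_peak] < 10.0 * baseline:
        raise ValueError(
            "resonance peak not resolvable above the noise baseline; "
            "cannot run thermal calibration"
        )
    f0_init = float(freqs[i_peak])
    half = psd[i_peak] / 2.0
    above = np.nonzero(psd > half)[0]
    width = max(float(freqs[above[-1]] - freqs[above[0]]), float(freqs[1] - freqs[0]))
    q_init = max(f0_init / width, 1.0)
    a_init = float(psd[i_peak] / q_init**2)

    logp = np.log(psd)

    # all four parameters are positive and span many decades; fitting their
    # logarithms keeps the problem well scaled (the white baseline in
    # particular may lie far below the resonance tails)
    def resid(theta):
        return np.log(_sho_psd(np.exp(theta), freqs)) - logp

    b_init = max(float(np.median(psd[-max(psd.size // 10, 4) :])), 1e-300)
    theta0 = np.log([a_init, f0_init, q_init, b_init])
    fit = least_squares(resid, theta0, method="lm", max_nfev=2000)
    a, f0, q, b = np.exp(fit.x)
    ss_res = float(np.sum(fit.fun**2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = max(0.0, 1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0

    z2 = math.pi * a * f0 * q / 2.0  # nm^2, area of the SHO component
    if z2 <= 0:
        raise ValueError("fitted SHO component has non-positive area")
    k = BOLTZMANN_NN_NM * temperature_k / z2  # nN/nm = N/m
    return CalibrationResult(
        deflection_sensitivity_nm_v=math.nan,
        spring_constant_n_m=float(k),
        fit_quality=min(r2, 1.0),
        resonance_freq_hz=float(f0),
        q_factor=float(q),
    )
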