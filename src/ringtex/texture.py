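"""2D-Fourier surface texture analysis and the areal parameter suite.

The spatial characterisation rests on the DC-centred modulus of the 2D
discrete Fourier transform of a (mean-subtracted) surface map.  Two reduced
spectra are derived from it:

* the **angular spectrum** A(i): amplitudes summed along M equiangularly
  spaced radial lines through the centre (upper half-plane, DC excluded);
  its flatness is the texture direction index S_tdi = mean(A)/max(A),
  which tends to 1 for isotropic surfaces and to 0 under a strongly
  dominant direction;
* the **radial spectrum** beta(r), r = 1 .. M/2-1: amplitudes summed over
  concentric semicircles of integer pixel radius; its flatness is the
  radial wave index S_rwi = mean(beta)/max(beta), near 0 when one
  wavelength dominates and near 1 for a flat (white) spectrum.

The average half wavelength S_hw is read off the integral radial spectrum
beta_i(r) = sum_{j<=r} beta(j): with r_0.5 the (interpolated) radius where
beta_i reaches half its total, S_hw = dx * (M - 1) / (2 * r_0.5), i.e. half
the wavelength at the median spectral radius (a pure sinusoid of wavelength
lambda gives lambda/2).

On top of these, :func:`parameter_suite` evaluates a registry of exactly 37
areal surface-texture parameters in four families (amplitude, spatial,
hybrid, functional) in the spirit of ISO 25178-2 / ISO 4287, applied to
height maps and to adhesion maps treated as effective height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .maps import SurfaceMap

__all__ = [
    "SpectrumSet",
    "SpectrumOptions",
    "ParameterSet",
    "PARAMETER_FAMILIES",
    "PARAMETER_NAMES",
    "amplitude_spectrum",
    "angular_spectrum",
    "radial_spectrum",
    "s_tdi",
    "s_rwi",
    "s_hw",
    "r_half",
    "parameter_suite",
]


@dataclass(frozen=True)
class SpectrumOptions:
    """Switchable conventions of the spectral reduction.

    halve_shw
        Divide the median-radius wavelength by two (default), so a pure
        sinusoid of wavelength lambda yields S_hw = lambda/2.
    interpolated_lines
        Sample the angular spectrum by bilinear interpolation along each
        radial line instead of nearest-line sector sums.  Sector sums are
        the default: they conserve total amplitude exactly and admit a
        direct per-pixel oracle.
    window
        Optional 2D window ("hann") applied before the FFT; default none,
        mean subtraction only.
    """

    halve_shw: bool = True
    interpolated_lines: bool = False
    window: str | None = None


@dataclass
class SpectrumSet:
    """DC-centred 2D amplitude spectrum with its angular/radial reductions."""

    amplitude2d: np.ndarray
    pixel_pitch_nm: float
    angular: np.ndarray | None = None
    radial: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.amplitude2d.shape[0]

    @property
    def integral_radial(self) -> np.ndarray:
        if self.radial is None:
            raise ValueError("radial spectrum not computed")
        return np.cumsum(self.radial)


def _half_plane_mask(m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Off-DC upper-half-plane pixel offsets (dy, dx) of a DC-centred grid.

    For even M the DC bin sits at (M/2, M/2).  Hermitian symmetry of a real
    map makes the lower half redundant; the half-plane is dy > 0 plus the
    dx > 0 half of the dy = 0 axis.
    """
    c = m // 2
    dy, dx = np.mgrid[-c : m - c, -c : m - c]
    mask = (dy > 0) | ((dy == 0) & (dx > 0))
    return mask, dy, dx


def amplitude_spectrum(
    smap: SurfaceMap, options: SpectrumOptions | None = None
) -> SpectrumSet:
    """Modulus of the 2D DFT, quadrant-swapped so DC is at (M/2, M/2).

    The map mean is subtracted first; no window is applied by default.
    """
    if options is None:
        options = SpectrumOptions()
    z = smap.values - smap.values.mean()
    if options.window == "hann":
        w = np.hanning(smap.size)
        z = z * np.outer(w, w)
    elif options.window is not None:
        raise ValueError(f"unknown window {options.window!r}")
    amp = np.abs(np.fft.fftshift(np.fft.fft2(z)))
    return SpectrumSet(amplitude2d=amp, pixel_pitch_nm=smap.pixel_pitch_nm)


def angular_spectrum(
    spec: SpectrumSet,
    m_lines: int | None = None,
    options: SpectrumOptions | None = None,
) -> np.ndarray:
    """Angular spectrum A(i): amplitude sums along M equiangular lines.

    Line i has angle ``alpha_i = i * pi / m_lines`` measured from the +x
    frequency axis, i = 0 .. m_lines-1 (directions are modulo pi by
    Hermitian symmetry).  By default each off-DC upper-half-plane pixel is
    assigned to its nearest line and amplitudes are summed per line;
    ``m_lines`` defaults to the image size M.

    Note the angle refers to the *wave vector*: a cosine whose stripes run
    along y (variation along x) contributes at alpha = 0.
    """
    if options is None:
        options = SpectrumOptions()
    m = spec.size
    if m_lines is None:
        m_lines = m
    mask, dy, dx = _half_plane_mask(m)
    amps = spec.amplitude2d[mask]
    if options.interpolated_lines:
        # Sample amplitude along each line at unit-radius steps.
        radii = np.arange(1, m // 2)
        out = np.empty(m_lines)
        for i in range(m_lines):
            a = i * math.pi / m_lines
            cols = m // 2 + radii * math.cos(a)
            rows = m // 2 + radii * math.sin(a)
            out[i] = ndimage.map_coordinates(
                spec.amplitude2d, np.vstack([rows, cols]), order=1, mode="constant"
            ).sum()
        spec.angular = out
        return out
    ang = np.arctan2(dy[mask], dx[mask])  # in [0, pi) on the half plane
    idx = np.rint(ang / (math.pi / m_lines)).astype(int) % m_lines
    out = np.bincount(idx, weights=amps, minlength=m_lines)
    spec.angular = out
    return out


def radial_spectrum(spec: SpectrumSet) -> np.ndarray:
    """Radial spectrum beta(r): amplitude sums over semicircles r = 1..M/2-1.

    Upper-half-plane off-DC pixels are binned by rounded integer radius in
    pixels; radii past M/2 - 1 (grid corners and the Nyquist row) are
    discarded.
    """
    m = spec.size
    mask, dy, dx = _half_plane_mask(m)
    r = np.rint(np.hypot(dy[mask], dx[mask])).astype(int)
    keep = (r >= 1) & (r <= m // 2 - 1)
    out = np.bincount(
        r[keep] - 1, weights=spec.amplitude2d[mask][keep], minlength=m // 2 - 1
    )
    spec.radial = out
    return out


def _require_angular(spec: SpectrumSet) -> np.ndarray:
    return spec.angular if spec.angular is not None else angular_spectrum(spec)


def _require_radial(spec: SpectrumSet) -> np.ndarray:
    return spec.radial if spec.radial is not None else radial_spectrum(spec)


def s_tdi(spec: SpectrumSet) -> float:
    """Texture direction index: mean over max of the angular spectrum."""
    a = _require_angular(spec)
    peak = a.max()
    if peak == 0.0:
        return math.nan
    return float(a.mean() / peak)


def s_rwi(spec: SpectrumSet) -> float:
    """Radial wave index: mean over max of the radial spectrum."""
    b = _require_radial(spec)
    peak = b.max()
    if peak == 0.0:
        return math.nan
    return float(b.mean() / peak)


def r_half(spec: SpectrumSet) -> float:
    """Interpolated radius where the integral radial spectrum is half its total.

    The cumulative sums beta_i(r) are linearly interpolated between integer
    radii (with beta_i(0) = 0); returns NaN for an all-zero spectrum.
    """
    b = _require_radial(spec)
    total = b.sum()
    if total <= 0.0:
        return math.nan
    cum = np.concatenate([[0.0], np.cumsum(b)]) / total  # index = radius
    k = int(np.searchsorted(cum, 0.5))  # first radius with cum >= 0.5
    if cum[k] == cum[k - 1]:
        return float(k)
    return float(k - 1 + (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1]))


def s_hw(
    spec: SpectrumSet,
    pixel_pitch_nm: float | None = None,
    options: SpectrumOptions | None = None,
) -> float:
    """Average half wavelength S_hw = dx (M-1) / (2 r_0.5), in nm.

    Insensitive to the overall map amplitude; decreases as spectral weight
    moves to finer scales.  With ``options.halve_shw=False`` the full
    median-radius wavelength dx (M-1) / r_0.5 is returned instead.
    """
    if options is None:
        options = SpectrumOptions()
    if pixel_pitch_nm is None:
        pixel_pitch_nm = spec.pixel_pitch_nm
    r05 = r_half(spec)
    if math.isnan(r05) or r05 <= 0.0:
        return math.nan
    wavelength = pixel_pitch_nm * (spec.size - 1) / r05
    return wavelength / 2.0 if options.halve_shw else wavelength


# ---------------------------------------------------------------------------
# 37-parameter areal texture suite
# ---------------------------------------------------------------------------

PARAMETER_FAMILIES: dict[str, tuple[str, ...]] = {
    "amplitude": ("Smean", "Sa", "Sq", "Ssk", "Sku", "Sp", "Sv", "Sz", "S10z"),
    "spatial": ("Sal", "Str20", "Str37", "Std", "Stdi", "Srw", "Srwi", "Shw", "Sfd"),
    "hybrid": ("Sdq", "Sdq6", "Sdr", "Ssc", "Sds", "S2A", "S3A"),
    "functional": (
        "Sbi",
        "Sci",
        "Svi",
        "Sk",
        "Spk",
        "Svk",
        "Smr1",
        "Smr2",
        "Sdc0-5",
        "Sdc5-10",
        "Sdc10-50",
        "Sdc50-95",
    ),
}

PARAMETER_NAMES: tuple[str, ...] = tuple(
    name for fam in PARAMETER_FAMILIES.values() for name in fam
)
assert len(PARAMETER_NAMES) == 37


@dataclass
class ParameterSet:
    """Named values of the 37-parameter suite for one map/channel.

    Undefined parameters (e.g. Ssk on a constant map) carry NaN as the
    missing-value marker.
    """

    values: dict[str, float]
    channel: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(PARAMETER_NAMES) - set(self.values)
        extra = set(self.values) - set(PARAMETER_NAMES)
        if missing or extra:
            raise ValueError(
                f"parameter set must contain exactly the 37 registry names; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)


def _local_extrema(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of strict 8-neighbour local maxima / minima (interior)."""
    maxf = ndimage.maximum_filter(z, size=3, mode="nearest")
    minf = ndimage.minimum_filter(z, size=3, mode="nearest")
    peaks = z >= maxf
    pits = z <= minf
    # strictness: exclude plateaus wider than one pixel
    plateau = maxf == minf
    peaks &= ~plateau
    pits &= ~plateau
    interior = np.zeros_like(peaks)
    interior[1:-1, 1:-1] = True
    return peaks & interior, pits & interior


def _ten_point_height(z: np.ndarray) -> float:
    peaks, pits = _local_extrema(z)
    ph = np.sort(z[peaks])[::-1][:5]
    pv = np.sort(z[pits])[:5]
    if ph.size == 0 or pv.size == 0:
        return math.nan
    return float(ph.mean() - pv.mean())


def _autocorrelation_lengths(
    z: np.ndarray, pitch: float, threshold: float, n_angles: int = 180
) -> tuple[float, float]:
    """Fastest / slowest decay lengths of the areal autocorrelation.

    The circular (FFT-based) normalized ACF is sampled along ``n_angles``
    rays from the centre; each ray reports the first radius at which the
    ACF drops below ``threshold``.  Returns (min, max) over rays in nm.
    """
    m = z.shape[0]
    var = z.var()
    if var == 0.0:
        return math.nan, math.nan
    f = np.fft.fft2(z - z.mean())
    acf = np.fft.fftshift(np.fft.ifft2(np.abs(f) ** 2).real) / (m * m * var)
    c = m // 2
    radii = np.arange(0, c, 0.5)
    angles = np.linspace(0.0, math.pi, n_angles, endpoint=False)
    first_cross = np.empty(n_angles)
    for k, a in enumerate(angles):
        rows = c + radii * math.sin(a)
        cols = c + radii * math.cos(a)
        prof = ndimage.map_coordinates(
            acf, np.vstack([rows, cols]), order=1, mode="nearest"
        )
        below = np.nonzero(prof < threshold)[0]
        if below.size == 0:
            first_cross[k] = radii[-1]
        else:
            j = below[0]
            if j == 0:
                first_cross[k] = 0.0
            else:
                # linear interpolation between the bracketing radii
                r0, r1 = radii[j - 1], radii[j]
                p0, p1 = prof[j - 1], prof[j]
                first_cross[k] = r0 + (p0 - threshold) / (p0 - p1) * (r1 - r0)
    return float(first_cross.min() * pitch), float(first_cross.max() * pitch)


def _gradients(z: np.ndarray, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    gy, gx = np.gradient(z, pitch)
    return gx, gy


_STENCIL6 = np.array([-1.0, 9.0, -45.0, 0.0, 45.0, -9.0, 1.0]) / 60.0


def _gradients6(z: np.ndarray, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    gx = ndimage.correlate1d(z, _STENCIL6, axis=1, mode="nearest") / pitch
    gy = ndimage.correlate1d(z, _STENCIL6, axis=0, mode="nearest") / pitch
    return gx, gy


def _bearing_height(d_sorted_desc: np.ndarray, p: float) -> float:
    """Height at bearing fraction p of the Abbott-Firestone curve.

    ``p`` is the fraction of the surface lying above the returned height;
    evaluated on the descending-sorted heights with linear interpolation.
    """
    n = d_sorted_desc.size
    pos = p * (n - 1)
    i = int(math.floor(pos))
    if i >= n - 1:
        return float(d_sorted_desc[-1])
    frac = pos - i
    return float(d_sorted_desc[i] * (1 - frac) + d_sorted_desc[i + 1] * frac)


def _void_volume(d_sorted_desc: np.ndarray, p: float) -> float:
    """Void volume per unit area under the plane at bearing fraction p."""
    h = _bearing_height(d_sorted_desc, p)
    return float(np.mean(np.clip(h - d_sorted_desc, 0.0, None)))


def _core_parameters(d_sorted_desc: np.ndarray) -> dict[str, float]:
    """Core roughness construction on the bearing curve (Sk family).

    Finds the 40%-bearing-width secant of minimum absolute slope on the
    Abbott-Firestone curve, extends it to bearing fractions 0 and 1 to
    obtain the core limits, and derives Sk, Spk, Svk, Smr1, Smr2.
    """
    n = d_sorted_desc.size
    p = np.linspace(0.0, 1.0, n)
    h = d_sorted_desc
    width = max(int(round(0.4 * (n - 1))), 1)
    slopes = (h[width:] - h[:-width]) / (p[width:] - p[:-width])
    j = int(np.argmin(np.abs(slopes)))
    slope = slopes[j]
    # secant through (p[j], h[j]) extended to p = 0 and p = 1
    h0 = h[j] - slope * p[j]
    h1 = h[j] + slope * (1.0 - p[j])
    sk = h0 - h1
    # Smr1/Smr2: bearing fractions where the curve crosses the core limits.
    smr1 = float(np.interp(-h0, -h, p))  # h is descending; negate for interp
    smr2 = float(np.interp(-h1, -h, p))
    above = np.clip(h - h0, 0.0, None)
    a1 = float(np.trapezoid(above, p))
    below = np.clip(h1 - h, 0.0, None)
    a2 = float(np.trapezoid(below, p))
    spk = 2.0 * a1 / smr1 if smr1 > 0 else math.nan
    svk = 2.0 * a2 / (1.0 - smr2) if smr2 < 1 else math.nan
    return {"Sk": float(sk), "Spk": spk, "Svk": svk, "Smr1": smr1, "Smr2": smr2}


def parameter_suite(
    smap: SurfaceMap, options: SpectrumOptions | None = None
) -> ParameterSet:
    """Evaluate the full 37-parameter areal texture suite on one map.

    Families:

    * amplitude — moments and extremes of the height distribution
      (Smean, Sa, Sq, Ssk, Sku, Sp, Sv, Sz, S10z);
    * spatial — autocorrelation lengths and aspect ratios (Sal, Str20,
      Str37), texture direction (Std, degrees from the +x frequency axis),
      the three Fourier indices (Stdi, Srwi, Shw), the dominant radial
      wavelength Srw, and a spectral-slope fractal dimension Sfd;
    * hybrid — slope, curvature, summit and area measures (Sdq, Sdq6, Sdr,
      Ssc, Sds, S2A, S3A);
    * functional — bearing-curve indices and section-height differences
      (Sbi, Sci, Svi, Sk family, Sdc bands).

    Adhesion maps enter as effective height: their values are treated
    exactly like heights in these formulas.  Parameters undefined on the
    input (e.g. Ssk of a constant map) are reported as NaN.
    """
    if options is None:
        options = SpectrumOptions()
    z = smap.values
    if not np.all(np.isfinite(z)):
        raise ValueError("map contains non-finite values")
    m = smap.size
    pitch = smap.pixel_pitch_nm
    out: dict[str, float] = {}

    mean = float(z.mean())
    d = z - mean
    sq = float(np.sqrt(np.mean(d**2)))
    out["Smean"] = mean
    out["Sa"] = float(np.mean(np.abs(d)))
    out["Sq"] = sq
    if sq == 0.0:
        out["Ssk"] = math.nan
        out["Sku"] = math.nan
    else:
        out["Ssk"] = float(np.mean(d**3) / sq**3)
        out["Sku"] = float(np.mean(d**4) / sq**4)
    out["Sp"] = float(d.max())
    out["Sv"] = float(-d.min())
    out["Sz"] = out["Sp"] + out["Sv"]
    out["S10z"] = _ten_point_height(d)

    # spatial family
    sal20, slowest20 = _autocorrelation_lengths(z, pitch, 0.2)
    out["Sal"] = sal20
    out["Str20"] = sal20 / slowest20 if slowest20 and slowest20 > 0 else math.nan
    sal37, slowest37 = _autocorrelation_lengths(z, pitch, 0.37)
    out["Str37"] = sal37 / slowest37 if slowest37 and slowest37 > 0 else math.nan

    spec = amplitude_spectrum(smap, options)
    ang = angular_spectrum(spec, options=options)
    rad = radial_spectrum(spec)
    if ang.max() > 0:
        out["Std"] = float(np.argmax(ang) * 180.0 / ang.size)
        out["Stdi"] = s_tdi(spec)
    else:
        out["Std"] = math.nan
        out["Stdi"] = math.nan
    if rad.max() > 0:
        r_dom = int(np.argmax(rad)) + 1
        out["Srw"] = pitch * (m - 1) / r_dom
        out["Srwi"] = s_rwi(spec)
        out["Shw"] = s_hw(spec, pitch, options)
        # fractal dimension from the log-log slope of the mean amplitude
        # per radius: power exponent beta = -2*slope, D = 4 - beta/2.
        mask, dy, dx = _half_plane_mask(m)
        rbin = np.rint(np.hypot(dy[mask], dx[mask])).astype(int)
        inside = (rbin >= 1) & (rbin <= m // 2 - 1)
        counts = np.bincount(rbin[inside] - 1, minlength=m // 2 - 1)
        radii = np.arange(1, m // 2)
        ok = (rad > 0) & (counts > 0) & (radii >= 2)
        if ok.sum() >= 3:
            slope = np.polyfit(np.log(radii[ok]), np.log(rad[ok] / counts[ok]), 1)[0]
            out["Sfd"] = float(np.clip(4.0 + slope, 2.0, 3.0))
        else:
            out["Sfd"] = math.nan
    else:
        out["Srw"] = math.nan
        out["Srwi"] = math.nan
        out["Shw"] = math.nan
        out["Sfd"] = math.nan

    # hybrid family
    gx, gy = _gradients(z, pitch)
    g2 = gx**2 + gy**2
    out["Sdq"] = float(np.sqrt(np.mean(g2)))
    gx6, gy6 = _gradients6(z, pitch)
    out["Sdq6"] = float(np.sqrt(np.mean(gx6**2 + gy6**2)))
    area_scale = np.sqrt(1.0 + g2)
    out["Sdr"] = float((np.mean(area_scale) - 1.0) * 100.0)
    peaks, _ = _local_extrema(z)
    n_summits = int(peaks.sum())
    area_um2 = (m * pitch * 1e-3) ** 2
    out["Sds"] = n_summits / area_um2
    if n_summits > 0:
        zxx = ndimage.correlate1d(z, [1.0, -2.0, 1.0], axis=1, mode="nearest") / pitch**2
        zyy = ndimage.correlate1d(z, [1.0, -2.0, 1.0], axis=0, mode="nearest") / pitch**2
        out["Ssc"] = float(np.mean(-0.5 * (zxx + zyy)[peaks]))
    else:
        out["Ssc"] = math.nan
    out["S2A"] = area_um2
    out["S3A"] = float(np.mean(area_scale) * area_um2)

    # functional family (bearing / Abbott-Firestone curve)
    ds = np.sort(d.ravel())[::-1]
    if sq == 0.0:
        for name in PARAMETER_FAMILIES["functional"]:
            out[name] = 0.0 if name.startswith("Sdc") or name == "Sk" else math.nan
        out["Spk"] = math.nan
        out["Svk"] = math.nan
    else:
        h05 = _bearing_height(ds, 0.05)
        out["Sbi"] = sq / h05 if h05 > 0 else math.nan
        vv05 = _void_volume(ds, 0.05)
        vv80 = _void_volume(ds, 0.8)
        out["Sci"] = (vv05 - vv80) / sq
        out["Svi"] = vv80 / sq
        out.update(_core_parameters(ds))
        for name, (p1, p2) in {
            "Sdc0-5": (0.0, 0.05),
            "Sdc5-10": (0.05, 0.10),
            "Sdc10-50": (0.10, 0.50),
            "Sdc50-95": (0.50, 0.95),
        }.items():
            out[name] = _bearing_height(ds, p1) - _bearing_height(ds, p2)

    return ParameterSet(values=out, channel=smap.channel, provenance=smap.provenance)
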