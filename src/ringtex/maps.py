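"""Surface-map container, pre-normalization, QC screening and cropping.

An AFM scan yields one square grid per data channel (height in nm, adhesion
channels in nN).  Adhesion values are treated downstream as an "effective
height", so a single container serves every channel.  Height maps carry an
arbitrary origin and an instrumental plane tilt, which is removed before any
parameter is computed; adhesion maps are used as recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SurfaceMap",
    "QCThresholds",
    "QCReport",
    "remove_plane_tilt",
    "screen_map",
    "crop_region",
]


@dataclass
class SurfaceMap:
    """One channel of an AFM scan on a square, even-sized pixel grid.

    Parameters
    ----------
    values : ndarray, shape (M, M)
        Channel values; nm for height, nN for adhesion channels.
    pixel_pitch_nm : float
        Lateral sampling step in nm (20 nm for the high-resolution scans
        this pipeline targets).
    channel : str
        Channel label, e.g. ``"height"`` or ``"restored adhesion"``.
    provenance : str
        Free-form source identifier (file path, generator seed, ...).
    """

    values: np.ndarray
    pixel_pitch_nm: float
    channel: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"map must be square, got shape {self.values.shape}")
        if self.values.shape[0] % 2 != 0:
            raise ValueError("map side must be even")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        if not self.pixel_pitch_nm > 0:
            raise ValueError("pixel_pitch_nm must be positive")

    @property
    def size(self) -> int:
        """Grid side length M in pixels."""
        return self.values.shape[0]

    @property
    def extent_nm(self) -> float:
        """Physical side length of the scan in nm."""
        return self.size * self.pixel_pitch_nm


@dataclass(frozen=True)
class QCThresholds:
    """Pass/fail thresholds for the automated artifact screen."""

    line_artifact: float = 1.0
    spike_fraction: float = 0.01
    saturation_fraction: float = 0.001


@dataclass(frozen=True)
class QCReport:
    line_artifact_score: float
    spike_fraction: float
    saturation_fraction: float
    passed: bool


def remove_plane_tilt(smap: SurfaceMap) -> SurfaceMap:
    """Subtract the least-squares plane ``a + b*x + c*y`` from a map.

    The returned map has zero mean; applying the operation twice is a
    no-op up to rounding.  In the default pipeline this is applied to the
    height channel only, since height origin and tilt are instrumental.
    """
    z = smap.values
    m = smap.size
    y, x = np.mgrid[0:m, 0:m].astype(float)
    design = np.column_stack([np.ones(m * m), x.ravel(), y.ravel()])
    coef, *_ = np.linalg.lstsq(design, z.ravel(), rcond=None)
    plane = (design @ coef).reshape(m, m)
    return replace(smap, values=z - plane)


def screen_map(smap: SurfaceMap, thresholds: QCThresholds | None = None) -> QCReport:
    """Automated proxy for the visual artifact screen applied to raw scans.

    Three scores are computed:

    * ``line_artifact_score`` — largest jump between adjacent row medians,
      in units of the map RMS; catches the scan-line offsets typical of
      tip instabilities.
    * ``spike_fraction`` — fraction of pixels farther than 6 MAD from the
      median; catches isolated spikes / debris.
    * ``saturation_fraction`` — fraction of pixels pinned at the extreme
      recorded value; catches range clipping.

    The map passes when every score is below its threshold.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    z = smap.values
    rms = float(np.std(z))
    if rms == 0.0:
        line_score = 0.0
        spike_frac = 0.0
    else:
        row_med = np.median(z, axis=1)
        line_score = float(np.max(np.abs(np.diff(row_med))) / rms)
        med = np.median(z)
        mad = np.median(np.abs(z - med))
        if mad == 0.0:
            spike_frac = float(np.mean(z != med))
        else:
            spike_frac = float(np.mean(np.abs(z - med) > 6.0 * mad))
    lo, hi = z.min(), z.max()
    if lo == hi:
        sat_frac = 0.0
    else:
        sat_frac = float(min(np.mean(z == lo), np.mean(z == hi)) * 2.0)
    passed = (
        line_score <= thresholds.line_artifact
        and spike_frac <= thresholds.spike_fraction
        and sat_frac <= thresholds.saturation_fraction
    )
    return QCReport(line_score, spike_frac, sat_frac, passed)


def crop_region(smap: SurfaceMap, center: tuple[int, int], size: int) -> SurfaceMap:
    """Extract a ``size`` x ``size`` sub-map centred on pixel ``center``.

    Mirrors selecting the central region of a cell from a wide survey scan
    so the analysis window lies entirely on the cell.  ``center`` is
    (row, col); the window is ``[c - size//2, c + size//2)`` in both axes
    and must lie inside the map.
    """
    if size % 2 != 0 or size < 2:
        raise ValueError("crop size must be a positive even number of pixels")
    r, c = center
    half = size // 2
    r0, r1 = r - half, r + half
    c0, c1 = c - half, c + half
    m = smap.size
    if r0 < 0 or c0 < 0 or r1 > m or c1 > m:
        raise ValueError(
            f"crop window rows {r0}:{r1}, cols {c0}:{c1} exceeds {m}x{m} map bounds"
        )
    return replace(smap, values=smap.values[r0:r1, c0:c1].copy())
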