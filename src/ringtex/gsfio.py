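"""File formats: Gwyddion Simple Field (GSF), CSV grids, trace text, reports.

GSF is the interchange format of the Gwyddion SPM suite: a one-line magic
string, ``key = value`` header lines (grid size, physical size, units,
title), NUL padding to a 4-byte boundary, then row-major little-endian
float32 data.  Physical sizes are stored in metres per the format; this
module converts to/from the package's nm-based :class:`SurfaceMap`.

CSV grids carry the same metadata in ``#``-prefixed header lines, and
force traces are two-column (time_s, force_nN) text with the generating
configuration in the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .extraction import ForceTrace
from .maps import SurfaceMap

__all__ = [
    "write_gsf",
    "read_gsf",
    "write_map_csv",
    "read_map_csv",
    "write_trace",
    "read_trace",
    "write_calibration_report",
    "read_calibration_report",
]

_GSF_MAGIC = "Gwyddion Simple Field 1.0"


def write_gsf(smap: SurfaceMap, path: str | Path) -> None:
    """Write a map as GSF (float32, metres for physical sizes)."""
    m = smap.size
    real_m = smap.extent_nm * 1e-9
    header = (
        f"{_GSF_MAGIC}\n"
        f"XRes = {m}\n"
        f"YRes = {m}\n"
        f"XReal = {real_m:.12g}\n"
        f"YReal = {real_m:.12g}\n"
        f"XYUnits = m\n"
        f"Title = {smap.channel or 'untitled'}\n"
    ).encode()
    pad = b"\x00" * (4 - len(header) % 4)
    data = smap.values.astype("<f4").tobytes()
    Path(path).write_bytes(header + pad + data)


def read_gsf(path: str | Path) -> SurfaceMap:
    raw = Path(path).read_bytes()
    nl = raw.find(b"\n")
    if nl < 0 or raw[:nl].decode(errors="replace") != _GSF_MAGIC:
        raise ValueError(f"{path}: not a Gwyddion Simple Field file")
    # header ends at the first NUL
    end = raw.find(b"\x00")
    if end < 0:
        raise ValueError(f"{path}: truncated GSF header")
    fields: dict[str, str] = {}
    for line in raw[nl + 1 : end].decode().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    try:
        xres, yres = int(fields["XRes"]), int(fields["YRes"])
        xreal = float(fields.get("XReal", 0.0))
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: malformed GSF header") from exc
    start = end + (4 - end % 4)
    data = np.frombuffer(raw[start:], dtype="<f4")
    if data.size != xres * yres:
        raise ValueError(
            f"{path}: payload has {data.size} samples, header says {xres * yres}"
        )
    pitch_nm = (xreal * 1e9 / xres) if xreal > 0 else 1.0
    return SurfaceMap(
        values=data.reshape(yres, xres).astype(float),
        pixel_pitch_nm=pitch_nm,
        channel=fields.get("Title", ""),
        provenance=str(path),
    )


def write_map_csv(smap: SurfaceMap, path: str | Path) -> None:
    header = (
        f"# channel: {smap.channel}\n"
        f"# pixel_pitch_nm: {smap.pixel_pitch_nm:.12g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, smap.values, delimiter=",", fmt="%.9g")


def read_map_csv(path: str | Path) -> SurfaceMap:
    channel, pitch = "", 1.0
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("channel:"):
                channel = body.split(":", 1)[1].strip()
            elif body.startswith("pixel_pitch_nm:"):
                pitch = float(body.split(":", 1)[1])
        elif line.strip():
            data_lines.append(line)
    values = np.loadtxt(data_lines, delimiter=",")
    return SurfaceMap(values=values, pixel_pitch_nm=pitch, channel=channel, provenance=str(path))


def write_trace(trace: ForceTrace, path: str | Path) -> None:
    meta = {k: v for k, v in trace.meta.items() if k != "truth"}
    header = f"# config: {json.dumps(meta)}\n# columns: time_s force_nN\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.column_stack([trace.time_s, trace.force_nN]), fmt="%.9g")


def read_trace(path: str | Path) -> ForceTrace:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("config:"):
                meta = json.loads(body.split(":", 1)[1])
        elif line.strip():
            data_lines.append(line)
    arr = np.loadtxt(data_lines)
    return ForceTrace(time_s=arr[:, 0], force_nN=arr[:, 1], meta=meta)


def write_calibration_report(result, path: str | Path) -> None:
    """Flat key-value text report of a calibration."""
    lines = [
        f"deflection_sensitivity_nm_v = {result.deflection_sensitivity_nm_v:.9g}",
        f"spring_constant_n_m = {result.spring_constant_n_m:.9g}",
        f"fit_quality = {result.fit_quality:.9g}",
        f"resonance_freq_hz = {result.resonance_freq_hz:.9g}",
        f"q_factor = {result.q_factor:.9g}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration_report(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            out[k.strip()] = float(v)
    return out
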