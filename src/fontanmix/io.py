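"""Configuration files, VTK velocity-field I/O and the run manifest.

External CFD output can be ingested as a time series of legacy-ASCII VTK
structured-points files (one file per stored phase of the cardiac cycle,
each carrying a 3-component ``velocity`` point-data array on a shared
regular grid).  The resulting field interpolates trilinearly in space and
periodic-linearly in time.  The same format is written by
:func:`write_field_vtk` for visual inspection of synthetic fields.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .config import FlowConfig


def load_config(path) -> FlowConfig:
    """Load and validate a JSON virtual-patient configuration.

    Unspecified fields take the documented defaults (7500 HV particles per
    step, 100 time steps per cycle, 12-cycle tracking horizon, ...).
    Validation errors name the offending field.
    """
    raw = json.loads(Path(path).read_text())
    try:
        return FlowConfig(**raw)
    except Exception as err:  # pydantic ValidationError already names fields
        raise ValueError(f"invalid configuration {path}: {err}") from err


def config_hash(config: FlowConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# legacy-ASCII VTK structured points


def write_field_vtk(field, path, dims=(33, 33, 33), t: float = 0.0) -> None:
    """Sample a velocity field on a regular grid and write legacy-ASCII VTK."""
    nx, ny, nz = dims
    a, L = field.a, field.L
    xg = np.linspace(-a, a, nx)
    yg = np.linspace(-a, a, ny)
    zg = np.linspace(0, L, nz)
    X, Y, Z = np.meshgrid(xg, yg, zg, indexing="ij")
    u, v, w = field.velocity(X, Y, Z, t)
    vec = np.stack([u, v, w], axis=-1)
    # VTK structured points iterate x fastest, z slowest
    flat = vec.transpose(2, 1, 0, 3).reshape(-1, 3)
    lines = [
        "# vtk DataFile Version 3.0",
        f"fontanmix velocity field t={t}",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {-a} {-a} 0.0",
        f"SPACING {2 * a / (nx - 1)} {2 * a / (ny - 1)} {L / (nz - 1)}",
        f"POINT_DATA {nx * ny * nz}",
        "VECTORS velocity double",
    ]
    body = "\n".join(" ".join(f"{c:.9g}" for c in row) for row in flat)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def _read_structured_points(path):
    tokens = Path(path).read_text().split("\n")
    dims = origin = spacing = None
    data_start = None
    n_points = None
    for i, line in enumerate(tokens):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].upper()
        if key == "DATASET" and parts[1].upper() not in ("STRUCTURED_POINTS",):
            raise ValueError(f"{path}: unsupported dataset type {parts[1]}")
        elif key == "DIMENSIONS":
            dims = tuple(int(p) for p in parts[1:4])
        elif key == "ORIGIN":
            origin = tuple(float(p) for p in parts[1:4])
        elif key == "SPACING":
            spacing = tuple(float(p) for p in parts[1:4])
        elif key == "POINT_DATA":
            n_points = int(parts[1])
        elif key == "VECTORS":
            if parts[1] != "velocity":
                raise ValueError(f"{path}: expected a 'velocity' vector array, found {parts[1]}")
            data_start = i + 1
            break
    if dims is None or origin is None or spacing is None:
        raise ValueError(f"{path}: missing structured-points geometry headers")
    if data_start is None:
        raise ValueError(f"{path}: missing 'velocity' VECTORS point data")
    values = np.array(" ".join(tokens[data_start:]).split(), dtype=float)
    if values.size != 3 * n_points:
        raise ValueError(f"{path}: expected {3 * n_points} velocity components, found {values.size}")
    nx, ny, nz = dims
    vec = values.reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)  # -> (nx, ny, nz, 3)
    axes = tuple(origin[d] + spacing[d] * np.arange(dims[d]) for d in range(3))
    return axes, vec


@dataclass
class InterpolatedField:
    """Velocity field interpolated from gridded snapshots of one period.

    Trilinear in space; periodic linear in time between the stored phases.
    Queries outside the grid bounds return NaN (an out-of-domain signal for
    the integrator).
    """

    axes: tuple
    snapshots: np.ndarray  # (n_times, nx, ny, nz, 3)
    times: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self._interps = [
            RegularGridInterpolator(self.axes, snap, bounds_error=False, fill_value=np.nan)
            for snap in self.snapshots
        ]

    @property
    def a(self) -> float:
        return float(min(self.axes[0][-1], -self.axes[0][0], self.axes[1][-1], -self.axes[1][0]))

    @property
    def L(self) -> float:
        return float(self.axes[2][-1])

    def velocity(self, x, y, z, t):
        x = np.asarray(x, dtype=float)
        pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
        tt = float(t) % self.period
        idx = np.searchsorted(self.times, tt, side="right") - 1
        i0 = idx % len(self.times)
        i1 = (idx + 1) % len(self.times)
        t0 = self.times[i0]
        t1 = self.times[i1] if i1 > i0 else self.times[i1] + self.period
        frac = 0.0 if t1 == t0 else (tt - t0) / (t1 - t0)
        v = (1 - frac) * self._interps[i0](pts) + frac * self._interps[i1](pts)
        return v[..., 0], v[..., 1], v[..., 2]


def read_velocity_vtk(paths, times, period: float) -> InterpolatedField:
    """Build an interpolating field from a VTK snapshot time series.

    ``paths`` and ``times`` (time stamps within one period, ascending) must
    match; all files must share the same grid.
    """
    paths = list(paths)
    times = np.asarray(times, dtype=float)
    if len(paths) != times.size or len(paths) == 0:
        raise ValueError("need matching, non-empty lists of snapshot paths and time stamps")
    if np.any(np.diff(times) <= 0) or times[0] < 0 or times[-1] >= period:
        raise ValueError("snapshot times must ascend within [0, period)")
    axes0 = None
    snaps = []
    for p in paths:
        axes, vec = _read_structured_points(p)
        if axes0 is None:
            axes0 = axes
        else:
            for g0, g in zip(axes0, axes):
                if g0.shape != g.shape or not np.allclose(g0, g):
                    raise ValueError(f"{p}: snapshot grid does not match the first snapshot")
        snaps.append(vec)
    return InterpolatedField(axes=axes0, snapshots=np.stack(snaps), times=times, period=period)


def write_pathlines_vtk(pathlines, path) -> None:
    """Write pathlines as legacy-ASCII VTK polylines (one cell per particle).

    Point data carry the source label so HV and IVC trajectories can be
    coloured separately in a viewer.
    """
    pathlines = list(pathlines)
    n_points = sum(len(p.t) for p in pathlines)
    lines = [
        "# vtk DataFile Version 3.0",
        "fontanmix pathlines",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n_points} double",
    ]
    for p in pathlines:
        for row in p.xyz:
            lines.append(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}")
    size = sum(len(p.t) + 1 for p in pathlines)
    lines.append(f"LINES {len(pathlines)} {size}")
    offset = 0
    for p in pathlines:
        n = len(p.t)
        lines.append(" ".join(str(v) for v in [n, *range(offset, offset + n)]))
        offset += n
    lines.append(f"POINT_DATA {n_points}")
    lines.append("SCALARS label int")
    lines.append("LOOKUP_TABLE default")
    for p in pathlines:
        lines.extend([str(int(p.label))] * len(p.t))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run manifest


@dataclass
class RunManifest:
    """Provenance record for a pipeline run."""

    config_hash: str
    seed: int
    version: str
    runtimes: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    files: dict = field(default_factory=dict)  # name -> sha256

    def add_file(self, path) -> None:
        path = Path(path)
        self.files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def time_stage(self, stage: str, start: float) -> None:
        self.runtimes[stage] = round(time.perf_counter() - start, 3)

    def write(self, path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "runtimes": self.runtimes,
            "warnings": self.warnings,
            "files": self.files,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
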