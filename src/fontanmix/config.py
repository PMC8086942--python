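"""Virtual-patient configuration for the synthetic Fontan conduit.

The conduit is modelled as a square duct of half-width ``a`` and length
``L`` (caudal end at z = 0, cranial/pulmonary end at z = L).  Axes follow
the anatomical convention used throughout the package:

* x: right (negative) to left (positive),
* y: posterior (negative) to anterior (positive),
* z: caudal (0) to cranial (L).

Hepatic-venous (HV) and inferior-vena-cava (IVC) inflow are represented as
labelled sub-regions of the caudal release plane; the analysis planes sit at
``z_caudal`` (just above the HV/IVC confluence) and ``z_cranial`` (just
below the pulmonary bifurcation).
"""

from __future__ import annotations

import zlib
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator


class InletRegion(BaseModel):
    """Axis-aligned rectangular sub-region of the caudal cross-section."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    @model_validator(mode="after")
    def _ordered(self) -> "InletRegion":
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("inlet region must have positive extent")
        return self

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


def _default_hv_regions() -> list[InletRegion]:
    # two hepatic-vein ostia in the posterior half, right and left
    return [
        InletRegion(x_min=-0.9, x_max=0.0, y_min=-0.9, y_max=-0.05),
        InletRegion(x_min=0.0, x_max=0.9, y_min=-0.9, y_max=-0.05),
    ]


def _default_ivc_region() -> InletRegion:
    return InletRegion(x_min=-0.9, x_max=0.9, y_min=0.05, y_max=0.9)


class FlowConfig(BaseModel):
    """All parameters of one virtual patient plus run options.

    Geometry and kinematics are expressed in non-dimensional duct units
    (lengths in units of the duct half-width, times in seconds); volumetric
    flow rates are in l/min and only enter through the IVC:HV particle-count
    ratio and the cohort generator.
    """

    a: float = Field(default=1.0, gt=0, description="duct half-width")
    L: float = Field(default=20.0, gt=0, description="duct length")
    z_caudal: Optional[float] = Field(default=None, description="caudal analysis plane (default 0.1 L)")
    z_cranial: Optional[float] = Field(default=None, description="cranial analysis plane (default 0.9 L)")
    w0: float = Field(default=10.0, gt=0, description="peak axial velocity")
    T: float = Field(default=1.0, gt=0, description="cardiac period, s")
    n_steps: int = Field(default=100, ge=2, description="time steps per cardiac cycle")
    pulsatility: float = Field(default=0.55, ge=0, lt=2, description="(Q_max - Q_min)/Q_mean of the waveform")
    eps: float = Field(default=0.15, ge=0, description="transverse (blinking) mixing amplitude, fraction of w0")
    tau: float = Field(default=0.5, gt=0, description="blink half-period, s")
    split_fraction: float = Field(default=0.5, gt=0, lt=1, description="fraction of outlet flux routed to the LPA")
    q_ivc: float = Field(default=3.0, gt=0, description="IVC flow, l/min")
    q_hv: float = Field(default=1.5, gt=0, description="total hepatic-venous flow, l/min")
    hv_regions: list[InletRegion] = Field(default_factory=_default_hv_regions)
    ivc_region: InletRegion = Field(default_factory=_default_ivc_region)
    seed: int = Field(default=0, ge=0)

    # run options
    n_hv: int = Field(default=7500, ge=1, description="HV particles released per time step")
    substeps: int = Field(default=10, ge=1, description="integrator substeps per time step")
    mixing_cycles: int = Field(default=5, ge=1, description="release cycles for the mixing analysis")
    hfd_min_cycles: int = Field(default=5, ge=1)
    hfd_max_cycles: int = Field(default=12, ge=1)

    @model_validator(mode="after")
    def _fill_and_check(self) -> "FlowConfig":
        if self.z_caudal is None:
            self.z_caudal = 0.1 * self.L
        if self.z_cranial is None:
            self.z_cranial = 0.9 * self.L
        if not (0.0 < self.z_caudal < self.z_cranial < self.L):
            raise ValueError("analysis planes must satisfy 0 < z_caudal < z_cranial < L")
        if not self.hv_regions:
            raise ValueError("at least one hepatic-vein inlet region is required")
        for reg in [*self.hv_regions, self.ivc_region]:
            if max(abs(reg.x_min), abs(reg.x_max), abs(reg.y_min), abs(reg.y_max)) > self.a:
                raise ValueError("inlet regions must lie inside the duct cross-section")
        if self.hfd_max_cycles < self.hfd_min_cycles:
            raise ValueError("hfd_max_cycles must be >= hfd_min_cycles")
        return self

    @property
    def q_conduit(self) -> float:
        """Total conduit flow, l/min (IVC plus hepatic-venous)."""
        return self.q_ivc + self.q_hv

    @property
    def dt(self) -> float:
        return self.T / self.n_steps

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage random generator derived from the seed.

        Each pipeline stage consumes its own substream so stages can be
        re-run in isolation without disturbing the others.
        """
        tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))


def generate_cohort(
    n_patients: int,
    seed: int = 0,
    eps_max: float = 0.3,
    base: Optional[FlowConfig] = None,
) -> list[FlowConfig]:
    """Sample a virtual cohort of Fontan patients.

    Flow rates follow the measured cohort dispersion (Q_IVC ~ N(3.0, 0.7),
    Q_HV ~ N(1.5, 0.6) l/min, truncated positive); the pulmonary split
    fraction is uniform on (0.3, 0.7) and the mixing amplitude uniform on
    (0, eps_max).  Deterministic given the seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x636F686F]))
    template = base.model_dump() if base is not None else {}
    cohort = []
    for i in range(n_patients):
        q_ivc = _truncated_normal(rng, 3.0, 0.7)
        q_hv = _truncated_normal(rng, 1.5, 0.6)
        s = rng.uniform(0.3, 0.7)
        eps = rng.uniform(0.0, eps_max)
        fields = dict(template)
        fields.update(
            q_ivc=q_ivc,
            q_hv=q_hv,
            split_fraction=s,
            eps=eps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(FlowConfig(**fields))
    return cohort


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError("truncated normal sampling failed")  # pragma: no cover
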