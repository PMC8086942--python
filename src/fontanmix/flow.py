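"""Analytic, divergence-free, time-periodic duct flow fields.

The axial profile is a product-cosine "parabolic-like" laminar profile,
w(x, y, t) = w0 cos(pi x / 2a) cos(pi y / 2a) q(t), which vanishes on the
duct wall and is maximal on the axis.  Transverse stirring is a blinking
sine flow: during the first half of each blink period 2*tau the flow shears
in x with u = eps w0 sin(pi y / a + phi); during the second half it shears
in y with v = eps w0 sin(pi x / a + phi').  Because u depends only on y,
v only on x, and w is independent of z, the field is divergence-free by
construction; eps = 0 gives perfectly segregated parallel streams while
large eps * tau produces near-uniform chaotic mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d
from scipy.optimize import brentq

from .config import FlowConfig


def pulsatile_waveform(t, pulsatility: float, period: float):
    """Dimensionless flow factor q(t) = 1 + (P/2) sin(2 pi t / T).

    The time mean of q over one period is exactly 1 and
    (q_max - q_min) / q_mean equals the pulsatility P.  P must be < 2,
    otherwise the flow would reverse.
    """
    if not 0.0 <= pulsatility < 2.0:
        raise ValueError("pulsatility must be in [0, 2) to keep the flow forward")
    if period <= 0:
        raise ValueError("period must be positive")
    return 1.0 + 0.5 * pulsatility * np.sin(2.0 * np.pi * np.asarray(t) / period)


@dataclass
class BlinkingDuctField:
    """Time-periodic velocity field in the square duct [-a, a]^2 x [0, L]."""

    a: float
    L: float
    w0: float
    period: float
    pulsatility: float = 0.0
    eps: float = 0.0
    tau: float = 0.25
    phase_u: float = 0.0
    phase_v: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a, self.L, self.period, self.w0) <= 0:
            raise ValueError("a, L, period and w0 must all be positive")
        if self.eps < 0 or self.tau <= 0:
            raise ValueError("eps must be >= 0 and tau > 0")

    def axial_profile(self, x, y):
        """Axial velocity shape (no waveform), clipped to zero outside the duct."""
        cx = np.clip(np.cos(0.5 * np.pi * np.asarray(x) / self.a), 0.0, None)
        cy = np.clip(np.cos(0.5 * np.pi * np.asarray(y) / self.a), 0.0, None)
        return self.w0 * cx * cy

    def waveform(self, t):
        return pulsatile_waveform(t, self.pulsatility, self.period)

    #: the transverse stirring is piecewise constant in time; integrators may
    #: freeze the blink regime per substep via ``t_blink`` (see tracing)
    blinking = True
    #: allow the fused single-pass RK4 kernel (numerically equivalent to the
    #: generic path; disable to force the generic field-interface route)
    fast_kernel: bool = True

    @property
    def kernel_params(self):
        if not self.fast_kernel:
            return None
        return (self.a, self.w0, self.pulsatility, self.period, self.eps, self.tau, self.phase_u, self.phase_v)

    def velocity(self, x, y, z, t, t_blink=None):
        """Velocity (u, v, w) at position arrays (x, y, z) and scalar time t.

        ``t_blink`` optionally fixes the time at which the blink regime
        (x-shear vs y-shear) is evaluated, so that a multi-stage integrator
        can hold the regime constant across one substep.
        """
        w = self.axial_profile(x, y) * self.waveform(t)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.eps == 0.0:
            zero = np.zeros_like(w)
            return zero, zero.copy(), w
        amp = self.eps * self.w0
        if ((t if t_blink is None else t_blink) % (2.0 * self.tau)) < self.tau:
            u = amp * np.sin(np.pi * y / self.a + self.phase_u)
            v = np.zeros_like(u)
        else:
            v = amp * np.sin(np.pi * x / self.a + self.phase_v)
            u = np.zeros_like(v)
        u = np.broadcast_to(u, w.shape).copy()
        v = np.broadcast_to(v, w.shape).copy()
        return u, v, w

    def in_section(self, x, y):
        return (np.abs(x) <= self.a) & (np.abs(y) <= self.a)


def make_duct_field(config: FlowConfig) -> BlinkingDuctField:
    """Build the blinking duct field for one virtual patient.

    The blink phases phi, phi' are drawn once from the configuration's
    seeded generator so the field is reproducible per patient.
    """
    rng = config.rng("field-phases")
    phase_u, phase_v = rng.uniform(0.0, 2.0 * np.pi, size=2)
    return BlinkingDuctField(
        a=config.a,
        L=config.L,
        w0=config.w0,
        period=config.T,
        pulsatility=config.pulsatility,
        eps=config.eps,
        tau=config.tau,
        phase_u=float(phase_u),
        phase_v=float(phase_v),
    )


def solve_split_threshold(
    field,
    s: float,
    z: float | None = None,
    n_x: int = 2049,
    n_y: int = 513,
    n_t: int = 32,
) -> float:
    """x-threshold such that the time-mean axial flux with x > x_split is s of the total.

    Particles reaching the cranial end with x > x_split are classified LPA,
    the rest RPA; s is the prescribed LPA fraction of pulmonary flow.  The
    time-mean axial flux is integrated on a tensor grid (trapezoid in x and
    y, uniform sampling in t over one period) and the threshold found by
    root bracketing on the cumulative flux to relative tolerance 1e-8.
    """
    if not 0.0 < s < 1.0:
        raise ValueError("split fraction s must lie strictly between 0 and 1")
    a = field.a
    if z is None:
        z = getattr(field, "L", 1.0)
    xg = np.linspace(-a, a, n_x)
    yg = np.linspace(-a, a, n_y)
    X, Y = np.meshgrid(xg, yg, indexing="ij")
    wbar = np.zeros_like(X)
    times = np.arange(n_t) * field.period / n_t
    for t in times:
        _, _, w = field.velocity(X, Y, np.full_like(X, min(z, field.L) * 0.999), t)
        wbar += w
    wbar /= n_t
    row = np.trapezoid(wbar, yg, axis=1)
    from scipy.integrate import cumulative_trapezoid

    cum = cumulative_trapezoid(row, xg, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise ValueError("no net axial flux through the outlet plane")
    frac_right = interp1d(xg, 1.0 - cum / total, kind="linear")

    def f(x):
        return float(frac_right(x)) - s

    lo, hi = -a, a
    # frac_right is monotone decreasing from 1 to 0
    if f(lo) <= 0:
        return lo
    if f(hi) >= 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12 * a, rtol=1e-14))


@dataclass
class SeedPlan:
    """Labelled particle release positions on one plane."""

    x: np.ndarray
    y: np.ndarray
    z: float
    label: np.ndarray  # tracing.LABEL_* codes
    subregion: np.ndarray
    counts: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.x.size


def apportion_largest_remainder(weights, total: int) -> np.ndarray:
    """Split ``total`` into integer counts proportional to ``weights``.

    Largest-remainder (Hamilton) rounding: counts sum exactly to ``total``;
    ties go to the lower index.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def seed_plan(
    config: FlowConfig,
    n_hv: int | None = None,
    rng: np.random.Generator | None = None,
    include_ivc: bool = True,
) -> SeedPlan:
    """Release positions for one time step at the caudal plane (z = 0).

    ``n_hv`` hepatic particles are apportioned over the HV sub-regions in
    proportion to their cross-sectional areas (largest-remainder rounding so
    counts sum exactly); the IVC count is round(n_hv * Q_IVC / Q_HV).
    Positions are uniform over each rectangular sub-region.
    """
    from .tracing import LABEL_HV, LABEL_IVC

    if n_hv is None:
        n_hv = config.n_hv
    if rng is None:
        rng = config.rng("seeding")
    areas = [r.area for r in config.hv_regions]
    if sum(areas) <= 0:
        raise ValueError("total hepatic-vein inlet area must be positive")
    hv_counts = apportion_largest_remainder(areas, n_hv)
    xs, ys, labels, subs = [], [], [], []
    for i, (reg, cnt) in enumerate(zip(config.hv_regions, hv_counts)):
        xs.append(rng.uniform(reg.x_min, reg.x_max, cnt))
        ys.append(rng.uniform(reg.y_min, reg.y_max, cnt))
        labels.append(np.full(cnt, LABEL_HV, dtype=np.int8))
        subs.append(np.full(cnt, i, dtype=np.int16))
    counts = {"hv": [int(c) for c in hv_counts]}
    if include_ivc:
        n_ivc = int(round(n_hv * config.q_ivc / config.q_hv))
        reg = config.ivc_region
        xs.append(rng.uniform(reg.x_min, reg.x_max, n_ivc))
        ys.append(rng.uniform(reg.y_min, reg.y_max, n_ivc))
        labels.append(np.full(n_ivc, LABEL_IVC, dtype=np.int8))
        subs.append(np.full(n_ivc, -1, dtype=np.int16))
        counts["ivc"] = n_ivc
    return SeedPlan(
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        z=0.0,
        label=np.concatenate(labels),
        subregion=np.concatenate(subs),
        counts=counts,
    )
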