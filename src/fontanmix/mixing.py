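"""Quadrant mixing index of hepatic-venous vs caval flow at a cross-section.

Each analysis plane is subdivided right-left and anterior-posterior into
four subsections.  For every time phase the hepatic (HV) fraction of
pathline transections in a subsection, f_s, is compared with the fraction
over the entire cross-section, f_g, through the tent ratio

    M = min(f_s / f_g, (1 - f_s) / (1 - f_g)),

which is 1 exactly when the subsection reproduces the global HV:IVC ratio
(perfect mixing) and 0 exactly when the subsection is pure (no mixing).
Phases where a subsection receives no transections, or where the global
counts are single-label, carry no ratio information and are undefined
(NaN); cycle averages are taken over the defined phases only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracing import LABEL_HV, LABEL_IVC, TraceResult

log = logging.getLogger(__name__)

QUADRANTS = ("left-anterior", "left-posterior", "right-anterior", "right-posterior")

#: categorical mixing bins, half-open on the left
MIXING_BINS = (
    (0.0, 0.1, "no mixing"),
    (0.1, 0.3, "poor mixing"),
    (0.3, 0.5, "mild mixing"),
    (0.5, 0.7, "moderate mixing"),
    (0.7, 0.9, "good mixing"),
    (0.9, 1.0, "uniform mixing"),
)


def quadrant_of(x: float, y: float) -> str:
    """Quadrant name for an in-plane point (x > 0 left, y > 0 anterior).

    Points on a dividing axis are assigned to the positive (left/anterior)
    side.
    """
    lr = "left" if x >= 0 else "right"
    ap = "anterior" if y >= 0 else "posterior"
    return f"{lr}-{ap}"


def quadrant_index(x, y):
    """Vectorised quadrant codes, indexing into :data:`QUADRANTS`."""
    x = np.asarray(x)
    y = np.asarray(y)
    return np.where(x >= 0, 0, 2) + np.where(y >= 0, 0, 1)


@dataclass
class TransectionTable:
    """Per-phase, per-quadrant HV/IVC transection counts at one plane."""

    plane_id: str
    counts: np.ndarray  # (n_steps, 4 quadrants, 2 labels: [HV, IVC])

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[1:] != (4, 2):
            raise ValueError("counts must have shape (n_steps, 4, 2)")
        if np.any(self.counts < 0):
            raise ValueError("transection counts must be non-negative")

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_crossings(cls, crossings: pd.DataFrame, plane_id: str, cycle: int, n_steps: int):
        """Bin +z crossings of one analysis cycle by phase, quadrant and label."""
        df = crossings[(crossings["plane"] == plane_id) & (crossings["cycle"] == cycle)]
        counts = np.zeros((n_steps, 4, 2), dtype=np.int64)
        if len(df):
            q = quadrant_index(df["x"].to_numpy(), df["y"].to_numpy())
            lab = np.where(df["label"].to_numpy() == LABEL_HV, 0, 1)
            ph = df["phase"].to_numpy() - 1
            np.add.at(counts, (ph, q, lab), 1)
        return cls(plane_id=plane_id, counts=counts)


def mixing_index(n_hv_s, n_ivc_s, n_hv_g, n_ivc_g) -> float:
    """Mixing index M of one subsection against the whole cross-section.

    Undefined (NaN) when the subsection is empty or the cross-section is
    single-label (f_g in {0, 1}); otherwise the tent ratio in [0, 1].
    """
    if min(n_hv_s, n_ivc_s, n_hv_g, n_ivc_g) < 0:
        raise ValueError("transection counts must be non-negative")
    tot_g = n_hv_g + n_ivc_g
    if tot_g <= 0:
        raise ValueError("global transection counts must be positive")
    tot_s = n_hv_s + n_ivc_s
    f_g = n_hv_g / tot_g
    if tot_s == 0 or f_g in (0.0, 1.0):
        return float("nan")
    f_s = n_hv_s / tot_s
    return min(f_s / f_g, (1.0 - f_s) / (1.0 - f_g))


def cross_section_mixing(m_quadrants, counts, weighted: bool = True) -> float:
    """Combine quadrant M values of one phase into a cross-section M.

    By default the transection-count-weighted mean over defined quadrants;
    ``weighted=False`` gives the plain mean.  NaN when all quadrants are
    undefined.
    """
    m = np.asarray(m_quadrants, dtype=float)
    w = np.asarray(counts, dtype=float)
    ok = np.isfinite(m)
    if not ok.any():
        return float("nan")
    if not weighted:
        return float(m[ok].mean())
    if w[ok].sum() <= 0:
        return float("nan")
    return float(np.average(m[ok], weights=w[ok]))


@dataclass
class MixingResult:
    """Time-resolved and cycle-averaged mixing at one cross-section."""

    plane_id: str
    m_quadrant: np.ndarray  # (n_steps, 4), NaN where undefined
    m_cross: np.ndarray  # (n_steps,)
    m_average_quadrant: np.ndarray  # (4,)
    m_average_cross: float
    n_undefined_quadrant: np.ndarray  # (4,) phases with undefined M
    n_undefined_cross: int
    categories: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, q in enumerate(QUADRANTS):
            rows.append(
                {
                    "plane": self.plane_id,
                    "quadrant": q,
                    "m_average": self.m_average_quadrant[i],
                    "n_undefined_phases": int(self.n_undefined_quadrant[i]),
                    "category": self.categories.get(q),
                }
            )
        rows.append(
            {
                "plane": self.plane_id,
                "quadrant": "all",
                "m_average": self.m_average_cross,
                "n_undefined_phases": self.n_undefined_cross,
                "category": self.categories.get("all"),
            }
        )
        return pd.DataFrame(rows)

    def by_phase(self) -> pd.DataFrame:
        rows = []
        for ph in range(self.m_quadrant.shape[0]):
            for i, q in enumerate(QUADRANTS):
                rows.append({"plane": self.plane_id, "quadrant": q, "phase": ph + 1, "M": self.m_quadrant[ph, i]})
            rows.append({"plane": self.plane_id, "quadrant": "all", "phase": ph + 1, "M": self.m_cross[ph]})
        return pd.DataFrame(rows)


def average_mixing(table: TransectionTable, weighted: bool = True) -> MixingResult:
    """Per-phase M for each quadrant and the cross-section, with cycle averages.

    Averages are arithmetic means over the phases where M is defined; the
    number of undefined phases is reported alongside.
    """
    n_steps = table.n_steps
    m_q = np.full((n_steps, 4), np.nan)
    m_x = np.full(n_steps, np.nan)
    for ph in range(n_steps):
        c = table.counts[ph]
        n_hv_g, n_ivc_g = int(c[:, 0].sum()), int(c[:, 1].sum())
        if n_hv_g + n_ivc_g == 0:
            continue
        for qi in range(4):
            m_q[ph, qi] = mixing_index(int(c[qi, 0]), int(c[qi, 1]), n_hv_g, n_ivc_g)
        m_x[ph] = cross_section_mixing(m_q[ph], c.sum(axis=1), weighted=weighted)

    n_undef_q = np.sum(~np.isfinite(m_q), axis=0)
    n_undef_x = int(np.sum(~np.isfinite(m_x)))
    import warnings as _warnings

    with _warnings.catch_warnings():
        # a quadrant undefined at every phase yields an all-NaN column
        _warnings.simplefilter("ignore", RuntimeWarning)
        avg_q = np.nanmean(m_q, axis=0)
    avg_x = float(np.nanmean(m_x)) if n_undef_x < n_steps else float("nan")
    if n_undef_x == n_steps:
        log.warning("mixing undefined at every phase on plane %s", table.plane_id)

    categories = {}
    for i, q in enumerate(QUADRANTS):
        categories[q] = categorize(avg_q[i]) if np.isfinite(avg_q[i]) else None
    categories["all"] = categorize(avg_x) if np.isfinite(avg_x) else None
    return MixingResult(
        plane_id=table.plane_id,
        m_quadrant=m_q,
        m_cross=m_x,
        m_average_quadrant=avg_q,
        m_average_cross=avg_x,
        n_undefined_quadrant=n_undef_q,
        n_undefined_cross=n_undef_x,
        categories=categories,
    )


def categorize(m_average: float) -> str:
    """Categorical mixing label for a cycle-averaged mixing index."""
    if not 0.0 <= m_average <= 1.0:
        raise ValueError(f"M_average must lie in [0, 1], got {m_average}")
    for lo, hi, name in MIXING_BINS:
        if lo <= m_average < hi:
            return name
    return MIXING_BINS[-1][2]  # m_average == 1.0


def mixing_from_trace(result: TraceResult, analysis_cycle: int | None = None, weighted: bool = True):
    """Mixing results for every plane present in a trace, at one analysis cycle.

    The analysis cycle defaults to the last released cycle (the 5th under
    the standard schedule, by which time the transection statistics have
    reached their periodic steady state).
    """
    if analysis_cycle is None:
        analysis_cycle = result.cycles_run
    out = {}
    for plane_id in result.crossings["plane"].unique():
        table = TransectionTable.from_crossings(result.crossings, plane_id, analysis_cycle, result.n_steps)
        out[plane_id] = average_mixing(table, weighted=weighted)
    return out
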