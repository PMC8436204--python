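"""Nanoparticle-uptake metrics from pre/post-incubation layer masses.

The supported vesicle layer (SVL) has areal mass ``m_svl`` before
nanoparticle (NP) incubation; the net areal-mass gain at the post-uptake
plateau is ``m_np``.  The primary readout is the percent mass change
100·m_np/m_svl, which can be converted to a lipid-per-NP count ratio given
the membrane composition and the NP molar mass, and whose dependence on
cholesterol is summarized by a continuous linear-decline-then-flat
(segmented) trend with a grid-searched breakpoint.

The lipid/NP conversion exposes ``lipid_mass_fraction`` — the fraction of
the measured SVL areal mass attributed to lipid rather than trapped water —
as an explicit parameter (default 1.0).  QCM-D masses of intact vesicle
layers are dominated by coupled water, so real analyses should set this
fraction deliberately; keeping it explicit makes the assumption auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidReferenceError,
    MissingReferenceError,
    NoUptakeError,
)

#: molar masses, g·mol⁻¹
M_DOPC = 786.1
M_CHOL = 386.7


@dataclass(frozen=True)
class MembraneComposition:
    """DOPC/cholesterol mixture and the lipid fraction of the measured mass."""

    x_chol: float = 0.0
    m_dopc: float = M_DOPC
    m_chol: float = M_CHOL
    lipid_mass_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.x_chol < 1.0:
            raise ValueError("x_chol must be in [0, 1)")
        if self.m_dopc <= 0 or self.m_chol <= 0:
            raise ValueError("molar masses must be positive")
        if not 0.0 < self.lipid_mass_fraction <= 1.0:
            raise ValueError("lipid_mass_fraction must be in (0, 1]")

    @property
    def mean_lipid_molar_mass(self) -> float:
        """Mole-fraction-weighted molar mass of the lipid mixture, g·mol⁻¹."""
        return (1.0 - self.x_chol) * self.m_dopc + self.x_chol * self.m_chol


@dataclass
class UptakeResult:
    """Uptake metrics for one cholesterol condition."""

    m_svl: float  # ng·cm⁻²
    m_np: float  # ng·cm⁻²
    percent_mass: float
    lipid_per_np: float | None = None
    model_tag: str = "voigt"  # or "sauerbrey_sqrt_n"


@dataclass
class UptakeTrend:
    """Normalized uptake vs cholesterol with a segmented-trend summary.

    ``breakpoint`` is None when a single line describes the data as well as
    the two-segment model (fallback rule).  ``slopes`` is (decline slope,
    plateau slope); the plateau slope is 0 by construction for the
    two-segment model.
    """

    x_chol: np.ndarray
    uptake_norm: np.ndarray  # percent of the 0%-cholesterol reference
    breakpoint: float | None
    slopes: tuple[float, float]
    intercept: float
    sse_segmented: float
    sse_line: float
    line_fit: tuple[float, float] = field(default=(0.0, 0.0))  # slope, intercept


def uptake_percent(m_svl: float, m_np: float) -> float:
    """Percent change in SVL mass after NP incorporation: 100·m_np/m_svl."""
    if m_svl <= 0:
        raise InvalidReferenceError(f"m_svl must be positive, got {m_svl}")
    return 100.0 * m_np / m_svl


def lipid_per_np(
    m_svl: float,
    m_np: float,
    comp: MembraneComposition,
    np_molar_mass: float,
) -> float:
    """Lipid molecules per incorporated NP.

    ratio = (m_svl · lipid_mass_fraction / M̄) / (m_np / M_NP) with
    M̄ the mean lipid molar mass.  Homogeneous of degree 0 under joint
    rescaling of both masses, and of degree −1 in m_np alone.
    """
    if m_np <= 0:
        raise NoUptakeError(f"m_np must be positive to form a ratio, got {m_np}")
    if np_molar_mass <= 0:
        raise ValueError("np_molar_mass must be positive")
    n_lipid = m_svl * comp.lipid_mass_fraction / comp.mean_lipid_molar_mass
    n_np = m_np / np_molar_mass
    return n_lipid / n_np


def estimate_np_molar_mass(
    core_diameter_nm: float = 2.4,
    gold_density_g_cm3: float = 19.32,
    ligand_density_per_nm2: float = 4.7,
    mus_fraction: float = 0.7,
    m_mus: float = 266.4,
    m_ot: float = 146.3,
) -> float:
    """Rough molar mass (g·mol⁻¹) of a MUS:OT-coated gold NP.

    Gold core mass from diameter and bulk gold density plus a ligand shell
    at a typical thiol grafting density with the given MUS:OT ratio
    (thiolate molar masses).  Intended as an order-of-magnitude helper for
    lipid/NP conversions; supply a measured molar mass when available.
    """
    if core_diameter_nm <= 0:
        raise ValueError("core diameter must be positive")
    n_a = 6.02214076e23
    vol_cm3 = math.pi / 6.0 * (core_diameter_nm * 1e-7) ** 3
    core = vol_cm3 * gold_density_g_cm3 * n_a
    surface_nm2 = math.pi * core_diameter_nm**2
    n_ligands = ligand_density_per_nm2 * surface_nm2
    shell = n_ligands * (mus_fraction * m_mus + (1.0 - mus_fraction) * m_ot)
    return core + shell


def segmented_uptake_trend(
    points: list[tuple[float, float]],
    reference_chol: float = 0.0,
    grid_step: float = 1.0,
    fallback_factor: float = 0.5,
) -> UptakeTrend:
    """Fit a continuous linear-decline-then-flat model to uptake vs cholesterol.

    Uptake values are first normalized so the ``reference_chol`` condition
    reads exactly 100%.  The two-segment model y = a + b·min(x, c) is fitted
    by linear least squares for every candidate breakpoint c on a
    ``grid_step``-resolution grid strictly inside the x-range; the c with the
    smallest residual sum of squares wins (ties → smallest c).  If the best
    segmented fit does not beat ``fallback_factor`` times the single-line
    residual, the trend is declared linear and ``breakpoint`` is None.
    """
    if len(points) < 4:
        raise InsufficientDataError("segmented trend needs at least 4 conditions")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    ref_mask = np.isclose(x, reference_chol)
    if not ref_mask.any():
        raise MissingReferenceError(
            f"no condition at the reference cholesterol {reference_chol} mol%"
        )
    y_ref = float(y[ref_mask].mean())
    if y_ref == 0:
        raise InvalidReferenceError("reference uptake is zero; cannot normalize")
    yn = 100.0 * y / y_ref

    order = np.argsort(x)
    x, yn = x[order], yn[order]

    # single line
    A_line = np.column_stack([np.ones_like(x), x])
    coef_line, *_ = np.linalg.lstsq(A_line, yn, rcond=None)
    sse_line = float(np.sum((A_line @ coef_line - yn) ** 2))

    lo = math.floor(x.min()) + grid_step
    hi = math.ceil(x.max()) - grid_step
    best = None  # (sse, c, a, b)
    c = lo
    while c <= hi + 1e-9:
        A = np.column_stack([np.ones_like(x), np.minimum(x, c)])
        coef, *_ = np.linalg.lstsq(A, yn, rcond=None)
        sse = float(np.sum((A @ coef - yn) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, c, coef[0], coef[1])
        c += grid_step
    assert best is not None
    sse_seg, c_best, a_seg, b_seg = best

    if sse_seg < fallback_factor * sse_line:
        return UptakeTrend(
            x_chol=x, uptake_norm=yn, breakpoint=float(c_best),
            slopes=(float(b_seg), 0.0), intercept=float(a_seg),
            sse_segmented=sse_seg, sse_line=sse_line,
            line_fit=(float(coef_line[1]), float(coef_line[0])),
        )
    return UptakeTrend(
        x_chol=x, uptake_norm=yn, breakpoint=None,
        slopes=(float(coef_line[1]), float(coef_line[1])),
        intercept=float(coef_line[0]),
        sse_segmented=sse_seg, sse_line=sse_line,
        line_fit=(float(coef_line[1]), float(coef_line[0])),
    )
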