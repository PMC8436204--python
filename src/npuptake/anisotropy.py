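"""Steady-state fluorescence anisotropy of membrane probes (DPH).

The anisotropy r of a rod-like fluorophore such as
1,6-diphenyl-1,3,5-hexatriene (DPH) embedded in a bilayer reports on acyl
chain order: tighter lipid packing slows probe rotation and raises r.
Intensities are measured with vertical/horizontal polarizer combinations
(I_VV, I_VH, I_HV, I_HH); the instrument G factor G = I_HV/I_HH corrects the
detection-path polarization bias:

    r = (I_VV − G·I_VH) / (I_VV + 2·G·I_VH)

Cholesterol increases DOPC chain packing, so r grows — linearly over the
0–45 mol % range — which :func:`linear_trend` quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateIntensityError, SingularDesignError
from .kinetics import LinearFitResult, _ols_line


@dataclass(frozen=True)
class PolarizedIntensities:
    """Background-corrected polarized intensities (arbitrary units, >= 0)."""

    i_vv: float
    i_vh: float
    i_hv: float
    i_hh: float

    def __post_init__(self):
        if min(self.i_vv, self.i_vh, self.i_hv, self.i_hh) < 0:
            raise ValueError("intensities must be nonnegative")


def anisotropy(p: PolarizedIntensities, g_correction: bool = True) -> float:
    """G-factor-corrected fluorescence anisotropy r.

    With ``g_correction`` False, G is taken as 1 (matched detection paths).
    r lies in (−0.5, 1] for nonnegative intensities; r = 1 when I_VH = 0 and
    r = 0 in the isotropic case I_VV = G·I_VH.
    """
    if g_correction:
        if p.i_hh <= 0:
            raise DegenerateIntensityError("G correction requires i_hh > 0")
        g = p.i_hv / p.i_hh
    else:
        g = 1.0
    denom = p.i_vv + 2.0 * g * p.i_vh
    if denom <= 0:
        raise DegenerateIntensityError(
            "total intensity i_vv + 2·G·i_vh must be positive"
        )
    return (p.i_vv - g * p.i_vh) / denom


def linear_trend(x, y, conf_level: float = 0.95) -> LinearFitResult:
    """Ordinary least squares y = slope·x + intercept with a slope CI.

    Exact on collinear input.  Raises :class:`SingularDesignError` when all
    x coincide.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise SingularDesignError("linear trend needs at least 3 points")
    if np.allclose(x, x[0]):
        raise SingularDesignError("all x values equal; slope is undefined")
    return _ols_line(x, y, conf_level)
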