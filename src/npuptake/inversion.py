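"""From raw multi-overtone QCM-D traces to plateau shifts and fitted Voigt layers.

Workflow: smooth the raw trace (moving average), locate the terminal plateau
of each experimental phase (robust-slope criterion), then invert the
per-overtone plateau (Δf, ΔD) pairs for the four Voigt film parameters by
bounded weighted least squares with a deterministic multistart grid.

The ρ–L degeneracy: in the thin-film model the frequency shift constrains
mostly the product ρ·L while ΔD constrains (L, η, μ); ρ and L separately can
be ill-determined.  Fits therefore always report the areal mass ρ·L as the
robust quantity and set ``identifiability_flag`` when the individual
parameters are much more uncertain than their product.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .errors import (
    EmptyTraceError,
    FitFailureError,
    InsufficientDataError,
    UnderdeterminedError,
)
from .qcm import (
    KG_M2_TO_NG_CM2,
    BulkLiquid,
    CrystalParams,
    ViscoelasticLayer,
    voigt_forward,
)

PHASES = ("baseline", "vesicles", "rinse", "nanoparticles", "final_rinse")

#: default parameter box for the Voigt inversion: (low, high) per parameter,
#: generous around the supported-vesicle-layer regime.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "rho": (500.0, 1500.0),  # kg·m⁻³
    "thickness": (1e-9, 1e-7),  # m
    "eta": (5e-4, 5e-2),  # Pa·s
    "mu": (1e2, 1e7),  # Pa
}

_PARAM_ORDER = ("rho", "thickness", "eta", "mu")


@dataclass
class QcmTrace:
    """Time-resolved per-overtone Δf/ΔD trace.

    ``delta_f`` and ``delta_d`` are (n_time, n_overtones) arrays; ``delta_d``
    is stored as a pure number.  ``phase`` optionally labels each time point
    with one of ``PHASES``.
    """

    time: np.ndarray
    overtones: tuple[int, ...]
    delta_f: np.ndarray
    delta_d: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        self.delta_d = np.asarray(self.delta_d, dtype=float)
        self.overtones = tuple(int(n) for n in self.overtones)
        if self.time.ndim != 1:
            raise ValueError("time must be 1-D")
        nt, nk = self.time.size, len(self.overtones)
        if self.delta_f.shape != (nt, nk) or self.delta_d.shape != (nt, nk):
            raise ValueError(
                f"delta_f/delta_d must have shape ({nt}, {nk}), got "
                f"{self.delta_f.shape} and {self.delta_d.shape}"
            )
        if nt > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)
            if self.phase.shape != (nt,):
                raise ValueError("phase must have one label per time point")

    def __len__(self) -> int:
        return self.time.size

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self) else 0.0

    def select_phase(self, label: str) -> "QcmTrace":
        """Sub-trace of the points carrying a given phase label."""
        if self.phase is None:
            raise ValueError("trace carries no phase labels")
        mask = self.phase == label
        if not mask.any():
            raise ValueError(f"no points labelled {label!r}")
        return QcmTrace(
            time=self.time[mask],
            overtones=self.overtones,
            delta_f=self.delta_f[mask],
            delta_d=self.delta_d[mask],
            phase=self.phase[mask],
        )


@dataclass
class PlateauResult:
    """Asymptotic per-overtone shifts over the detected terminal plateau."""

    overtones: tuple[int, ...]
    delta_f: np.ndarray  # Hz, per overtone
    delta_d: np.ndarray  # dimensionless, per overtone
    onset_time: float  # s
    achieved: bool

    def as_dict(self) -> dict[int, tuple[float, float]]:
        return {
            n: (float(f), float(d))
            for n, f, d in zip(self.overtones, self.delta_f, self.delta_d)
        }


@dataclass
class LayerFit:
    """Result of the Voigt inversion."""

    layer: ViscoelasticLayer
    residual_norm: float
    conf: dict[str, float] = field(default_factory=dict)  # 95% half-widths
    areal_mass: float = 0.0  # kg·m⁻²
    areal_mass_conf: float = 0.0
    identifiability_flag: bool = False
    overtones: tuple[int, ...] = ()
    n_starts_converged: int = 0

    def __post_init__(self):
        self.areal_mass = self.layer.areal_mass

    @property
    def areal_mass_ng_cm2(self) -> float:
        return self.areal_mass * KG_M2_TO_NG_CM2


def smooth_trace(trace: QcmTrace, window: int) -> QcmTrace:
    """Centered moving average with edge shrinkage; time grid unchanged.

    At the boundaries the window is truncated to the available points, so a
    constant trace is reproduced exactly and a linear ramp is unchanged at
    interior points.
    """
    if len(trace) == 0:
        raise EmptyTraceError("cannot smooth an empty trace")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(trace):
        raise ValueError(f"window {window} exceeds trace length {len(trace)}")
    if window == 1:
        return replace(trace)

    def _smooth(arr: np.ndarray) -> np.ndarray:
        out = np.empty_like(arr)
        half = window // 2
        n = arr.shape[0]
        csum = np.concatenate([np.zeros((1, arr.shape[1])), np.cumsum(arr, axis=0)])
        for i in range(n):
            lo = max(0, i - half)
            hi = min(n, i + half + 1)
            out[i] = (csum[hi] - csum[lo]) / (hi - lo)
        return out

    return QcmTrace(
        time=trace.time.copy(),
        overtones=trace.overtones,
        delta_f=_smooth(trace.delta_f),
        delta_d=_smooth(trace.delta_d),
        phase=None if trace.phase is None else trace.phase.copy(),
    )


def _robust_slope(t: np.ndarray, y: np.ndarray, max_points: int = 151) -> float:
    """Theil–Sen slope, subsampled for long segments (O(n²) pairs otherwise)."""
    if t.size > max_points:
        idx = np.linspace(0, t.size - 1, max_points).round().astype(int)
        t, y = t[idx], y[idx]
    if np.allclose(y, y[0]):
        return 0.0
    return float(stats.theilslopes(y, t)[0])


def detect_plateau(
    trace: QcmTrace,
    slope_tol: float = 0.05,
    min_duration: float = 1800.0,
    n_candidates: int = 120,
) -> PlateauResult:
    """Find the terminal plateau of a trace and report its asymptotic shifts.

    A plateau is the longest terminal segment on which the robust
    (Theil–Sen) slope of every overtone's Δf stays within ``slope_tol``
    (Hz per minute), both over the whole segment and over its initial
    ``min_duration`` window (for a saturating approach the initial window
    carries the steepest residual drift, so checking it prevents declaring
    a plateau too early), and that lasts at least ``min_duration`` seconds.
    The earliest onset satisfying the criterion is reported as the plateau
    onset.  The asymptotic *values* are averaged over the final
    ``min_duration`` window only: a mean over the whole segment would carry
    a bias of order slope_tol × segment length from the residual approach,
    whereas the terminal window sits closest to the asymptote.  If no
    qualifying segment exists the terminal-window mean is still returned,
    with ``achieved=False`` and a warning.
    """
    if len(trace) < 3:
        raise InsufficientDataError("plateau detection needs at least 3 points")
    if min_duration >= trace.span:
        raise ValueError("min_duration must be shorter than the trace span")
    tol_hz_s = slope_tol / 60.0
    t = trace.time
    t_end = t[-1]
    latest_onset = t_end - min_duration
    candidates = np.unique(
        np.searchsorted(t, np.linspace(t[0], latest_onset, n_candidates))
    )

    def _segment_ok(i: int) -> bool:
        seg = slice(i, len(trace))
        head = slice(i, int(np.searchsorted(t, t[i] + min_duration)) + 1)
        for k in range(len(trace.overtones)):
            if abs(_robust_slope(t[head], trace.delta_f[head, k])) > tol_hz_s:
                return False
            if abs(_robust_slope(t[seg], trace.delta_f[seg, k])) > tol_hz_s:
                return False
        return True

    onset_idx = None
    for i in candidates:
        if t[-1] - t[int(i)] < min_duration:
            break
        if _segment_ok(int(i)):
            onset_idx = int(i)
            break
    achieved = onset_idx is not None
    if not achieved:
        warnings.warn(
            "no terminal plateau found within slope tolerance; "
            "reporting mean over the final window",
            stacklevel=2,
        )
        onset_idx = int(np.searchsorted(t, t_end - min_duration))
    tail = slice(int(np.searchsorted(t, t_end - min_duration)), len(trace))
    return PlateauResult(
        overtones=trace.overtones,
        delta_f=trace.delta_f[tail].mean(axis=0),
        delta_d=trace.delta_d[tail].mean(axis=0),
        onset_time=float(t[onset_idx]),
        achieved=achieved,
    )


def _predict(theta_log: np.ndarray, free: list[str], fixed_vals: dict[str, float],
             bulk: BulkLiquid, crystal: CrystalParams, ns: list[int]) -> np.ndarray:
    params = dict(fixed_vals)
    for name, v in zip(free, theta_log):
        params[name] = 10.0**v
    layer = ViscoelasticLayer(**params)
    out = np.empty(2 * len(ns))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # thin-film warning handled by caller
        for j, n in enumerate(ns):
            out[2 * j], out[2 * j + 1] = voigt_forward(layer, bulk, crystal, n)
    return out


def fit_viscoelastic_layer(
    plateaus: PlateauResult | dict[int, tuple[float, float]],
    bulk: BulkLiquid,
    crystal: CrystalParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed: dict[str, float] | None = None,
    df_weight: str = "1/n",
    dd_scale: float = 1e8,
) -> LayerFit:
    """Invert per-overtone (Δf, ΔD) plateaus for the Voigt film parameters.

    Minimizes a weighted least-squares objective over all supplied overtones:
    Δf residuals are weighted by 1/n (so high overtones, with their larger
    raw shifts, do not dominate) and ΔD residuals are rescaled by
    ``dd_scale`` (default 1e8, deliberately overweighting dissipation: ΔD pins
    the film's viscoelastic correction, leaving the Δf residuals to fix the
    areal mass, which conditions the inversion far better than equal scales).  Free parameters are optimized in log10
    space within ``bounds`` from a deterministic multistart grid; the best
    local optimum is reported together with 95% confidence half-widths from
    the local curvature (Jacobian) at the optimum.

    Parameters in ``fixed`` (name → value) are held constant.  Raises
    :class:`UnderdeterminedError` when observations cannot constrain the
    free parameters, and :class:`FitFailureError` if no start converges.
    """
    obs = plateaus.as_dict() if isinstance(plateaus, PlateauResult) else dict(plateaus)
    ns = sorted(obs)
    fixed = dict(fixed or {})
    free = [p for p in _PARAM_ORDER if p not in fixed]
    n_obs = 2 * len(ns)
    if len(ns) < 2 or n_obs < len(free):
        raise UnderdeterminedError(
            f"{len(ns)} overtone(s) give {n_obs} observations for "
            f"{len(free)} free parameters; need >=2 overtones and enough data"
        )
    box = dict(DEFAULT_BOUNDS)
    box.update(bounds or {})
    lo = np.log10([box[p][0] for p in free])
    hi = np.log10([box[p][1] for p in free])

    y = np.empty(n_obs)
    w = np.empty(n_obs)
    for j, n in enumerate(ns):
        y[2 * j], y[2 * j + 1] = obs[n]
        w[2 * j] = 1.0 / n if df_weight == "1/n" else 1.0
        w[2 * j + 1] = dd_scale

    def resid(theta):
        return (_predict(theta, free, fixed, bulk, crystal, ns) - y) * w

    # deterministic multistart: 1/4 and 3/4 quantiles of each log-range
    starts = list(itertools.product(*[(l + 0.25 * (h - l), l + 0.75 * (h - l))
                                      for l, h in zip(lo, hi)]))
    starts.append(tuple((l + h) / 2 for l, h in zip(lo, hi)))

    best = None
    n_conv = 0
    for s in starts:
        try:
            sol = optimize.least_squares(
                resid, np.array(s), bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        if sol.success or sol.cost < np.inf:
            n_conv += int(sol.success)
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or n_conv == 0:
        raise FitFailureError(
            "Voigt inversion failed to converge from every start",
            best_residual=None if best is None else float(np.sqrt(2 * best.cost)),
        )

    params = dict(fixed)
    for name, v in zip(free, best.x):
        params[name] = 10.0**v
    layer = ViscoelasticLayer(**params)

    # curvature-based 95% half-widths in log10 space, propagated to linear
    dof = max(n_obs - len(free), 1)
    sigma2 = 2.0 * best.cost / dof
    J = best.jac
    conf: dict[str, float] = {}
    cov_log = None
    try:
        cov_log = sigma2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov_log = sigma2 * np.linalg.pinv(J.T @ J)
    half_log = 1.96 * np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
    for name, v, hw in zip(free, best.x, half_log):
        conf[name] = 10.0**v * math.log(10.0) * hw  # linear-scale half-width
    for name in fixed:
        conf[name] = 0.0

    # areal mass uncertainty and the rho–L identifiability flag.  The
    # thin-film model carries an exact scaling degeneracy
    # (rho, L, eta, mu) -> (c·rho, L/c, eta/c, mu/c) that leaves all
    # observables unchanged, so with rho and L both free the flag is based
    # on the *unscaled* curvature (sigma² cancels in the ratio) plus the
    # Jacobian conditioning, which detects the degeneracy even on noiseless
    # data where sigma² -> 0.
    am_conf = 0.0
    ident = False
    if "rho" in free and "thickness" in free:
        i, j = free.index("rho"), free.index("thickness")
        var_log_m = cov_log[i, i] + cov_log[j, j] + 2 * cov_log[i, j]
        am_conf = layer.areal_mass * math.log(10.0) * 1.96 * math.sqrt(max(var_log_m, 0.0))
        sv = np.linalg.svd(J, compute_uv=False)
        if sv[-1] <= 1e-7 * sv[0]:
            ident = True
        else:
            unscaled = np.linalg.pinv(J.T @ J)
            u_m = unscaled[i, i] + unscaled[j, j] + 2 * unscaled[i, j]
            if u_m > 0:
                ident = (math.sqrt(max(unscaled[i, i], 0.0) / u_m) > 3
                         or math.sqrt(max(unscaled[j, j], 0.0) / u_m) > 3)

    return LayerFit(
        layer=layer,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        conf=conf,
        areal_mass_conf=float(am_conf),
        identifiability_flag=bool(ident),
        overtones=tuple(ns),
        n_starts_converged=n_conv,
    )
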