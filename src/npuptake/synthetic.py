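"""Synthetic study generators with known ground truth.

Emulates the three data streams the analysis consumes, for a
DOPC/cholesterol study at 0/15/30/45 mol % cholesterol:

* QCM-D traces: baseline → vesicle deposition approaching the per-overtone
  (Δf, ΔD) of a ground-truth Voigt layer → rinse → NP incubation approaching
  the post-uptake layer (areal mass increased by the uptake truth) → final
  rinse, with additive Gaussian instrument noise per channel.
* First-ligand anchoring times: exponential waits with
  τ(c) = τ0·exp(ΔG(c)/k_BT), ΔG linear in cholesterol mole percent, Type-I
  censored at the run length; anchored-ligand counts by sequential
  exponential events in a fixed window.
* DPH polarized-intensity quadruples whose noiseless anisotropy is linear
  in cholesterol.

Scenario defaults echo the regime of the emulated study (SVL density near
0.762 g·cm⁻³ at 0% cholesterol and rising; barriers 12→32 kJ/mol across
15→45 mol %; 12 trials per condition) but every number is configuration,
not a constant.  The default τ0 is calibrated so that the 45% condition has
τ = 2× the 1 μs observation window, i.e. ~0.5 anchored ligands expected; a
consequence of combining this calibration with the steep barrier truth is
that low-cholesterol synthetic waits are much shorter than any physical
anchoring time — the generator reproduces the study's *relations*, not
absolute coarse-grained timescales.

Every generator is a deterministic function of (config, seed): streams are
derived from ``numpy.random.SeedSequence(seed, stream_index)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anisotropy import PolarizedIntensities
from .errors import ConfigError
from .inversion import QcmTrace
from .kinetics import KBT_300K, AnchoringSample, BarrierEstimate
from .qcm import BulkLiquid, CrystalParams, ViscoelasticLayer, voigt_forward

_STREAM_QCM = 1
_STREAM_ANCHOR = 2
_STREAM_ANIS = 3


@dataclass
class SyntheticStudyConfig:
    """Ground truth and noise model for one synthetic study."""

    chol_levels: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0)
    seed: int = 0

    # --- SVL viscoelastic truth (per mole percent cholesterol) ---
    svl_rho0: float = 762.0  # kg·m⁻³ at 0% chol
    svl_rho_slope: float = 1.8  # kg·m⁻³ per mol %
    svl_thickness: float = 15e-9  # m, composition-independent
    svl_eta0: float = 6e-3  # Pa·s
    svl_eta_slope: float = 5.0e-5  # Pa·s per mol %
    svl_mu0: float = 1.5e6  # Pa
    svl_mu_slope: float = 1.0e4  # Pa per mol %

    # --- QCM trace shape ---
    svl_formation_timescale: float = 1800.0  # s
    np_uptake_timescale: float = 5400.0  # s
    baseline_duration: float = 1800.0  # s
    rinse_duration: float = 1800.0  # s
    phase_spans: float = 8.0  # phase duration in units of its timescale
    dt: float = 15.0  # s
    overtones: tuple[int, ...] = (3, 5, 7, 9, 11, 13)
    crystal: CrystalParams = field(default_factory=CrystalParams)
    bulk: BulkLiquid = field(default_factory=BulkLiquid)
    noise_df: float = 0.3  # Hz, additive Gaussian on Δf
    noise_dd: float = 1e-7  # absolute, additive Gaussian on ΔD

    # --- NP uptake truth ---
    uptake_percent0: float = 18.0  # percent mass gain at 0% chol
    uptake_breakpoint: float = 35.0  # mol %
    uptake_residual_fraction: float = 0.2  # plateau level relative to 0% chol

    # --- anchoring kinetics truth ---
    barrier_intercept: float = 2.0  # kJ/mol (exact line through 12/21/32 at 15/30/45)
    barrier_slope: float = 2.0 / 3.0  # kJ/mol per mol %
    kbt: float = KBT_300K
    tau0: float = 2000.0 * math.exp(-32.0 / KBT_300K)  # ns; τ(45%) = 2× window
    trials_per_level: int = 12
    run_length: float = 5000.0  # ns
    window: float = 1000.0  # ns (1 μs)

    # --- anisotropy truth ---
    anis_intercept: float = 0.080  # r of DPH in pure DOPC
    anis_slope: float = 8.0 / 3000.0  # per mol %; r ≈ 0.20 at 45%
    g_factor: float = 0.9
    anis_replicates: int = 3
    anis_total_intensity: float = 900.0  # a.u., I_VV + 2·G·I_VH
    noise_intensity: float = 2.0  # a.u.

    def __post_init__(self):
        if len(set(self.chol_levels)) != len(self.chol_levels):
            raise ConfigError("cholesterol levels must be distinct")
        for name in ("svl_formation_timescale", "np_uptake_timescale", "dt",
                     "run_length", "window", "tau0", "kbt"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("noise_df", "noise_dd", "noise_intensity"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.trials_per_level < 1:
            raise ConfigError("trials_per_level must be >= 1")

    # ------- ground-truth accessors -------

    def _level_index(self, level: float) -> int:
        for i, c in enumerate(self.chol_levels):
            if math.isclose(c, level):
                return i
        raise ConfigError(f"cholesterol level {level} not in {self.chol_levels}")

    def svl_layer(self, level: float) -> ViscoelasticLayer:
        """Ground-truth SVL Voigt layer at a cholesterol level."""
        self._level_index(level)
        return ViscoelasticLayer(
            rho=self.svl_rho0 + self.svl_rho_slope * level,
            thickness=self.svl_thickness,
            eta=self.svl_eta0 + self.svl_eta_slope * level,
            mu=self.svl_mu0 + self.svl_mu_slope * level,
        )

    def uptake_percent_truth(self, level: float) -> float:
        """Percent areal-mass gain: linear decline to the breakpoint, then flat."""
        self._level_index(level)
        frac = min(level, self.uptake_breakpoint) / self.uptake_breakpoint
        return self.uptake_percent0 * (1.0 - (1.0 - self.uptake_residual_fraction) * frac)

    def post_np_layer(self, level: float) -> ViscoelasticLayer:
        """SVL layer after NP uptake: density raised by Δm/L, rest unchanged."""
        svl = self.svl_layer(level)
        dm = self.uptake_percent_truth(level) / 100.0 * svl.areal_mass
        return ViscoelasticLayer(
            rho=svl.rho + dm / svl.thickness,
            thickness=svl.thickness,
            eta=svl.eta,
            mu=svl.mu,
        )

    def barrier_truth(self, level: float) -> BarrierEstimate:
        return BarrierEstimate(
            chol_pct=level,
            delta_g=self.barrier_intercept + self.barrier_slope * level,
            source="synthetic_truth",
        )

    def tau_truth(self, level: float) -> float:
        """τ(c) = τ0 · exp(ΔG(c)/k_BT), ns."""
        return self.tau0 * math.exp(self.barrier_truth(level).delta_g / self.kbt)

    def anisotropy_truth(self, level: float) -> float:
        return self.anis_intercept + self.anis_slope * level

    def _rng(self, stream: int, *keys: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream, *keys)))


# ---------------------------------------------------------------------------


def simulate_qcm_experiment(cfg: SyntheticStudyConfig, level: float) -> QcmTrace:
    """One full QCM-D experiment trace at a cholesterol level.

    Phases: baseline (zero shifts) → vesicle deposition (saturating
    exponential toward the SVL truth's per-overtone Voigt prediction) →
    rinse (steady) → NP incubation (saturating exponential toward the
    post-uptake prediction) → final rinse (steady).  Additive Gaussian noise
    per channel; deterministic under (config.seed, level).
    """
    idx = cfg._level_index(level)
    rng = cfg._rng(_STREAM_QCM, idx)
    svl = cfg.svl_layer(level)
    post = cfg.post_np_layer(level)
    targets_svl = np.array([voigt_forward(svl, cfg.bulk, cfg.crystal, n)
                            for n in cfg.overtones])
    targets_post = np.array([voigt_forward(post, cfg.bulk, cfg.crystal, n)
                             for n in cfg.overtones])

    t_form = cfg.phase_spans * cfg.svl_formation_timescale
    t_np = cfg.phase_spans * cfg.np_uptake_timescale
    bounds = np.cumsum([
        cfg.baseline_duration, t_form, cfg.rinse_duration, t_np, cfg.rinse_duration,
    ])
    t = np.arange(0.0, bounds[-1], cfg.dt)
    nk = len(cfg.overtones)
    df = np.zeros((t.size, nk))
    dd = np.zeros((t.size, nk))
    phase = np.empty(t.size, dtype=object)

    masks = [
        (t < bounds[0], "baseline"),
        ((t >= bounds[0]) & (t < bounds[1]), "vesicles"),
        ((t >= bounds[1]) & (t < bounds[2]), "rinse"),
        ((t >= bounds[2]) & (t < bounds[3]), "nanoparticles"),
        (t >= bounds[3], "final_rinse"),
    ]
    for mask, label in masks:
        phase[mask] = label

    m_ves = masks[1][0]
    rise = 1.0 - np.exp(-(t[m_ves] - bounds[0]) / cfg.svl_formation_timescale)
    df[m_ves] = np.outer(rise, targets_svl[:, 0])
    dd[m_ves] = np.outer(rise, targets_svl[:, 1])

    m_rinse = masks[2][0]
    df[m_rinse] = targets_svl[:, 0]
    dd[m_rinse] = targets_svl[:, 1]

    m_np = masks[3][0]
    rise = 1.0 - np.exp(-(t[m_np] - bounds[2]) / cfg.np_uptake_timescale)
    df[m_np] = targets_svl[:, 0] + np.outer(rise, targets_post[:, 0] - targets_svl[:, 0])
    dd[m_np] = targets_svl[:, 1] + np.outer(rise, targets_post[:, 1] - targets_svl[:, 1])

    m_fin = masks[4][0]
    df[m_fin] = targets_post[:, 0]
    dd[m_fin] = targets_post[:, 1]

    if cfg.noise_df > 0:
        df = df + rng.normal(0.0, cfg.noise_df, df.shape)
    if cfg.noise_dd > 0:
        dd = dd + rng.normal(0.0, cfg.noise_dd, dd.shape)

    return QcmTrace(time=t, overtones=cfg.overtones, delta_f=df, delta_d=dd,
                    phase=phase)


def sample_anchoring_study(cfg: SyntheticStudyConfig) -> dict[float, AnchoringSample]:
    """Per-level first-anchoring waits and windowed anchor counts.

    Waits are exponential with the level's τ truth; waits exceeding the run
    length are censored at it.  Anchored-ligand counts follow sequential
    exponential inter-anchoring times (the first being the trial's own
    wait): by memorylessness the count within the window is exactly
    1 + Poisson((window − first wait)/τ) when the first anchoring falls
    inside the window, 0 otherwise.
    """
    out: dict[float, AnchoringSample] = {}
    for idx, level in enumerate(cfg.chol_levels):
        rng = cfg._rng(_STREAM_ANCHOR, idx)
        tau = cfg.tau_truth(level)
        raw = rng.exponential(tau, cfg.trials_per_level)
        censored = raw > cfg.run_length
        waits = np.where(censored, cfg.run_length, raw)
        remaining = np.maximum(cfg.window - raw, 0.0)
        counts = np.where(
            raw <= cfg.window, 1 + rng.poisson(remaining / tau), 0
        ).astype(float)
        out[level] = AnchoringSample(
            chol_pct=level, waits=waits, censored=censored,
            run_length=cfg.run_length, n_anchors_window=counts,
            window=cfg.window,
        )
    return out


def simulate_anisotropy_study(
    cfg: SyntheticStudyConfig,
) -> dict[float, list[PolarizedIntensities]]:
    """Polarized-intensity quadruples whose noiseless anisotropy is linear in chol.

    For target anisotropy r and G factor g, intensities are constructed from
    the fixed total T = I_VV + 2·g·I_VH: I_VV = T(1+2r)/3 and
    I_VH = T(1−r)/(3g), with I_HH fixed and I_HV = g·I_HH; Gaussian noise is
    then added to each channel (clipped at zero).
    """
    out: dict[float, list[PolarizedIntensities]] = {}
    for idx, level in enumerate(cfg.chol_levels):
        r = cfg.anisotropy_truth(level)
        if not -0.5 < r < 1.0:
            raise ConfigError(f"target anisotropy {r:.3f} at {level} mol% "
                              "outside (-0.5, 1)")
        rng = cfg._rng(_STREAM_ANIS, idx)
        T = cfg.anis_total_intensity
        i_hh = T / 2.0
        i_hv = cfg.g_factor * i_hh
        i_vv = T * (1.0 + 2.0 * r) / 3.0
        i_vh = T * (1.0 - r) / (3.0 * cfg.g_factor)
        reps = []
        for _ in range(cfg.anis_replicates):
            vals = np.array([i_vv, i_vh, i_hv, i_hh])
            if cfg.noise_intensity > 0:
                vals = np.clip(vals + rng.normal(0.0, cfg.noise_intensity, 4), 0.0, None)
            reps.append(PolarizedIntensities(*vals))
        out[level] = reps
    return out
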