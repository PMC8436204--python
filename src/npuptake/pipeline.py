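"""End-to-end study driver: synthetic generation → inversion → uptake → kinetics.

``run_full_study`` chains every stage of the analysis on a synthetic
scenario with known ground truth and emits a single deterministic JSON-able
report plus a run manifest (config digest, seed registry, stage outputs).
The same stage functions operate on real data loaded through
:mod:`npuptake.io`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .anisotropy import anisotropy, linear_trend
from .errors import NpUptakeError
from .inversion import detect_plateau, fit_viscoelastic_layer, smooth_trace
from .io import sha256_of
from .kinetics import (
    ThermalScale,
    arrhenius_consistency,
    barrier_vs_chol_fit,
    estimate_tau_mle,
    expected_anchors,
    fit_cumulative_poisson,
    lntau_vs_chol_fit,
)
from .qcm import KG_M2_TO_NG_CM2, sauerbrey_mass
from .synthetic import (
    SyntheticStudyConfig,
    sample_anchoring_study,
    simulate_anisotropy_study,
    simulate_qcm_experiment,
)
from .uptake import segmented_uptake_trend, uptake_percent

log = logging.getLogger("npuptake")

SMOOTH_WINDOW = 20  # points, the conventional display smoothing


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    tool_version: str
    config_digest: str
    seed: int
    stages: list[str] = field(default_factory=list)
    input_digests: dict[str, str] = field(default_factory=dict)


def analyze_qcm_level(cfg: SyntheticStudyConfig, level: float,
                      slope_tol: float = 0.05, min_duration: float = 1800.0) -> dict:
    """SVL formation + NP uptake analysis of one cholesterol condition.

    Returns both mass routes: the Voigt inversion (areal mass from the
    fitted film) and the √n-normalized Sauerbrey estimate, each applied to
    the vesicle-phase and NP-phase plateaus of the same trace.
    """
    trace = simulate_qcm_experiment(cfg, level)
    trace = smooth_trace(trace, SMOOTH_WINDOW)

    svl_phase = trace.select_phase("vesicles")
    np_phase = trace.select_phase("nanoparticles")
    plat_svl = detect_plateau(svl_phase, slope_tol=slope_tol, min_duration=min_duration)
    plat_np = detect_plateau(np_phase, slope_tol=slope_tol, min_duration=min_duration)

    fit_svl = fit_viscoelastic_layer(plat_svl, cfg.bulk, cfg.crystal)
    fit_np = fit_viscoelastic_layer(plat_np, cfg.bulk, cfg.crystal)
    m_svl_v = fit_svl.areal_mass_ng_cm2
    m_np_v = fit_np.areal_mass_ng_cm2 - m_svl_v

    # √n-Sauerbrey route on the same plateaus, averaged over overtones
    m_svl_s = float(np.mean([
        sauerbrey_mass(f, n, cfg.crystal, mode="sqrt_n")
        for n, f in zip(plat_svl.overtones, plat_svl.delta_f)
    ]))
    m_tot_s = float(np.mean([
        sauerbrey_mass(f, n, cfg.crystal, mode="sqrt_n")
        for n, f in zip(plat_np.overtones, plat_np.delta_f)
    ]))
    m_np_s = m_tot_s - m_svl_s

    return {
        "chol_pct": level,
        "plateau_svl_achieved": plat_svl.achieved,
        "plateau_np_achieved": plat_np.achieved,
        "voigt": {
            "m_svl_ng_cm2": m_svl_v,
            "m_np_ng_cm2": m_np_v,
            "percent_mass": uptake_percent(m_svl_v, m_np_v),
            "layer_density_g_cm3": fit_svl.layer.rho / 1000.0,
            "layer_thickness_nm": fit_svl.layer.thickness * 1e9,
            "identifiability_flag": fit_svl.identifiability_flag,
        },
        "sauerbrey_sqrt_n": {
            "m_svl_ng_cm2": m_svl_s,
            "m_np_ng_cm2": m_np_s,
            "percent_mass": uptake_percent(m_svl_s, m_np_s),
        },
        "truth": {
            "m_svl_ng_cm2": cfg.svl_layer(level).areal_mass * KG_M2_TO_NG_CM2,
            "percent_mass": cfg.uptake_percent_truth(level),
        },
    }


def run_full_study(cfg: SyntheticStudyConfig) -> dict:
    """Execute the full synthetic study and return the report dictionary.

    Stages: per-level QCM analysis (plateaus, Voigt fit, both mass routes)
    → segmented uptake trend → anchoring-kinetics estimation (censored MLE
    and cumulative-CDF fit) → barrier trend and Arrhenius consistency →
    anisotropy trend.  The report is a plain dict, deterministically
    serializable, with no timestamps.
    """
    manifest = RunManifest(
        tool_version=__version__,
        config_digest=sha256_of(asdict(cfg)),
        seed=cfg.seed,
    )
    report: dict = {"manifest": None}

    log.info("stage qcm: %d levels, config %s", len(cfg.chol_levels),
             manifest.config_digest[:12])
    qcm_levels = [analyze_qcm_level(cfg, lv) for lv in cfg.chol_levels]
    manifest.stages.append("qcm")

    trend_points_v = [(r["chol_pct"], r["voigt"]["percent_mass"]) for r in qcm_levels]
    trend_points_s = [(r["chol_pct"], r["sauerbrey_sqrt_n"]["percent_mass"])
                      for r in qcm_levels]
    trend_v = segmented_uptake_trend(trend_points_v)
    trend_s = segmented_uptake_trend(trend_points_s)
    manifest.stages.append("uptake_trend")

    log.info("stage kinetics: %d trials/level", cfg.trials_per_level)
    samples = sample_anchoring_study(cfg)
    scale = ThermalScale(kbt=cfg.kbt, tau0=cfg.tau0)
    taus_mle, taus_cdf, kin_levels = [], [], []
    for lv in cfg.chol_levels:
        s = samples[lv]
        t_mle = estimate_tau_mle(s)
        taus_mle.append(t_mle)
        entry = {
            "chol_pct": lv,
            "n_trials": s.n_trials,
            "n_censored": s.n_trials - s.n_uncensored,
            "tau_mle_ns": t_mle.tau,
            "tau_ci_ns": [t_mle.ci_low, t_mle.ci_high],
            "mean_n_anchors_window": float(np.mean(s.n_anchors_window)),
            "expected_anchors_from_tau": expected_anchors(t_mle.tau, cfg.window),
            "tau_truth_ns": cfg.tau_truth(lv),
        }
        try:
            t_cdf = fit_cumulative_poisson(s)
            taus_cdf.append(t_cdf)
            entry["tau_cdf_ns"] = t_cdf.tau
            entry["ks_distance"] = t_cdf.ks_distance
        except NpUptakeError:
            entry["tau_cdf_ns"] = None
        kin_levels.append(entry)
    manifest.stages.append("kinetics")

    barriers = [cfg.barrier_truth(lv) for lv in cfg.chol_levels]
    barrier_fit = barrier_vs_chol_fit(barriers)
    lntau_fit = lntau_vs_chol_fit(taus_mle)
    # tolerance: twice the pooled CI width in ln-tau units; a pairwise
    # discrepancy combines two estimates, so this admits ~3-sigma draws on
    # both while remaining far below any condition-permutation signal
    consistency = arrhenius_consistency(
        taus_mle, barriers, scale,
        tolerance=2.0 * float(np.mean([
            math.log(t.ci_high / t.ci_low) for t in taus_mle
        ])),
    )
    manifest.stages.append("arrhenius")

    anis = simulate_anisotropy_study(cfg)
    anis_levels = []
    for lv in cfg.chol_levels:
        r_vals = [anisotropy(p) for p in anis[lv]]
        anis_levels.append({
            "chol_pct": lv,
            "r_mean": float(np.mean(r_vals)),
            "r_values": r_vals,
            "r_truth": cfg.anisotropy_truth(lv),
        })
    anis_fit = linear_trend([a["chol_pct"] for a in anis_levels],
                            [a["r_mean"] for a in anis_levels])
    manifest.stages.append("anisotropy")

    report.update({
        "qcm_levels": qcm_levels,
        "uptake_trend_voigt": asdict(trend_v),
        "uptake_trend_sauerbrey": asdict(trend_s),
        "kinetics_levels": kin_levels,
        "barrier_fit": asdict(barrier_fit),
        "lntau_fit": asdict(lntau_fit),
        "lntau_slope_expected": cfg.barrier_slope / cfg.kbt,
        "arrhenius_consistency": asdict(consistency),
        "anisotropy_levels": anis_levels,
        "anisotropy_fit": asdict(anis_fit),
    })
    report["manifest"] = asdict(manifest)
    return report
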