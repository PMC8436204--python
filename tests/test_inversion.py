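"""Trace smoothing, plateau detection, and the Voigt layer inversion."""

import numpy as np
import pytest

from npuptake.errors import EmptyTraceError, InsufficientDataError, UnderdeterminedError
from npuptake.inversion import (
    QcmTrace,
    detect_plateau,
    fit_viscoelastic_layer,
    smooth_trace,
)
from npuptake.qcm import ViscoelasticLayer, voigt_forward

OVERTONES = (3, 5, 7, 9, 11, 13)


def make_trace(t, values, overtones=(5,), dd=None):
    t = np.asarray(t, dtype=float)
    vals = np.tile(np.asarray(values, dtype=float)[:, None], (1, len(overtones)))
    ddv = np.zeros_like(vals) if dd is None else np.tile(
        np.asarray(dd, dtype=float)[:, None], (1, len(overtones)))
    return QcmTrace(time=t, overtones=overtones, delta_f=vals, delta_d=ddv)


class TestSmoothTrace:
    def test_constant_trace_unchanged(self):
        tr = make_trace(np.arange(100.0), np.full(100, -28.0))
        sm = smooth_trace(tr, 20)
        assert np.allclose(sm.delta_f, -28.0)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        tr = make_trace(np.arange(50.0), rng.normal(size=50))
        sm = smooth_trace(tr, 1)
        assert np.array_equal(sm.delta_f, tr.delta_f)

    def test_linear_ramp_interior_unchanged(self):
        t = np.arange(200.0)
        tr = make_trace(t, 0.3 * t)
        sm = smooth_trace(tr, 21)
        interior = slice(10, -10)
        assert np.allclose(sm.delta_f[interior, 0], 0.3 * t[interior])

    def test_mean_preserved_on_constant_region(self):
        tr = make_trace(np.arange(300.0), np.full(300, 5.5))
        sm = smooth_trace(tr, 20)
        assert sm.delta_f.mean() == pytest.approx(tr.delta_f.mean(), rel=1e-12)

    def test_time_grid_unchanged(self):
        tr = make_trace(np.arange(40.0), np.sin(np.arange(40.0)))
        assert np.array_equal(smooth_trace(tr, 7).time, tr.time)

    def test_empty_trace_rejected(self):
        tr = make_trace([], [])
        with pytest.raises(EmptyTraceError):
            smooth_trace(tr, 5)

    def test_oversized_window_rejected(self):
        tr = make_trace(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError):
            smooth_trace(tr, 11)


class TestDetectPlateau:
    def test_constant_trace_plateau_at_start(self):
        t = np.arange(0.0, 7200.0, 10.0)
        tr = make_trace(t, np.full(t.size, -28.0))
        res = detect_plateau(tr, min_duration=600.0)
        assert res.achieved
        assert res.delta_f[0] == pytest.approx(-28.0)
        assert res.onset_time == pytest.approx(t[0])

    def test_saturating_exponential_reaches_asymptote(self):
        # span of 8 time constants: plateau value within 1% of the asymptote
        t0, A = 1800.0, -30.0
        t = np.arange(0.0, 8 * t0, 15.0)
        tr = make_trace(t, A * (1 - np.exp(-t / t0)))
        res = detect_plateau(tr)
        assert res.achieved
        assert res.delta_f[0] == pytest.approx(A, rel=0.01)

    def test_linear_drift_not_a_plateau(self):
        t = np.arange(0.0, 7200.0, 10.0)
        tr = make_trace(t, -0.01 * t)  # 0.6 Hz/min drift everywhere
        with pytest.warns(UserWarning, match="no terminal plateau"):
            res = detect_plateau(tr, slope_tol=0.1, min_duration=600.0)
        assert not res.achieved

    def test_idempotent_on_constant_plateau(self):
        t = np.arange(0.0, 3600.0, 10.0)
        tr = make_trace(t, np.full(t.size, -41.5))
        r1 = detect_plateau(tr, min_duration=600.0)
        r2 = detect_plateau(tr, min_duration=600.0)
        assert r1.delta_f[0] == r2.delta_f[0] == pytest.approx(-41.5)

    def test_too_few_points_rejected(self):
        tr = make_trace([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(InsufficientDataError):
            detect_plateau(tr, min_duration=0.5)


class TestFitViscoelasticLayer:
    TRUTH = ViscoelasticLayer(rho=820.0, thickness=1.2e-8, eta=8e-3, mu=2.5e5)

    def _obs(self, crystal, pbs, layer=None, noise=None, seed=0):
        layer = layer or self.TRUTH
        obs = {}
        rng = np.random.default_rng(seed)
        for n in OVERTONES:
            df, dd = voigt_forward(layer, pbs, crystal, n)
            if noise:
                df *= 1 + rng.normal(0, noise)
                dd *= 1 + rng.normal(0, noise)
            obs[n] = (df, dd)
        return obs

    def test_noiseless_round_trip_recovers_areal_mass(self, crystal, pbs):
        fit = fit_viscoelastic_layer(self._obs(crystal, pbs), pbs, crystal)
        assert fit.areal_mass == pytest.approx(self.TRUTH.areal_mass, rel=0.01)

    def test_density_fixed_recovers_all_parameters(self, crystal, pbs):
        # the thin-film model is invariant under (rho,L,eta,mu) ->
        # (c rho, L/c, eta/c, mu/c); pinning rho removes the degeneracy
        fit = fit_viscoelastic_layer(
            self._obs(crystal, pbs), pbs, crystal, fixed={"rho": self.TRUTH.rho}
        )
        assert fit.layer.thickness == pytest.approx(self.TRUTH.thickness, rel=0.01)
        assert fit.layer.eta == pytest.approx(self.TRUTH.eta, rel=0.01)
        assert fit.layer.mu == pytest.approx(self.TRUTH.mu, rel=0.01)

    def test_degeneracy_is_flagged_when_all_free(self, crystal, pbs):
        fit = fit_viscoelastic_layer(self._obs(crystal, pbs), pbs, crystal)
        assert fit.identifiability_flag

    def test_two_percent_noise_keeps_areal_mass_within_five_percent(
        self, crystal, pbs
    ):
        hits = 0
        for seed in range(5):
            obs = self._obs(crystal, pbs, noise=0.02, seed=seed)
            fit = fit_viscoelastic_layer(obs, pbs, crystal)
            if abs(fit.areal_mass / self.TRUTH.areal_mass - 1) < 0.05:
                hits += 1
        assert hits >= 4

    def test_single_overtone_underdetermined(self, crystal, pbs):
        obs = {5: voigt_forward(self.TRUTH, pbs, crystal, 5)}
        with pytest.raises(UnderdeterminedError):
            fit_viscoelastic_layer(obs, pbs, crystal)

    def test_residual_reported_and_nonnegative(self, crystal, pbs):
        fit = fit_viscoelastic_layer(self._obs(crystal, pbs), pbs, crystal)
        assert fit.residual_norm >= 0.0
        assert fit.residual_norm < 1e-6


class TestQcmTraceValidation:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            make_trace([0.0, 2.0, 1.0], [0.0, 0.0, 0.0])

    def test_phase_selection(self):
        t = np.arange(6.0)
        tr = QcmTrace(
            time=t, overtones=(5,),
            delta_f=np.zeros((6, 1)), delta_d=np.zeros((6, 1)),
            phase=np.array(["baseline"] * 3 + ["vesicles"] * 3, dtype=object),
        )
        sub = tr.select_phase("vesicles")
        assert len(sub) == 3 and np.all(sub.time == t[3:])
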