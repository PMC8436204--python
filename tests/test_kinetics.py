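"""Anchoring-time estimators, barrier trends, and Arrhenius consistency."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from npuptake.errors import (
    AllCensoredError,
    ConditionMismatchError,
    InsufficientDataError,
)
from npuptake.kinetics import (
    AnchoringSample,
    BarrierEstimate,
    TauEstimate,
    ThermalScale,
    arrhenius_consistency,
    barrier_vs_chol_fit,
    estimate_tau_mle,
    expected_anchors,
    fit_cumulative_poisson,
    lntau_vs_chol_fit,
    tau_from_barrier,
)


def make_sample(waits, censored=None, run_length=None, chol=0.0):
    waits = np.asarray(waits, dtype=float)
    if censored is None:
        censored = np.zeros(waits.size, dtype=bool)
    if run_length is None:
        run_length = float(waits.max()) * 2
    return AnchoringSample(chol_pct=chol, waits=waits, censored=np.asarray(censored),
                           run_length=run_length)


class TestTauMle:
    def test_equal_waits_give_their_value(self):
        est = estimate_tau_mle(make_sample([50.0] * 10))
        assert est.tau == pytest.approx(50.0)
        assert est.ci_low < 50.0 < est.ci_high

    def test_censored_closed_form(self):
        # 6 uncensored waits + 6 censored at 1000 ns: tau = total/6
        waits = [100.0, 200.0, 300.0, 400.0, 500.0, 600.0] + [1000.0] * 6
        cens = [False] * 6 + [True] * 6
        est = estimate_tau_mle(make_sample(waits, cens, run_length=1000.0))
        assert est.tau == pytest.approx(sum(waits) / 6.0, rel=1e-12)

    def test_large_sample_recovery_within_ci(self):
        rng = np.random.default_rng(1)
        waits = rng.exponential(100.0, 1000)
        est = estimate_tau_mle(make_sample(waits))
        assert est.ci_low <= 100.0 <= est.ci_high
        assert est.tau == pytest.approx(100.0, rel=0.10)

    def test_all_censored_raises_with_lower_bound(self):
        s = make_sample([500.0] * 5, [True] * 5, run_length=500.0)
        with pytest.raises(AllCensoredError) as exc:
            estimate_tau_mle(s)
        assert exc.value.tau_lower is not None and exc.value.tau_lower > 0

    @given(extra=st.integers(1, 5))
    def test_adding_censored_trials_never_decreases_tau(self, extra):
        base = make_sample([10.0, 20.0, 30.0, 40.0], run_length=100.0)
        tau0 = estimate_tau_mle(base).tau
        waits = np.concatenate([base.waits, [100.0] * extra])
        cens = np.concatenate([np.zeros(4, bool), np.ones(extra, bool)])
        tau1 = estimate_tau_mle(make_sample(waits, cens, run_length=100.0)).tau
        assert tau1 >= tau0

    @given(c=st.floats(0.1, 50.0))
    def test_unit_equivariance(self, c):
        waits = np.array([12.0, 7.0, 30.0, 18.0, 44.0])
        t1 = estimate_tau_mle(make_sample(waits)).tau
        t2 = estimate_tau_mle(make_sample(waits * c)).tau
        assert t2 == pytest.approx(c * t1, rel=1e-9)
        assert expected_anchors(t2, c * 100.0) == pytest.approx(
            expected_anchors(t1, 100.0), rel=1e-9
        )


class TestCumulativePoissonFit:
    def test_noiseless_quantile_inversion(self):
        # waits placed at exact exponential quantiles: empirical CDF equals
        # 1 - exp(-t/50) at every point, so the fit must return 50
        n = 200
        p = (np.arange(1, n + 1) - 0.5) / n
        waits = -50.0 * np.log1p(-p)
        est = fit_cumulative_poisson(make_sample(waits))
        assert est.tau == pytest.approx(50.0, rel=1e-3)

    def test_agrees_with_mle_on_seeded_draws(self):
        rng = np.random.default_rng(7)
        waits = rng.exponential(200.0, 500)
        s = make_sample(waits)
        mle = estimate_tau_mle(s)
        cdf = fit_cumulative_poisson(s)
        assert mle.ci_low <= cdf.tau <= mle.ci_high
        assert cdf.ci_low <= mle.tau <= cdf.ci_high

    def test_uniform_waits_flagged_by_ks_distance(self):
        # KS distance of a uniform sample must exceed the 95th percentile of
        # KS distances from true exponential samples of the same size
        n, n_cal = 100, 200
        rng = np.random.default_rng(3)
        ks_cal = []
        for _ in range(n_cal):
            s = make_sample(rng.exponential(50.0, n))
            ks_cal.append(fit_cumulative_poisson(s).ks_distance)
        threshold = np.quantile(ks_cal, 0.95)
        uniform = make_sample(rng.uniform(1.0, 99.0, n))
        assert fit_cumulative_poisson(uniform).ks_distance > threshold

    def test_too_few_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_cumulative_poisson(make_sample([5.0, 6.0, 7.0]))


class TestTauFromBarrier:
    def test_zero_barrier_gives_prefactor(self):
        scale = ThermalScale(kbt=2.494, tau0=3.3)
        assert tau_from_barrier(BarrierEstimate(0.0, 0.0), scale) == pytest.approx(3.3)

    def test_barrier_span_ratio_hand_value(self):
        # 20 kJ/mol between conditions at kbt = 2.494 kJ/mol
        scale = ThermalScale(kbt=2.494, tau0=1.0)
        r = tau_from_barrier(BarrierEstimate(45.0, 32.0), scale) / tau_from_barrier(
            BarrierEstimate(15.0, 12.0), scale
        )
        assert r == pytest.approx(math.exp(20.0 / 2.494), rel=1e-9)
        assert r == pytest.approx(3.04e3, rel=1e-2)

    @given(g1=st.floats(0.0, 30.0), dg=st.floats(0.1, 20.0))
    def test_strictly_increasing_in_barrier(self, g1, dg):
        scale = ThermalScale()
        assert tau_from_barrier(BarrierEstimate(0, g1 + dg), scale) > tau_from_barrier(
            BarrierEstimate(0, g1), scale
        )


class TestBarrierVsCholFit:
    def test_collinear_input_exact(self):
        pts = [BarrierEstimate(c, 2.0 + 0.5 * c) for c in (0.0, 10.0, 20.0, 40.0)]
        fit = barrier_vs_chol_fit(pts)
        assert fit.slope == pytest.approx(0.5, rel=1e-9)
        assert fit.intercept == pytest.approx(2.0, rel=1e-9)
        assert fit.residual_norm < 1e-9

    def test_reported_barrier_triple_positive_slope(self):
        # ~12, ~21, ~32 kJ/mol at 15/30/45 mol % cholesterol
        pts = [BarrierEstimate(15.0, 12.0), BarrierEstimate(30.0, 21.0),
               BarrierEstimate(45.0, 32.0)]
        fit = barrier_vs_chol_fit(pts)
        assert fit.slope > 0
        assert fit.slope == pytest.approx(20.0 / 30.0, rel=0.05)
        barrier_spread = 32.0 - 12.0
        assert fit.residual_norm < 0.1 * barrier_spread

    def test_slope_invariant_under_constant_offset(self):
        pts = [BarrierEstimate(c, 1.0 + 0.7 * c) for c in (0.0, 15.0, 30.0, 45.0)]
        shifted = [BarrierEstimate(b.chol_pct, b.delta_g + 100.0) for b in pts]
        assert barrier_vs_chol_fit(shifted).slope == pytest.approx(
            barrier_vs_chol_fit(pts).slope, rel=1e-9
        )

    def test_too_few_conditions_rejected(self):
        with pytest.raises(InsufficientDataError):
            barrier_vs_chol_fit([BarrierEstimate(0, 1.0), BarrierEstimate(15, 2.0)])


class TestArrheniusConsistency:
    SCALE = ThermalScale(kbt=2.494, tau0=2.0)

    def _exact_taus(self, barriers):
        return [
            TauEstimate(tau=tau_from_barrier(b, self.SCALE), ci_low=1e-9,
                        ci_high=1e12, method="mle", chol_pct=b.chol_pct)
            for b in barriers
        ]

    def test_exact_arrhenius_times_have_zero_discrepancy(self):
        barriers = [BarrierEstimate(c, 2.0 + 0.6 * c) for c in (15.0, 30.0, 45.0)]
        rep = arrhenius_consistency(self._exact_taus(barriers), barriers, self.SCALE)
        assert rep.passed
        assert max(rep.discrepancy) < 1e-9

    def test_permuted_times_fail(self):
        barriers = [BarrierEstimate(c, 2.0 + 0.6 * c) for c in (15.0, 30.0, 45.0)]
        taus = self._exact_taus(barriers)
        for t, b in zip(taus, reversed(barriers)):
            t.chol_pct = b.chol_pct  # scramble the condition labels
        rep = arrhenius_consistency(taus, barriers, self.SCALE, tolerance=0.5)
        assert not rep.passed

    def test_disjoint_conditions_rejected(self):
        barriers = [BarrierEstimate(10.0, 5.0), BarrierEstimate(20.0, 8.0)]
        taus = self._exact_taus([BarrierEstimate(33.0, 5.0)])
        with pytest.raises(ConditionMismatchError):
            arrhenius_consistency(taus, barriers, self.SCALE)


class TestExpectedAnchors:
    def test_window_equal_tau_gives_one(self):
        assert expected_anchors(1000.0, 1000.0) == pytest.approx(1.0)

    def test_double_window_tau_gives_half(self):
        # τ = 2 μs against a 1 μs window: 0.5 anchored ligands expected
        assert expected_anchors(2000.0, 1000.0) == pytest.approx(0.5)

    def test_halving_tau_doubles_count(self):
        assert expected_anchors(500.0, 1000.0) == pytest.approx(
            2 * expected_anchors(1000.0, 1000.0)
        )


class TestComposedParameterRecovery:
    def test_lntau_slope_recovers_barrier_slope_over_kbt(self):
        # ΔG(c) = a + b·c ground truth; ln τ̂ vs c slope ≈ b/kbt, CI coverage
        a, b, kbt, tau0 = 2.0, 2.0 / 3.0, 2.494, 0.005
        levels = (0.0, 15.0, 30.0, 45.0)
        rng = np.random.default_rng(11)
        covered = 0
        n_rep = 40
        for _ in range(n_rep):
            taus = []
            for c in levels:
                tau = tau0 * math.exp((a + b * c) / kbt)
                waits = rng.exponential(tau, 12)
                taus.append(estimate_tau_mle(make_sample(waits, chol=c)))
            fit = lntau_vs_chol_fit(taus)
            if fit.slope_ci[0] <= b / kbt <= fit.slope_ci[1]:
                covered += 1
        assert covered >= int(0.9 * n_rep)


class TestTauEstimateValidation:
    def test_ci_ordering_enforced(self):
        with pytest.raises(ValueError):
            TauEstimate(tau=10.0, ci_low=20.0, ci_high=30.0, method="mle")

    def test_ks_distance_matches_scipy_reference(self):
        rng = np.random.default_rng(5)
        waits = rng.exponential(80.0, 200)
        est = fit_cumulative_poisson(make_sample(waits))
        ref = stats.kstest(waits, "expon", args=(0, est.tau)).statistic
        assert est.ks_distance == pytest.approx(ref, rel=1e-12)
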