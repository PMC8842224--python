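import math

import numpy as np
import pytest

from adenofep import GAS_CONSTANT_KCAL
from adenofep.fep_engine import (
    EdgeEstimate,
    Environment,
    LegResult,
    WindowSamples,
    aggregate_replicates,
    bar_window,
    edge_ddg,
    leg_free_energy,
    linear_lambda_schedule,
    sigmoidal_lambda_schedule,
    zwanzig_forward,
    zwanzig_reverse,
)
from adenofep.synthetic_data import simulate_work_samples


class TestLambdaSchedule:
    def test_two_windows(self):
        assert sigmoidal_lambda_schedule(2).values == (0.0, 1.0)

    @pytest.mark.parametrize("n", [2, 3, 11, 101])
    def test_endpoints_monotone_symmetric(self, n):
        lam = sigmoidal_lambda_schedule(n).values
        assert len(lam) == n
        assert lam[0] == 0.0 and lam[-1] == 1.0
        assert all(b > a for a, b in zip(lam, lam[1:]))
        for i in range(n):
            assert lam[i] + lam[n - 1 - i] == pytest.approx(1.0, abs=1e-12)

    def test_denser_near_endpoints_than_midpoint(self):
        lam = np.array(sigmoidal_lambda_schedule(101).values)
        gaps = np.diff(lam)
        assert gaps[0] < gaps[len(gaps) // 2]
        assert gaps[-1] < gaps[len(gaps) // 2]

    def test_linear_schedule(self):
        lam = linear_lambda_schedule(5).values
        assert lam == (0.0, 0.25, 0.5, 0.75, 1.0)

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            sigmoidal_lambda_schedule(1)


class TestBarWindow:
    def test_symmetric_zero_samples(self):
        s = WindowSamples(w_forward=np.zeros(100), w_reverse=np.zeros(100))
        dg, err = bar_window(s)
        assert dg == pytest.approx(0.0, abs=1e-9)

    def test_swapping_directions_negates_dg(self):
        rng = np.random.default_rng(7)
        wf = rng.normal(1.0, 0.8, 500)
        wr = rng.normal(-0.4, 0.8, 500)
        dg_fwd, _ = bar_window(WindowSamples(w_forward=wf, w_reverse=wr))
        dg_rev, _ = bar_window(WindowSamples(w_forward=wr, w_reverse=wf))
        assert dg_rev == pytest.approx(-dg_fwd, abs=1e-6)

    def test_gaussian_closed_form(self):
        # Crooks-consistent Gaussian work: exact ΔG = μ_F − σ²/2RT
        rt = 0.5925
        t_kelvin = rt / GAS_CONSTANT_KCAL
        target = 2.0 - 1.0 / (2 * rt)  # = 1.156...
        s = simulate_work_samples(target, 1.0, 100_000, T_kelvin=t_kelvin, seed=11)
        assert s.w_forward.mean() == pytest.approx(2.0, abs=0.02)
        dg, err = bar_window(s)
        assert err > 0
        assert abs(dg - target) < 3 * err

    def test_bar_beats_one_sided_zwanzig_estimators(self):
        # In a dissipative regime the two one-sided exponential-average
        # estimators acquire large biases of opposite sign (forward high,
        # reverse low), straddling the true value; BAR stays nearly
        # unbiased and typically falls between them.  The straddle is a
        # statistical tendency, not a per-sample guarantee.
        truth, sigma, n = -1.0, 3.0, 1000
        bars, zfs, zrs, bracketed = [], [], [], 0
        for seed in range(60):
            s = simulate_work_samples(truth, sigma, n, seed=seed)
            dg, _ = bar_window(s)
            zf, zr = zwanzig_forward(s), zwanzig_reverse(s)
            bars.append(dg)
            zfs.append(zf)
            zrs.append(zr)
            if min(zf, zr) - 1e-9 <= dg <= max(zf, zr) + 1e-9:
                bracketed += 1
        assert np.mean(zfs) > truth > np.mean(zrs)
        assert abs(np.mean(bars) - truth) < 0.1
        assert abs(np.mean(zfs) - truth) > 1.0  # EXP badly biased here
        assert abs(np.mean(zrs) - truth) > 1.0
        assert bracketed >= 42  # >= 70% of seeds

    def test_degenerate_constant_samples(self):
        s = WindowSamples(w_forward=np.full(10, 1.5), w_reverse=np.full(10, -1.5))
        dg, err = bar_window(s)
        assert dg == pytest.approx(1.5, abs=1e-12)
        assert err == 0.0

    def test_unequal_sample_counts(self):
        s = simulate_work_samples(0.7, 0.5, 4000, seed=3)
        trimmed = WindowSamples(
            w_forward=s.w_forward, w_reverse=s.w_reverse[:1000], T_kelvin=s.T_kelvin
        )
        dg, err = bar_window(trimmed)
        assert abs(dg - 0.7) < 4 * err

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            WindowSamples(w_forward=np.array([]), w_reverse=np.array([1.0]))

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValueError):
            WindowSamples(w_forward=np.array([np.inf]), w_reverse=np.array([1.0]))


class TestLegFreeEnergy:
    def _window(self, dg, seed):
        return simulate_work_samples(dg, 0.3, 400, seed=seed)

    def test_single_zero_window(self):
        leg = leg_free_energy(
            [WindowSamples(w_forward=np.zeros(50), w_reverse=np.zeros(50))],
            Environment.WATER,
        )
        assert leg.total_dg == pytest.approx(0.0, abs=1e-9)

    def test_additivity_and_permutation_invariance(self):
        w1, w2 = self._window(0.5, 1), self._window(-0.2, 2)
        leg12 = leg_free_energy([w1, w2], "water")
        leg21 = leg_free_energy([w2, w1], "water")
        assert leg12.total_dg == pytest.approx(sum(leg12.window_dg), abs=1e-12)
        assert leg12.total_dg == pytest.approx(leg21.total_dg, abs=1e-12)
        assert leg12.total_dg == pytest.approx(0.3, abs=0.15)

    def test_empty_leg_rejected(self):
        with pytest.raises(ValueError):
            leg_free_energy([], "water")


class TestEdgeDdg:
    def _leg(self, env, total):
        return LegResult(environment=env, window_dg=[total], window_stderr=[0.0])

    def test_thermodynamic_cycle(self):
        complex_leg = self._leg(Environment.RECEPTOR_COMPLEX, -5.0)
        water_leg = self._leg(Environment.WATER, -3.8)
        assert edge_ddg(complex_leg, water_leg) == pytest.approx(-1.2)

    def test_equal_legs_cancel(self):
        a = self._leg(Environment.RECEPTOR_COMPLEX, -2.0)
        b = self._leg(Environment.WATER, -2.0)
        assert edge_ddg(a, b) == 0.0

    def test_environment_mismatch_rejected(self):
        w = self._leg(Environment.WATER, 0.0)
        c = self._leg(Environment.RECEPTOR_COMPLEX, 0.0)
        with pytest.raises(ValueError):
            edge_ddg(w, c)


class TestAggregateReplicates:
    def test_mean_and_sem(self):
        est = aggregate_replicates(("a", "b"), [1.0, 2.0, 3.0])
        assert est.mean == pytest.approx(2.0)
        assert est.sem == pytest.approx(1.0 / math.sqrt(3), abs=1e-3)
        assert est.n_replicates == 3

    def test_identical_values_zero_sem(self):
        est = aggregate_replicates(("a", "b"), [0.7] * 10)
        assert est.sem == 0.0

    def test_single_replicate_warns(self):
        with pytest.warns(UserWarning, match="single replicate"):
            est = aggregate_replicates(("a", "b"), [1.2])
        assert est.sem == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates(("a", "b"), [])
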