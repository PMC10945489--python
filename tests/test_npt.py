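"""NPT analysis: evaporation detection, heating ladders, density maximum."""

import numpy as np
import pytest

from aquaphase.npt import (
    DensityTrace,
    HeatingLadder,
    NoMaximumError,
    detect_evaporation,
    estimate_T_evap,
    fit_density_maximum,
    heating_schedule,
    split_trace,
    split_uncertainty,
)
from aquaphase.synthetic import LadderSpec, gen_collapse_trace, gen_npt_ladder


def constant_trace(T=500.0, rho=950.0, n=200):
    times = 0.01 * (1 + np.arange(n))
    return DensityTrace(T=T, pressure_setpoint=1.0, times=times, density=np.full(n, rho))


class TestDetectEvaporation:
    def test_constant_liquid_trace_is_not_evaporated(self):
        assert detect_evaporation(constant_trace(rho=950.0), 1000.0) == (False, None)

    def test_collapse_trace_onset_located(self):
        trace = gen_collapse_trace(
            rho_liquid=700.0, rho_vapor=5.0, onset_time=2.0, noise_sd=5.0, seed=2
        )
        evaporated, onset = detect_evaporation(trace, 700.0)
        assert evaporated
        assert 1.9 <= onset <= 2.3

    def test_transient_dip_with_recovery_not_evaporated(self):
        rho = np.full(200, 950.0)
        rho[80] = 450.0  # one-sample dip, then recovery
        times = 0.01 * (1 + np.arange(200))
        trace = DensityTrace(T=500.0, pressure_setpoint=1.0, times=times, density=rho)
        assert detect_evaporation(trace, 1000.0) == (False, None)

    def test_threshold_monotonicity(self):
        """Raising the collapse threshold can only flip liquid -> evaporated."""
        traces = [
            gen_collapse_trace(rho_liquid=700.0, onset_time=4.0, noise_sd=20.0, seed=s)
            for s in range(3)
        ] + [constant_trace(rho=600.0)]
        for trace in traces:
            previous = False
            for fraction in np.linspace(0.05, 0.95, 19):
                verdict, _ = detect_evaporation(trace, 700.0, collapse_fraction=fraction)
                assert verdict or not previous
                previous = verdict

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            detect_evaporation(constant_trace(), -1.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_evaporation(constant_trace(n=10), 1000.0)


class TestEstimateTevap:
    def test_recovers_generator_truth_across_seeds(self):
        """Median estimate within +-3 K of the true 600 K over 10 seeds."""
        estimates = []
        for seed in range(10):
            ladder, truth = gen_npt_ladder(LadderSpec(seed=seed))
            result = estimate_T_evap(ladder, truth.rho_ref_by_T)
            assert result.reached
            estimates.append(result.T_evap)
        assert abs(np.median(estimates) - 600.0) <= 3.0

    def test_all_liquid_ladder_reports_not_reached(self):
        spec = LadderSpec(T_start=500.0, T_end=540.0, T_evap_true=540.0, seed=1)
        ladder, truth = gen_npt_ladder(spec)
        result = estimate_T_evap(ladder, truth.rho_ref_by_T)
        assert not result.reached and result.T_evap is None

    def test_non_monotone_ladder_flagged_inconsistent(self):
        steps = (
            constant_trace(T=589.0, rho=700.0),
            gen_collapse_trace(T=590.0, rho_liquid=700.0, onset_time=1.0),
            constant_trace(T=591.0, rho=700.0),
            gen_collapse_trace(T=592.0, rho_liquid=700.0, onset_time=1.0),
        )
        ladder = HeatingLadder(steps=steps, dT=1.0, tau_per_step=5.0)
        with pytest.warns(UserWarning, match="non-monotone"):
            result = estimate_T_evap(ladder, 700.0)
        assert result.T_evap == 590.0
        assert not result.consistent


class TestHeatingSchedule:
    @pytest.mark.parametrize("dT,tau,rate", [(1.0, 5.0, 0.2), (2.0, 5.0, 0.4)])
    def test_heating_rate(self, dT, tau, rate):
        ladder = heating_schedule(580.0, 620.0, dT, tau)
        assert ladder.heating_rate == pytest.approx(rate)
        assert ladder.temperatures[0] == 580.0
        assert ladder.temperatures[-1] == 620.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            heating_schedule(600.0, 600.0, 1.0, 5.0)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            heating_schedule(580.0, 620.0, -1.0, 5.0)


class TestFitDensityMaximum:
    def test_noiseless_parabola_recovered_exactly(self):
        T = np.arange(240.0, 321.0, 10.0)
        rho = 1000.0 - 0.007 * (T - 277.0) ** 2
        fit = fit_density_maximum(T, rho)
        assert fit.T_MD == pytest.approx(277.0, abs=1e-6)
        assert fit.rho_MD == pytest.approx(1000.0, abs=1e-6)

    def test_noisy_samples_recover_truth_on_average(self):
        """0.2 g/L noise, 20 seeds: mean T_MD within +-1.5 K of 277."""
        from aquaphase.synthetic import gen_density_vs_T

        T = np.arange(240.0, 321.0, 10.0)
        estimates = []
        for seed in range(20):
            t, rho, sd = gen_density_vs_T(T, noise_sd=0.2, seed=seed)
            estimates.append(fit_density_maximum(t, rho, sd).T_MD)
        assert abs(np.mean(estimates) - 277.0) <= 1.5

    def test_monotonic_samples_have_no_maximum(self):
        T = np.arange(240.0, 321.0, 10.0)
        with pytest.raises(NoMaximumError):
            fit_density_maximum(T, 1000.0 - 2.0 * T)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_density_maximum(np.array([250.0, 260, 270, 280]), np.ones(4))


class TestSplitUncertainty:
    def test_equal_constant_blocks(self):
        blocks = [constant_trace(rho=1000.0) for _ in range(6)]
        stats = split_uncertainty(blocks)
        assert stats.mean == 1000.0
        assert stats.sd == 0.0
        assert stats.n_blocks_retained == 5

    def test_biased_first_block_discarded(self):
        times = 0.01 * (1 + np.arange(3000))
        rho = np.full(3000, 1000.0)
        rho[:500] = 1100.0  # equilibration artifact in the first 5 ns
        trace = DensityTrace(T=300.0, pressure_setpoint=1.0, times=times, density=rho)
        stats = split_uncertainty(split_trace(trace, 6))
        assert stats.mean == pytest.approx(1000.0)
        assert stats.sd == 0.0

    def test_too_few_retained_blocks_rejected(self):
        with pytest.raises(ValueError):
            split_uncertainty([constant_trace(), constant_trace()], discard_first=True)

    def test_block_spread_calibrated_against_seeds(self):
        """Block sd within 3x the cross-seed spread of whole-trace means."""
        from aquaphase.synthetic import LadderSpec, gen_npt_ladder

        def long_trace(seed):
            spec = LadderSpec(
                T_start=400.0, T_end=402.0, dT=1.0, T_evap_true=402.0,
                tau_per_step=30.0, seed=seed,
            )
            ladder, _ = gen_npt_ladder(spec)
            return ladder.steps[0]

        stats = split_uncertainty(split_trace(long_trace(0), 6))
        seed_block_means = [
            float(np.mean(split_trace(long_trace(s), 6)[1].density)) for s in range(1, 21)
        ]
        assert stats.sd > 0
        assert stats.sd < 3.0 * np.std(seed_block_means, ddof=1) + 1e-9
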