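"""Forward-model and bulk-kinetics fitting tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from switchsense import (
    IlluminationSchedule,
    Phase,
    SensorModel,
    SwitchingTrace,
    average_off_cycles,
    effective_tau,
    er_sensor,
    fit_exponential,
    global_biexp,
    global_single_exp,
    hill_fraction,
    measure_fatigue,
    simulate_trace,
    spectrometer_schedule,
    tomography_schedule,
)
from switchsense.errors import (
    AlignmentError,
    InsufficientDataError,
    ParameterError,
    ScheduleError,
)

from conftest import grid_search_tau


# ---------------------------------------------------------------------------
# hill_fraction
# ---------------------------------------------------------------------------


class TestHillFraction:
    def test_er_occupancy_at_er_lumen_concentration(self):
        assert hill_fraction(500.0, 72.0, 1.0) == pytest.approx(
            500.0 / 572.0, abs=1e-12
        )

    def test_half_occupancy_at_kd_for_any_hill_coefficient(self):
        for n in (0.5, 1.0, 2.0, 4.0):
            assert hill_fraction(72.0, 72.0, n) == pytest.approx(0.5, abs=1e-12)

    def test_zero_ligand_gives_zero_occupancy(self):
        assert hill_fraction(0.0, 72.0, 1.0) == 0.0

    def test_saturates_to_one(self):
        assert hill_fraction(1e300, 72.0, 1.0) == pytest.approx(1.0, abs=1e-12)
        assert hill_fraction(np.inf, 72.0, 1.0) == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(
        kd=st.floats(1e-3, 1e3),
        n=st.floats(0.2, 5.0),
        lo=st.floats(-3.0, 5.0),
        step=st.floats(0.01, 3.0),
    )
    def test_monotone_non_decreasing_in_ca(self, kd, n, lo, step):
        f1 = hill_fraction(10.0**lo, kd, n)
        f2 = hill_fraction(10.0 ** (lo + step), kd, n)
        assert 0.0 <= f1 <= f2 <= 1.0

    def test_monotone_on_log_grid_with_limits(self):
        ca = np.geomspace(1e-3, 1e6, 50)
        f = hill_fraction(ca, 72.0, 1.3)
        assert np.all(np.diff(f) > 0)
        assert f[0] < 1e-4 and f[-1] > 0.9999

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ParameterError):
            hill_fraction(-1.0, 72.0, 1.0)
        with pytest.raises(ParameterError):
            hill_fraction(10.0, 0.0, 1.0)
        with pytest.raises(ParameterError):
            hill_fraction(10.0, 72.0, 0.0)


# ---------------------------------------------------------------------------
# SensorModel / IlluminationSchedule invariants
# ---------------------------------------------------------------------------


class TestDomainTypes:
    def test_sensor_invariants_enforced(self):
        with pytest.raises(ParameterError):
            SensorModel(kd=-1.0)
        with pytest.raises(ParameterError):
            SensorModel(kd=1.0, eps_free=1.5)
        with pytest.raises(ParameterError):
            SensorModel(kd=1.0, sigma_fast=0.1, sigma_slow=0.5)
        with pytest.raises(ParameterError):
            SensorModel(kd=1.0, fatigue_per_cycle=1.0)

    def test_schedule_requires_integral_frames(self):
        with pytest.raises(ScheduleError):
            IlluminationSchedule(
                phases=(Phase(488, 1.0, 120),), pulses_per_frame=7
            )

    def test_empty_schedule_rejected(self):
        with pytest.raises(ScheduleError):
            IlluminationSchedule(phases=())

    def test_tomography_schedule_frame_count(self):
        sch = tomography_schedule(pulses_per_frame=3)
        assert sch.n_frames == 10 * (120 + 120) // 3 == 800

    def test_trace_requires_increasing_time(self):
        with pytest.raises(ValueError):
            SwitchingTrace(t=[0.0, 0.0, 1.0], s=[1, 2, 3], phase_id=[0, 0, 0])


# ---------------------------------------------------------------------------
# simulate_trace
# ---------------------------------------------------------------------------


class TestSimulateTrace:
    def test_unbound_sensor_gives_constant_dim_trace(self, tomo10):
        sensor = er_sensor(dark_offset=0.5)
        tr = simulate_trace(sensor, tomo10, ca=0.0, noise_sd=0.0)
        expected = 0.1 * sensor.brightness + 0.5
        assert np.allclose(tr.s, expected, atol=1e-12)

    def test_single_species_saturating_matches_closed_form(self):
        # all pulses in one OFF phase; with a single species and full
        # occupancy the model is exactly A e^{-sigma I t} + offset
        sensor = er_sensor(sigma_slow=1.0, fatigue_per_cycle=0.0)
        sch = spectrometer_schedule(n_pulses=240, intensity=0.7)
        ca = 1e6  # >> kd
        tr = simulate_trace(sensor, sch, ca=ca, noise_sd=0.0)
        f = sensor.bound_fraction(ca)
        expected = (
            sensor.brightness * f * np.exp(-sensor.sigma_fast * 0.7 * tr.t)
            + sensor.eps_free * (1 - f) * sensor.brightness
            + sensor.dark_offset
        )
        assert np.allclose(tr.s, expected, rtol=1e-12, atol=1e-12)

    def test_seeded_noise_is_bit_reproducible(self, er, tomo10):
        a = simulate_trace(er, tomo10, ca=10.0, noise_sd=1.0, seed=42)
        b = simulate_trace(er, tomo10, ca=10.0, noise_sd=1.0, seed=42)
        assert np.array_equal(a.s, b.s)
        c = simulate_trace(er, tomo10, ca=10.0, noise_sd=1.0, seed=43)
        assert not np.array_equal(a.s, c.s)

    def test_noiseless_output_independent_of_seed(self, er, tomo10):
        a = simulate_trace(er, tomo10, ca=10.0, noise_sd=0.0, seed=1)
        b = simulate_trace(er, tomo10, ca=10.0, noise_sd=0.0, seed=999)
        assert np.array_equal(a.s, b.s)

    def test_effective_tau_strictly_decreasing_in_ca(self, er, spectro):
        taus = []
        for mult in (0.1, 1.0, 10.0, 100.0):
            tr = simulate_trace(er, spectro, ca=mult * er.kd, noise_sd=0.0)
            fit = effective_tau(tr)
            assert fit.valid
            taus.append(fit.tau)
        assert all(a > b for a, b in zip(taus, taus[1:]))

    def test_rejects_negative_noise(self, er, tomo10):
        with pytest.raises(ParameterError):
            simulate_trace(er, tomo10, ca=1.0, noise_sd=-0.1)


# ---------------------------------------------------------------------------
# effective_tau / fit_exponential
# ---------------------------------------------------------------------------


class TestEffectiveTau:
    def test_recovers_pure_exponential_parameters(self):
        t = np.arange(0.0, 12.0, 0.1)
        s = 1.0 * np.exp(-t / 2.0) + 0.1
        fit = fit_exponential(t, s)
        assert fit.valid
        assert fit.tau == pytest.approx(2.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.y0 == pytest.approx(0.1, abs=1e-6)

    def test_constant_trace_flagged_invalid_not_raised(self):
        t = np.arange(0.0, 10.0, 0.1)
        fit = fit_exponential(t, np.full_like(t, 3.3))
        assert not fit.valid
        assert np.isnan(fit.tau)

    def test_too_few_samples_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential(np.arange(3.0), np.ones(3))

    def test_matches_grid_oracle_on_biexponential_mixture(self):
        t = np.arange(0.0, 20.0, 0.1)
        y0 = 0.3
        s = 0.6 * np.exp(-1.2 * t) + 0.4 * np.exp(-0.25 * t) + y0
        fit = fit_exponential(t, s, y0_fixed=y0)
        oracle = grid_search_tau(t, s, y0)
        assert fit.valid
        assert fit.tau == pytest.approx(oracle, rel=1e-3)

    def test_fixed_offset_respected(self):
        t = np.arange(0.0, 12.0, 0.1)
        s = 2.0 * np.exp(-t / 1.5) + 0.7
        fit = fit_exponential(t, s, y0_fixed=0.7)
        assert fit.y0 == 0.7 and fit.y0_fixed
        assert fit.tau == pytest.approx(1.5, abs=1e-6)


# ---------------------------------------------------------------------------
# global biexponential fitting
# ---------------------------------------------------------------------------


def _biexp_traces(k=(3.0, 0.4), mixes=(0.2, 0.5, 0.8), noise_sd=0.0, seed=None):
    t = np.arange(0.0, 12.0, 0.1)
    rng = np.random.default_rng(seed)
    traces = []
    for m in mixes:
        s = m * np.exp(-k[0] * t) + (1 - m) * np.exp(-k[1] * t) + 0.05
        if noise_sd > 0:
            s = s + rng.normal(0.0, noise_sd, size=s.shape)
        traces.append(SwitchingTrace(t=t, s=s, phase_id=np.zeros(len(t), int)))
    return traces


class TestGlobalBiexp:
    def test_recovers_shared_rates_noiseless(self):
        fit = global_biexp(_biexp_traces())
        assert fit.k_fast == pytest.approx(3.0, rel=0.02)
        assert fit.k_slow == pytest.approx(0.4, rel=0.02)

    def test_single_species_degenerates_to_single_exponential(self):
        traces = _biexp_traces(k=(0.8, 0.8), mixes=(0.3, 0.7))
        fit = global_biexp(traces)
        assert fit.residual <= fit.single_exp_residual + 1e-8
        assert fit.residual == pytest.approx(fit.single_exp_residual, abs=1e-8)

    def test_residual_never_exceeds_single_exponential(self):
        for seed in range(5):
            traces = _biexp_traces(noise_sd=0.01, seed=seed)
            fit = global_biexp(traces)
            assert fit.residual <= fit.single_exp_residual + 1e-12

    def test_noisy_rate_recovery_over_seeds(self):
        # 1% of amplitude noise, averaged over 25 synthetic repeats
        t = np.arange(0.0, 12.0, 0.1)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            traces = []
            for m in (0.25, 0.75):
                clean = m * np.exp(-3.0 * t) + (1 - m) * np.exp(-0.4 * t)
                reps = clean + rng.normal(0.0, 0.01, size=(25, len(t)))
                traces.append(
                    SwitchingTrace(
                        t=t, s=reps.mean(axis=0), phase_id=np.zeros(len(t), int)
                    )
                )
            fit = global_biexp(traces)
            errs.append(
                max(abs(fit.k_fast / 3.0 - 1.0), abs(fit.k_slow / 0.4 - 1.0))
            )
        assert max(errs) < 0.10

    def test_misaligned_time_bases_raise(self):
        a, b = _biexp_traces(mixes=(0.3, 0.6))
        b.t = b.t + 0.05
        with pytest.raises(AlignmentError):
            global_biexp([a, b])

    def test_single_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            global_biexp(_biexp_traces(mixes=(0.5,)))

    def test_global_single_exp_finds_generating_rate(self):
        traces = _biexp_traces(k=(0.8, 0.8), mixes=(0.3, 0.7))
        k, _ = global_single_exp(traces)
        assert k == pytest.approx(0.8, rel=1e-3)


# ---------------------------------------------------------------------------
# cycle averaging and fatigue
# ---------------------------------------------------------------------------


class TestCyclesAndFatigue:
    def test_average_off_cycles_reduces_noise(self, er, tomo10):
        tr = simulate_trace(er, tomo10, ca=100.0, noise_sd=2.0, seed=0)
        avg = average_off_cycles(tr, tomo10)
        assert len(avg) == 12  # 120 OFF pulses / 10 per frame
        clean = simulate_trace(er, tomo10, ca=100.0, noise_sd=0.0)
        clean_avg = average_off_cycles(clean, tomo10)
        resid = avg.s - clean_avg.s
        assert resid.std() < 2.0 / np.sqrt(10) * 1.8  # ~sd/sqrt(n_cycles)

    def test_no_fatigue_measured_as_zero(self, tomo10):
        sensor = er_sensor(fatigue_per_cycle=0.0)
        tr = simulate_trace(sensor, tomo10, ca=1000.0, noise_sd=0.0)
        assert measure_fatigue(tr, tomo10) == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_fatigue_recovered(self, tomo10):
        sensor = er_sensor(fatigue_per_cycle=0.05)
        tr = simulate_trace(sensor, tomo10, ca=1000.0, noise_sd=0.0)
        assert measure_fatigue(tr, tomo10) == pytest.approx(0.05, abs=1e-3)

    def test_noisy_fatigue_mean_over_seeds(self, tomo10):
        sensor = er_sensor(fatigue_per_cycle=0.02)
        vals = []
        for seed in range(20):
            tr = simulate_trace(sensor, tomo10, ca=1000.0, noise_sd=0.9, seed=seed)
            vals.append(measure_fatigue(tr, tomo10))
        assert abs(float(np.mean(vals)) - 0.02) < 0.005

    def test_too_few_cycles_raise(self):
        sch = tomography_schedule(pulses_per_frame=10, n_cycles=2)
        tr = simulate_trace(er_sensor(), sch, ca=1000.0)
        with pytest.raises(InsufficientDataError):
            measure_fatigue(tr, sch)
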