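"""Killing-curve virulence, one-step growth, adsorption, biofilm, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from charkit import synthetic_data as sd
from charkit.errors import NoBurstError, UndefinedValueError
from charkit.kinetics import (GrowthCurveSet, LocalVirulence, TiterSeries,
                              adsorption, biofilm_inhibition, local_virulence,
                              log_reduction, one_step, virulence_curve,
                              virulence_index)

# the published per-MOI local virulence ladder for the characterized phage
TABLE_MOIS = [10.0 ** e for e in range(-7, 1)]
TABLE_V = [0.17, 0.16, 0.20, 0.25, 0.68, 0.97, 0.92, 0.97]


def _curves(times, control, moi_map, window_end=None):
    return GrowthCurveSet(times=np.asarray(times, float),
                          control_od=np.asarray(control, float),
                          moi_curves={m: np.asarray(v, float)
                                      for m, v in moi_map.items()},
                          window_end=window_end)


class TestLocalVirulence:
    times = np.arange(0.0, 361.0, 30.0)
    control = np.linspace(0.05, 1.0, 13)

    def test_identical_curve_gives_zero(self):
        c = _curves(self.times, self.control, {1.0: self.control}, 360)
        assert local_virulence(c, 1.0).v == 0.0

    def test_total_suppression_gives_one(self):
        c = _curves(self.times, self.control,
                    {1.0: np.zeros_like(self.control)}, 360)
        assert local_virulence(c, 1.0).v == 1.0

    def test_half_control_gives_half(self):
        c = _curves(self.times, self.control, {1.0: 0.5 * self.control}, 360)
        assert local_virulence(c, 1.0).v == pytest.approx(0.5)

    def test_monotone_in_pointwise_suppression(self):
        lower = 0.3 * self.control
        higher = 0.8 * self.control
        c = _curves(self.times, self.control, {1.0: lower, 2.0: higher}, 360)
        assert local_virulence(c, 1.0).v >= local_virulence(c, 2.0).v

    def test_zero_control_area_is_undefined(self):
        c = _curves([0, 30], [0, 0], {1.0: [0, 0]}, 30)
        with pytest.raises(UndefinedValueError):
            local_virulence(c, 1.0)


class TestVirulenceIndex:
    def test_published_ladder_reproduces_printed_index(self):
        """Trapezoidal integration of the printed eight-point ladder over
        log10 MOI in [-7, 0] gives 0.536, matching the published 0.535."""
        locals_ = [LocalVirulence(m, v) for m, v in zip(TABLE_MOIS, TABLE_V)]
        assert virulence_index(locals_) == pytest.approx(0.535, abs=0.002)

    def test_bounds(self):
        ones = [LocalVirulence(m, 1.0) for m in TABLE_MOIS]
        zeros = [LocalVirulence(m, 0.0) for m in TABLE_MOIS]
        assert virulence_index(ones) == pytest.approx(1.0)
        assert virulence_index(zeros) == pytest.approx(0.0)

    def test_invariant_under_reordering(self):
        locals_ = [LocalVirulence(m, v) for m, v in zip(TABLE_MOIS, TABLE_V)]
        rng = np.random.default_rng(1)
        shuffled = list(locals_)
        rng.shuffle(shuffled)
        assert virulence_index(shuffled) == virulence_index(locals_)

    def test_duplicate_moi_raises(self):
        with pytest.raises(ValueError):
            virulence_index([LocalVirulence(1.0, 0.5), LocalVirulence(1.0, 0.6)])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=8, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_index_stays_in_unit_interval(self, vs):
        locals_ = [LocalVirulence(m, v) for m, v in zip(TABLE_MOIS, vs)]
        assert 0.0 <= virulence_index(locals_) <= 1.0


class TestOneStep:
    def test_hand_computed_step_fixture(self):
        """Step from 1e4 to 6e5 PFU/mL between 20 and 30 min with n0 = 1e4
        infective input: latent 20 min, burst 60."""
        series = TiterSeries(times=np.arange(0, 51, 10.0),
                             titer=np.array([1e4, 1e4, 1e4, 6e5, 6e5, 6e5]),
                             n0=1e4, volume_ml=1.0)
        res = one_step(series)
        assert res.latent_min == 20.0
        assert res.burst_size == pytest.approx(60.0)
        assert res.rise_min == 10.0

    def test_flat_series_has_no_burst(self):
        series = TiterSeries(times=np.arange(0, 51, 10.0),
                             titer=np.full(6, 1e4), n0=1e4)
        with pytest.raises(NoBurstError):
            one_step(series)

    def test_noiseless_simulator_roundtrip(self, onestep_times):
        params = sd.InfectionModelParams(latent_min=20, burst=60, seed=0)
        series, truth = sd.simulate_one_step(params, onestep_times)
        res = one_step(series)
        assert res.latent_min == truth["latent_min"]
        assert res.burst_size == pytest.approx(truth["burst"], rel=0.01)

    def test_second_burst_does_not_disturb_first_plateau(self, onestep_times):
        params = sd.InfectionModelParams(latent_min=20, burst=60, seed=0)
        series, truth = sd.simulate_one_step(params, onestep_times,
                                             second_burst=True)
        res = one_step(series)
        assert res.burst_size == pytest.approx(truth["burst"], rel=0.01)

    def test_noisy_recovery_within_15_percent_most_of_the_time(self, onestep_times):
        hits = 0
        for seed in range(100):
            params = sd.InfectionModelParams(latent_min=20, burst=60,
                                             noise_sd=0.1, seed=seed)
            series, truth = sd.simulate_one_step(params, onestep_times)
            try:
                res = one_step(series)
            except Exception:
                continue
            if abs(res.burst_size - truth["burst"]) / truth["burst"] <= 0.15 \
                    and abs(res.latent_min - truth["latent_min"]) <= 10.0:
                hits += 1
        assert hits >= 95


class TestAdsorption:
    times = np.array([0.0, 1, 2, 3, 4, 5, 10, 15])

    def test_constant_titer_means_no_adsorption(self):
        series = TiterSeries(times=self.times, titer=np.full(8, 1e8))
        res = adsorption(series, cell_density=2e8)
        assert res.percent_adsorbed_at[5.0] == 0.0
        assert res.rate_constant == pytest.approx(0.0)

    def test_published_fraction_converts_to_percent(self):
        """P/P0 = 0.244 at 5 min corresponds to 75.6% adsorbed."""
        series = TiterSeries(times=np.array([0.0, 5.0, 15.0]),
                             titer=np.array([1e8, 0.244e8, 0.094e8]))
        res = adsorption(series)
        assert res.percent_adsorbed_at[5.0] == pytest.approx(75.6)
        assert res.percent_adsorbed_at[15.0] == pytest.approx(90.6)

    def test_noiseless_rate_recovery(self):
        k, cells = 7.3e-10, 3e8
        series = sd.simulate_adsorption(1e8, k, cells, self.times)
        res = adsorption(series, cell_density=cells)
        assert res.rate_constant == pytest.approx(k, rel=1e-6)

    def test_zero_initial_titer_raises(self):
        series = TiterSeries(times=np.array([0.0, 5.0]),
                             titer=np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            adsorption(series)


class TestBiofilmInhibition:
    def test_equal_means_no_inhibition(self):
        assert biofilm_inhibition([0.5, 0.6], [0.55, 0.55]) == pytest.approx(0.0)

    @pytest.mark.parametrize("factor,expected", [(0.18, 82.0), (0.76, 24.0)])
    def test_published_inhibition_range(self, factor, expected):
        control = np.array([1.0, 1.2, 0.8])
        assert biofilm_inhibition(control, factor * control) \
            == pytest.approx(expected)

    def test_enhancement_reported_negative(self):
        assert biofilm_inhibition([0.5], [0.6]) < 0

    def test_zero_control_raises(self):
        with pytest.raises(UndefinedValueError):
            biofilm_inhibition([0.0], [0.1])


class TestLogReduction:
    def test_two_log_drop(self):
        value, censored = log_reduction(7.0e8, 7.0e6)
        assert value == pytest.approx(2.0)
        assert not censored

    def test_equal_titers(self):
        assert log_reduction(5e6, 5e6) == (pytest.approx(0.0), False)

    def test_complete_inactivation_is_censored(self):
        value, censored = log_reduction(2.0e6, 0.0, lod=10.0)
        assert censored
        assert value == pytest.approx(np.log10(2.0e6) - 1.0)

    def test_additivity_when_uncensored(self):
        ab, _ = log_reduction(1e8, 4e6)
        bc, _ = log_reduction(4e6, 3e3)
        ac, _ = log_reduction(1e8, 3e3)
        assert ab + bc == pytest.approx(ac)


class TestSimulatedKillingCurves:
    def test_virulence_index_increases_with_adsorption_rate(self):
        times = np.arange(0.0, 390.1, 30.0)
        mois = TABLE_MOIS
        indices = []
        for k in (1e-10, 5e-10, 2e-9):
            params = sd.InfectionModelParams(k_ads=k, seed=2)
            curves = sd.simulate_growth_curves(params, mois, times)
            indices.append(virulence_index(virulence_curve(curves)))
        assert indices[0] < indices[1] < indices[2]

    def test_high_moi_more_virulent_than_low(self):
        times = np.arange(0.0, 390.1, 30.0)
        params = sd.InfectionModelParams(seed=3)
        curves = sd.simulate_growth_curves(params, [1e-7, 1.0], times)
        assert local_virulence(curves, 1.0).v > local_virulence(curves, 1e-7).v
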