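"""1:1 Langmuir model, reference subtraction, global and steady-state fits."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidyn.errors import FitError, InputError
from epidyn.kinetics import (
    KineticParams,
    Sensorgram,
    equilibrium_responses,
    frame_to_sensorgrams,
    global_fit,
    model_response,
    reference_subtract,
    sensorgrams_to_frame,
    steady_state_fit,
)
from epidyn.synthetic_data import (
    SensorgramSpec,
    make_sensorgram_set,
    make_two_site_sensorgram_set,
)

P = KineticParams(ka=1.0e3, kd=2.52e-2, rmax=2.5)  # K_D = 25.2 uM


class TestModelResponse:
    def test_plateau_at_kD_is_half_rmax(self):
        r = model_response(P, P.kD, np.array([1e6]), t_assoc=2e6)
        assert r[0] == pytest.approx(P.rmax / 2, rel=1e-9)

    def test_zero_concentration_is_flat_zero(self):
        t = np.linspace(0, 120, 50)
        np.testing.assert_array_equal(model_response(P, 0.0, t, 60.0), 0.0)

    def test_kobs_recovered_from_association(self):
        conc = 40e-6
        t = np.linspace(0, 30, 400)
        r = model_response(P, conc, t, t_assoc=60.0)
        r_eq = P.rmax * conc / (conc + P.kD)
        k_obs = -np.polyfit(t[1:], np.log(1 - r[1:] / r_eq), 1)[0]
        assert k_obs == pytest.approx(P.ka * conc + P.kd, rel=1e-6)

    def test_dissociation_is_pure_exponential(self):
        t = np.array([60.0, 70.0, 80.0])
        r = model_response(P, 20e-6, t, t_assoc=60.0)
        assert r[1] / r[0] == pytest.approx(np.exp(-P.kd * 10), rel=1e-9)

    @given(st.floats(1e-7, 1e-4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_association_monotone_dissociation_decreasing(self, conc):
        t = np.linspace(0, 120, 241)
        r = model_response(P, conc, t, t_assoc=60.0)
        assoc = r[t < 60.0]
        dissoc = r[t >= 60.0]
        assert np.all(np.diff(assoc) >= -1e-15)
        assert np.all(np.diff(dissoc) < 0)

    def test_equilibrium_monotone_in_concentration_bounded_by_rmax(self):
        concs = np.array([1e-6, 5e-6, 20e-6, 80e-6])
        r_eq = np.array(
            [model_response(P, c, np.array([1e5]), 2e5)[0] for c in concs]
        )
        assert np.all(np.diff(r_eq) > 0)
        assert np.all(r_eq < P.rmax)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InputError):
            model_response(P, -1e-6, np.array([1.0]), 60.0)


class TestReferenceSubtract:
    def make_curve(self, response, conc=1e-6):
        t = np.linspace(0, 120, 121)
        return Sensorgram(time=t, response=response(t), concentration=conc, t_assoc=60.0)

    def test_self_subtraction_is_zero(self):
        c = self.make_curve(lambda t: np.sin(t / 10))
        np.testing.assert_array_equal(reference_subtract(c, c).response, 0.0)

    def test_zero_reference_is_identity(self):
        c = self.make_curve(lambda t: np.cos(t / 7))
        ref = self.make_curve(lambda t: np.zeros_like(t), conc=0.0)
        np.testing.assert_array_equal(reference_subtract(c, ref).response, c.response)

    def test_removes_shared_drift(self):
        spec = SensorgramSpec(noise_sigma=0.0, drift=0.005, seed=3)
        curves, reference = make_sensorgram_set(spec)
        clean = model_response(
            spec.params, curves[0].concentration, curves[0].time, spec.t_assoc
        )
        corrected = reference_subtract(curves[0], reference)
        np.testing.assert_allclose(corrected.response, clean, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = self.make_curve(lambda t: t)
        b = Sensorgram(
            time=np.linspace(0, 120, 61),
            response=np.zeros(61),
            concentration=0.0,
            t_assoc=60.0,
        )
        with pytest.raises(InputError):
            reference_subtract(a, b)


class TestGlobalFit:
    def test_noiseless_recovery_to_1e6_relative(self):
        curves, _ = make_sensorgram_set(SensorgramSpec(noise_sigma=0.0, seed=0))
        fit = global_fit(curves)
        assert fit.params.ka == pytest.approx(P.ka, rel=1e-6)
        assert fit.params.kd == pytest.approx(P.kd, rel=1e-6)
        assert fit.params.rmax == pytest.approx(P.rmax, rel=1e-6)
        assert not fit.poor_fit
        assert fit.kD == pytest.approx(fit.params.kd / fit.params.ka, rel=1e-12)

    def test_noisy_recovery_within_10pc(self):
        curves, ref = make_sensorgram_set(SensorgramSpec(seed=4))
        fit = global_fit([reference_subtract(c, ref) for c in curves])
        assert fit.kD == pytest.approx(25.2e-6, rel=0.10)
        assert fit.r_squared > 0.95

    def test_single_concentration_refused(self):
        curves, _ = make_sensorgram_set(SensorgramSpec(noise_sigma=0.0, seed=0))
        with pytest.raises(FitError):
            global_fit([curves[0]])

    def test_curve_without_dissociation_refused(self):
        curves, _ = make_sensorgram_set(SensorgramSpec(noise_sigma=0.0, seed=0))
        assoc_only = [
            replace(c, time=c.time[c.association_mask], response=c.response[c.association_mask])
            for c in curves
        ]
        with pytest.raises(FitError):
            global_fit(assoc_only)

    def test_invariant_to_curve_ordering(self):
        curves, _ = make_sensorgram_set(SensorgramSpec(seed=9))
        a = global_fit(curves)
        b = global_fit(list(reversed(curves)))
        assert a.kD == pytest.approx(b.kD, rel=1e-9)

    def test_invariant_to_uniform_time_offset(self):
        curves, _ = make_sensorgram_set(SensorgramSpec(seed=9))
        offset = 37.0
        shifted = [
            replace(c, time=c.time + offset, t_assoc=c.t_assoc + offset)
            for c in curves
        ]
        a = global_fit(curves)
        b = global_fit(shifted)
        assert a.kD == pytest.approx(b.kD, rel=1e-9)

    def test_two_site_data_flagged_poor(self):
        spec = SensorgramSpec(params=KineticParams(ka=200.0, kd=5e-3, rmax=2.5), seed=1)
        curves, ref = make_two_site_sensorgram_set(spec)
        fit = global_fit([reference_subtract(c, ref) for c in curves])
        assert fit.poor_fit
        assert fit.r_squared < 0.9

    def test_standard_errors_are_finite_and_small_for_clean_data(self):
        curves, _ = make_sensorgram_set(SensorgramSpec(seed=2))
        fit = global_fit(curves)
        assert np.isfinite(fit.se["kD"])
        assert fit.se["kD"] < 0.2 * fit.kD


class TestSteadyState:
    def test_exact_hyperbola_recovered(self):
        kD, rmax = 10e-6, 2.0
        concs = np.array([1.25, 2.5, 5, 10, 20, 40]) * 1e-6
        points = [(c, rmax * c / (c + kD)) for c in concs]
        got_kD, got_rmax = steady_state_fit(points)
        assert got_kD == pytest.approx(kD, rel=1e-6)
        assert got_rmax == pytest.approx(rmax, rel=1e-6)

    def test_half_saturation_at_kD(self):
        kD, rmax = 25.2e-6, 2.5
        points = [(c, rmax * c / (c + kD)) for c in (kD / 4, kD, 4 * kD)]
        got_kD, got_rmax = steady_state_fit(points)
        r_at_kD = got_rmax * got_kD / (got_kD + got_kD)
        assert r_at_kD == pytest.approx(got_rmax / 2)

    def test_consistent_with_kinetic_fit_within_15pc(self):
        # long association so every dose genuinely equilibrates
        spec = SensorgramSpec(t_assoc=300.0, t_dissoc=60.0, seed=6)
        curves, ref = make_sensorgram_set(spec)
        corrected = [reference_subtract(c, ref) for c in curves]
        kinetic = global_fit(corrected)
        steady_kD, _ = steady_state_fit(equilibrium_responses(corrected))
        assert steady_kD == pytest.approx(kinetic.kD, rel=0.15)

    def test_degenerate_flat_responses_rejected(self):
        with pytest.raises(FitError):
            steady_state_fit([(1e-6, 1.0), (2e-6, 1.0), (4e-6, 1.0)])

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(FitError):
            steady_state_fit([(1e-6, 0.5), (2e-6, 0.8)])


class TestCsvRoundTrip:
    def test_frame_round_trip(self):
        curves, ref = make_sensorgram_set(SensorgramSpec(seed=5))
        df = sensorgrams_to_frame(curves + [ref])
        back = frame_to_sensorgrams(df)
        assert len(back) == len(curves) + 1
        for orig, again in zip(curves + [ref], back):
            np.testing.assert_allclose(again.time, orig.time)
            np.testing.assert_allclose(again.response, orig.response)
            assert again.concentration == orig.concentration
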