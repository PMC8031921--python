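import numpy as np
import pytest

from sovt.constants import AIR_DENSITY, SAMPLING_RATE
from sovt.simulate import (
    AcousticField,
    F0NotDetected,
    SimConfig,
    band_energy,
    estimate_f0,
    glottal_flow,
    propagate,
    simulate,
    spectrum,
)
from sovt.walls import quasi_static_equilibrium

FS = SAMPLING_RATE


class TestGlottalFlow:
    def test_equal_pressures_zero_flow(self):
        q, press = glottal_flow(1000.0, 1000.0, [5, 5, 5, 5, 5])
        assert q == 0.0

    def test_bernoulli_reference(self):
        # dP = 2.5 kPa through 10 mm^2: Q = A sqrt(2 dP / rho) = 0.662 L/s
        q, _ = glottal_flow(2500.0, 0.0, [12, 11, 10, 11, 12])
        assert q == pytest.approx(0.662, abs=0.002)

    def test_separated_sections_carry_downstream_pressure(self):
        # divergent with exit 25% above the minimum: exit is separated
        q, press = glottal_flow(2500.0, 800.0, [10.0, 10.0, 10.0, 11.0, 12.5])
        assert press[-1] == pytest.approx(800.0)
        assert press[0] < 2500.0

    def test_closed_glottis(self):
        q, press = glottal_flow(2500.0, 0.0, [5, 3, 0.0, 3, 5])
        assert q == 0.0
        assert press[0] == 2500.0 and press[-1] == 0.0


class TestPropagate:
    def test_uniform_pulse_translates(self):
        areas = np.full(10, 2e-4)
        field = AcousticField(np.zeros(10), np.zeros(10))
        field.forward[3] = 1.0
        out = propagate(field, areas, 1.0 / (2 * FS))
        assert out.forward[4] == pytest.approx(1.0)
        assert np.count_nonzero(out.forward[1:]) == 1
        assert np.allclose(out.backward[:-1], 0.0)

    def test_closed_end_full_reflection(self):
        # a huge area drop reflects the pressure wave with coefficient ~ +1
        areas = np.array([2e-4, 2e-4, 2e-12])
        field = AcousticField(np.array([0.0, 1.0, 0.0]), np.zeros(3))
        out = propagate(field, areas, 1.0 / (2 * FS))
        assert out.backward[1] == pytest.approx(1.0, rel=1e-6)

    def test_half_area_reflection_third(self):
        # r = (A0 - A1)/(A0 + A1) = 1/3; transmitted pressure = 1 + r
        areas = np.array([2e-4, 1e-4])
        field = AcousticField(np.array([1.0, 0.0]), np.zeros(2))
        out = propagate(field, areas, 1.0 / (2 * FS))
        assert out.backward[0] == pytest.approx(1.0 / 3.0)
        assert out.forward[1] == pytest.approx(4.0 / 3.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            propagate(AcousticField(np.zeros(3), np.zeros(3)),
                      np.array([1e-4, 0.0, 1e-4]), 1.0 / (2 * FS))


class TestSimulate:
    def test_zero_lung_pressure_silent(self, model_airway):
        res = simulate(model_airway, SimConfig(lung_pressure_kpa=0.0,
                                               duration_s=0.1))
        assert np.allclose(res.oral_pressure_pa, 0.0)
        assert np.allclose(res.glottal_flow_l_s, 0.0)
        assert np.allclose(res.mean_area_mm2, res.pre_area_mm2, rtol=1e-9)

    def test_deterministic_reruns(self, model_airway):
        cfg = SimConfig(duration_s=0.2)
        r1 = simulate(model_airway, cfg)
        r2 = simulate(model_airway, cfg)
        assert np.array_equal(r1.oral_pressure_pa, r2.oral_pressure_pa)
        assert np.array_equal(r1.glottal_area_mm2, r2.glottal_area_mm2)
        assert np.array_equal(r1.mean_radius_mm, r2.mean_radius_mm)

    def test_open_phonation_self_oscillates(self, open_run):
        fs = open_run.sampling_rate_hz
        tail = open_run.glottal_area_mm2[int(0.5 * fs):]
        assert tail.max() - tail.min() > 1.0  # sustained, not decayed
        f0 = estimate_f0(tail, fs)
        # fold natural frequency is 300 Hz at the reference pitch scale
        assert f0 == pytest.approx(300.0, rel=0.08)

    def test_open_phonation_amplitude_saturates(self, open_run):
        fs = open_run.sampling_rate_hz
        f0 = estimate_f0(open_run.glottal_area_mm2[int(0.5 * fs):], fs)
        period = int(round(fs / f0))
        tail = open_run.glottal_area_mm2[-10 * period:]
        peaks = tail.reshape(10, period).max(axis=1)
        assert np.max(np.abs(np.diff(peaks))) / peaks.mean() < 0.02

    def test_semi_occlusion_builds_oral_pressure(self, results_run):
        fs = results_run.sampling_rate_hz
        tail = results_run.oral_pressure_pa[int(0.7 * fs):]
        assert 1300.0 < tail.mean() < 2300.0

    def test_expansion_monotone_with_occlusion(self, results_run, open_run):
        # the oral semi-occlusion expands the supraglottal airway; with an
        # open mouth the supraglottal mean pressure is ~0 and it stays at rest
        lm = results_run.airway.landmarks
        i = lm["pharyngeal_entry"]
        occluded = results_run.mean_area_mm2[i] / results_run.pre_area_mm2[i]
        j = open_run.airway.landmarks["pharyngeal_entry"]
        open_ratio = open_run.mean_area_mm2[j] / open_run.pre_area_mm2[j]
        assert occluded > 1.3
        assert open_ratio < 1.1

    def test_mean_state_matches_steady_oracle(self, results_run):
        # time-averaged radii vs the self-consistent quasi-static network
        # oracle, excluding the oscillating fold sections and the rigid tube
        airway = results_run.airway
        oracle = quasi_static_equilibrium(airway, 2.5)
        r_oracle = np.array([s.d_minor_mm / 2 for s in oracle.sections])
        r_sim = results_run.mean_radius_mm
        keep = [i for i, s in enumerate(airway.sections)
                if s.region not in ("glottis", "tube")]
        rel = np.abs(r_sim[keep] - r_oracle[keep]) / r_oracle[keep]
        assert np.max(rel) < 0.15


class TestSignalAnalysis:
    def test_f0_of_sine(self):
        t = np.arange(int(0.5 * FS)) / FS
        assert estimate_f0(np.sin(2 * np.pi * 300 * t), FS) == pytest.approx(
            300.0, abs=0.5)

    def test_constant_signal_not_detected(self):
        with pytest.raises(F0NotDetected):
            estimate_f0(np.ones(int(0.5 * FS)), FS)

    def test_spectrum_peak_location(self):
        t = np.arange(int(0.5 * FS)) / FS
        spec = spectrum(np.sin(2 * np.pi * 441 * t), FS)
        peak = spec.frequency_hz[np.argmax(spec.power)]
        assert peak == pytest.approx(441.0, abs=3.0)
        assert spec.magnitude_db.max() == 0.0

    def test_parseval(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=int(0.3 * FS))
        x = x - x.mean()
        w = np.hanning(len(x))
        spec = spectrum(x, FS)
        time_energy = np.sum((x - 0) ** 2 * w**2)
        # rfft power double-counts all but DC/Nyquist bins
        p = spec.power.copy()
        p[1:-1] *= 2
        assert p.sum() / len(x) == pytest.approx(time_energy, rel=1e-6)

    def test_band_energy_total(self):
        t = np.arange(int(0.3 * FS)) / FS
        spec = spectrum(np.sin(2 * np.pi * 500 * t), FS)
        total = band_energy(spec, 1.0, FS / 2)
        inside = band_energy(spec, 400, 600)
        outside = band_energy(spec, 3000, 4000)
        assert inside == pytest.approx(total, abs=0.1)
        assert outside < inside - 40

    def test_empty_band_rejected(self):
        t = np.arange(int(0.3 * FS)) / FS
        spec = spectrum(np.sin(2 * np.pi * 500 * t), FS)
        with pytest.raises(ValueError):
            band_energy(spec, 1000.0, 900.0)
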