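import numpy as np
import pytest

from sovt.constants import AIR_DENSITY, SECTION_LENGTH_CM, SPEED_OF_SOUND
from sovt.acoustics import (
    DEFAULT_GRID,
    F1NotDetected,
    Inertagram,
    detect_f1,
    input_impedance,
    make_inertagram,
    mean_band_inertance,
    radiation_impedance,
    subglottal_impedance,
    supraglottal_impedance,
)
from sovt.geometry import Section, AIRWAY_WALL_PARAMS, TubeSpec, build_vowel_airway


def uniform_tube(n, diameter_mm=20.0):
    return [Section(i, "supraglottal", "circle", SECTION_LENGTH_CM,
                    diameter_mm, None, AIRWAY_WALL_PARAMS) for i in range(n)]


class TestRadiation:
    def test_open_end_limit(self):
        z = radiation_impedance(3e-4, [1.0, 10.0, 100.0])
        assert np.all(np.abs(z) == np.sort(np.abs(z)))
        assert abs(z[0]) < 1e3

    def test_low_frequency_end_correction(self):
        area = 3e-4
        a = np.sqrt(area / np.pi)
        f = np.array([20.0])
        z = radiation_impedance(area, f)
        expected = 2 * np.pi * f[0] * AIR_DENSITY * 0.8488 * a / area
        assert z[0].imag == pytest.approx(expected, rel=0.01)

    def test_smaller_opening_higher_reactance(self):
        # X ~ 0.85 a / A ~ A**-0.5: halving the opening scales |Z| by sqrt(2)
        f = np.array([50.0])
        z1 = radiation_impedance(3e-4, f)[0]
        z2 = radiation_impedance(1.5e-4, f)[0]
        assert abs(z2) == pytest.approx(np.sqrt(2) * abs(z1), rel=0.01)


class TestChainMatrix:
    def test_closed_tube_equals_cotangent(self):
        secs = uniform_tube(44)
        L = 44 * SECTION_LENGTH_CM / 100.0
        area = np.pi * 0.020**2 / 4
        zc = AIR_DENSITY * SPEED_OF_SOUND / area
        f = DEFAULT_GRID
        z = input_impedance(secs, f, 1e18, wall_losses=False,
                            viscous_losses=False).impedance
        closed = -1j * zc / np.tan(2 * np.pi * f * L / SPEED_OF_SOUND)
        assert np.max(np.abs(z - closed) / np.abs(closed)) < 1e-8

    def test_empty_range_returns_termination(self):
        f = np.array([100.0, 200.0])
        term = np.array([1 + 2j, 3 + 4j])
        z = input_impedance([], f, term).impedance
        assert np.allclose(z, term)

    def test_composability(self):
        secs = uniform_tube(10) + uniform_tube(10, diameter_mm=12.0)
        f = np.arange(50, 3000, 50.0)
        zrad = radiation_impedance(np.pi * 0.012**2 / 4, f)
        whole = input_impedance(secs, f, zrad).impedance
        inner = input_impedance(secs[10:], f, zrad).impedance
        outer = input_impedance(secs[:10], f, inner).impedance
        assert np.max(np.abs(whole - outer) / np.abs(whole)) < 1e-10

    def test_passivity(self):
        airway = build_vowel_airway("narrow", 0.2, TubeSpec(0.08, 0.003))
        z = supraglottal_impedance(airway)
        assert np.all(z.resistance >= 0)


class TestSubglottal:
    def test_zero_length_returns_termination(self):
        f = np.array([100.0])
        z = input_impedance([], f, 5e5 + 0j).impedance
        assert z[0] == pytest.approx(5e5)

    def test_compliant_band_below_1khz(self, model_airway):
        z = subglottal_impedance(model_airway)
        f = z.frequency_hz
        band = (f > 200) & (f < 1000)
        assert np.any(z.reactance[band] < 0)

    def test_termination_resistance_passivity(self, model_airway):
        f = DEFAULT_GRID
        z1 = subglottal_impedance(model_airway, f, termination=2e5 + 0j)
        z2 = subglottal_impedance(model_airway, f, termination=4e5 + 0j)
        # doubling a resistive termination never turns the input active
        assert np.all(z2.resistance >= 0)
        assert np.all(z1.resistance >= 0)


class TestInertagram:
    def test_pure_inertance(self):
        f = np.arange(10, 1000, 2.0)
        ig = make_inertagram(
            type("Z", (), {"frequency_hz": f,
                           "reactance": 2 * np.pi * f * 0.5,
                           "impedance": 1j * 2 * np.pi * f * 0.5})())
        assert np.allclose(ig.inertance, 0.5)

    def test_zero_reactance(self):
        f = np.arange(10, 1000, 2.0)
        from sovt.acoustics import ImpedanceSpectrum
        ig = make_inertagram(ImpedanceSpectrum(f, np.ones_like(f) + 0j))
        assert np.all(ig.inertance == 0.0)

    def test_narrow_epilarynx_peak_3_4khz(self):
        # the 2.4 cm x 0.2 cm^2 epilarynx resonates near c/4L ~ 3.6 kHz and
        # dominates the upper inertagram of the wide-pharynx shape
        airway = build_vowel_airway("wide", 0.2, None)
        ig = make_inertagram(supraglottal_impedance(airway))
        band = (ig.frequency_hz >= 2000) & (ig.frequency_hz <= 5000)
        peak = ig.frequency_hz[band][np.argmax(ig.inertance[band])]
        assert 2800 <= peak <= 4200

    def test_grid_mismatch_rejected(self):
        from sovt.acoustics import ImpedanceSpectrum
        f1 = np.arange(10, 100, 2.0)
        f2 = np.arange(10, 100, 4.0)
        a = ImpedanceSpectrum(f1, np.ones_like(f1) * 1j)
        b = ImpedanceSpectrum(f2, np.ones_like(f2) * 1j)
        with pytest.raises(ValueError):
            make_inertagram(a, b)


class TestF1:
    def test_quarter_wave_tube(self):
        # 17.46 cm uniform tube, ideally open far end: F1 = c/4L
        secs = uniform_tube(44)
        L = 44 * SECTION_LENGTH_CM / 100.0
        z = input_impedance(secs, DEFAULT_GRID, None, wall_losses=False,
                            viscous_losses=False)
        ig = make_inertagram(z)
        assert detect_f1(ig) == pytest.approx(SPEED_OF_SOUND / (4 * L), abs=2.0)

    def test_tube_lowers_f1_both_shapes(self):
        for pharynx in ("wide", "narrow"):
            free = make_inertagram(supraglottal_impedance(
                build_vowel_airway(pharynx, 0.2, None)))
            tubed = make_inertagram(supraglottal_impedance(
                build_vowel_airway(pharynx, 0.2, TubeSpec(0.08, 0.003))))
            assert detect_f1(tubed) < detect_f1(free)

    def test_no_crossing_raises(self):
        f = np.arange(10, 1000, 2.0)
        ig = Inertagram(f, np.zeros_like(f), np.zeros_like(f), [])
        with pytest.raises(F1NotDetected):
            detect_f1(ig)
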