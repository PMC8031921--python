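import io
import math

import numpy as np
import pytest

from sovt.constants import SAMPLING_RATE, SECTION_LENGTH_CM, SPEED_OF_SOUND
from sovt.geometry import (
    Airway,
    GeometryError,
    Section,
    TubeSpec,
    WallParams,
    AIRWAY_WALL_PARAMS,
    build_model_airway,
    build_vowel_airway,
    read_area_function,
    section_area,
    set_glottal_profile,
    write_area_function,
)


class TestModelAirway:
    def test_section_counts_and_lengths(self, model_airway):
        counts = {r: len(model_airway.region_indices(r))
                  for r in ("trachea", "transition", "glottis", "epilarynx",
                            "supraglottal")}
        assert counts == {"trachea": 36, "transition": 2, "glottis": 5,
                          "epilarynx": 6, "supraglottal": 38}
        trachea_len = sum(model_airway.sections[i].length_cm
                          for i in model_airway.region_indices("trachea"))
        assert trachea_len == pytest.approx(14.3, abs=0.05)
        glottis_len = sum(model_airway.sections[i].length_cm
                          for i in model_airway.region_indices("glottis"))
        assert glottis_len == pytest.approx(0.8, abs=1e-9)
        epi_len = sum(model_airway.sections[i].length_cm
                      for i in model_airway.region_indices("epilarynx"))
        assert epi_len == pytest.approx(2.38, abs=0.01)

    def test_supraglottal_total(self, model_airway):
        supra = [s for s in model_airway.sections
                 if s.region in ("epilarynx", "supraglottal")]
        assert len(supra) == 44
        assert sum(s.length_cm for s in supra) == pytest.approx(17.5, abs=0.05)

    def test_section_length_matches_sampling(self):
        assert SECTION_LENGTH_CM == pytest.approx(
            SPEED_OF_SOUND / (2 * SAMPLING_RATE) * 100, abs=5e-5)
        assert SECTION_LENGTH_CM == 0.3968

    def test_landmark_areas(self, model_airway):
        areas = model_airway.areas_mm2()
        lm = model_airway.landmarks
        assert areas[0] == pytest.approx(255.0)
        assert areas[lm["glottal_entry"]] == pytest.approx(4.7)
        assert areas[lm["glottal_exit"]] == pytest.approx(6.3)
        assert areas[lm["epilarynx_entry"]] == pytest.approx(20.0)
        assert areas[lm["pharyngeal_entry"]] == pytest.approx(155.0)

    def test_tube_appended(self):
        airway = build_model_airway(tube=TubeSpec(0.10, 0.003))
        tube = airway.region_indices("tube")
        assert len(tube) == 25
        assert airway.sections[tube[0]].d_minor_mm == pytest.approx(3.0)

    def test_invalid_total_length_rejected(self):
        with pytest.raises(GeometryError):
            build_model_airway(trachea_length_cm=14.0)


class TestVowelAirway:
    def test_epilarynx_diameter(self):
        airway = build_vowel_airway("wide", 0.2, None)
        epi = [airway.sections[i] for i in airway.region_indices("epilarynx")]
        assert len(epi) == 6
        for s in epi:
            assert s.d_minor_mm == pytest.approx(5.05, abs=0.01)
            assert section_area(s) == pytest.approx(20.0, rel=1e-3)

    def test_tube_spec_respected(self):
        airway = build_vowel_airway("narrow", 0.2, TubeSpec(0.08, 0.003))
        tube = [airway.sections[i] for i in airway.region_indices("tube")]
        assert tube[-1].d_minor_mm == pytest.approx(3.0)
        assert sum(s.length_cm for s in tube) == pytest.approx(8.0, abs=0.1)

    def test_shapes_share_epilarynx_and_subglottis(self):
        wide = build_vowel_airway("wide", 0.2, None)
        narrow = build_vowel_airway("narrow", 0.2, None)
        for region in ("trachea", "transition", "glottis", "epilarynx"):
            iw, inn = wide.region_indices(region), narrow.region_indices(region)
            assert [wide.sections[i] for i in iw] == \
                [narrow.sections[i] for i in inn]
        assert wide.areas_mm2()[wide.landmarks["pharyngeal_entry"] + 10] != \
            narrow.areas_mm2()[narrow.landmarks["pharyngeal_entry"] + 10]


class TestGlottalProfile:
    def test_convergent_interpolation(self, model_airway):
        airway = set_glottal_profile(model_airway, "convergent", 4.7, 6.3)
        glottis = [airway.sections[i] for i in airway.region_indices("glottis")]
        assert glottis[0].d_minor_mm == pytest.approx(0.598, abs=2e-3)
        assert glottis[-1].d_minor_mm == pytest.approx(0.802, abs=2e-3)
        diffs = np.diff([s.d_minor_mm for s in glottis])
        assert np.allclose(diffs, diffs[0])

    def test_rectangular_uniform(self, model_airway):
        airway = set_glottal_profile(model_airway, "rectangular", 5.0, 5.0)
        minors = [airway.sections[i].d_minor_mm
                  for i in airway.region_indices("glottis")]
        assert len(set(np.round(minors, 12))) == 1

    def test_bulging_interior_minimum(self, model_airway):
        airway = set_glottal_profile(model_airway, "bulging", 4.7, 6.3)
        minors = [airway.sections[i].d_minor_mm
                  for i in airway.region_indices("glottis")]
        assert int(np.argmin(minors)) in (1, 2, 3)

    def test_negative_area_rejected(self, model_airway):
        with pytest.raises(GeometryError):
            set_glottal_profile(model_airway, "convergent", -1.0, 6.3)


class TestSectionArea:
    def test_circle(self):
        s = Section(0, "trachea", "circle", SECTION_LENGTH_CM, 5.05, None,
                    AIRWAY_WALL_PARAMS)
        assert section_area(s) == pytest.approx(20.0, abs=0.05)

    def test_ellipse(self):
        s = Section(0, "glottis", "ellipse", 0.16, 0.598, 10.0,
                    AIRWAY_WALL_PARAMS)
        assert section_area(s) == pytest.approx(4.70, rel=1e-3)

    def test_zero_minor_diameter(self):
        s = Section(0, "glottis", "ellipse", 0.16, 0.0, 10.0,
                    AIRWAY_WALL_PARAMS)
        assert section_area(s) == 0.0


class TestSerialization:
    def test_round_trip_identity(self):
        for airway in (build_model_airway(), build_vowel_airway("narrow", 0.3,
                                                                TubeSpec(0.08, 0.004))):
            buf = io.StringIO()
            write_area_function(airway, buf)
            buf.seek(0)
            again = read_area_function(buf)
            assert again.sections == airway.sections

    def test_negative_length_rejected(self):
        text = ("index\tregion\tshape\tlength_cm\td_minor_mm\td_major_mm\t"
                "E_kPa\tG_kPa\tm_g_cm2\tzeta\n"
                "0\ttrachea\tcircle\t-1.0\t18.0\t\t9.62\t1.67\t1.5\t1.26\n")
        with pytest.raises(GeometryError, match="line 2"):
            read_area_function(io.StringIO(text))

    def test_region_order_enforced(self):
        header = ("index\tregion\tshape\tlength_cm\td_minor_mm\td_major_mm\t"
                  "E_kPa\tG_kPa\tm_g_cm2\tzeta\n")
        rows = ("0\tepilarynx\tcircle\t0.3968\t5.0\t\t9.62\t1.67\t1.5\t1.26\n"
                "1\ttrachea\tcircle\t0.3968\t18.0\t\t9.62\t1.67\t1.5\t1.26\n")
        with pytest.raises(GeometryError, match="out of order"):
            read_area_function(io.StringIO(header + rows))


class TestInvariants:
    def test_wall_params_validated(self):
        with pytest.raises(GeometryError):
            WallParams(-1.0, 1.0, 1.0, 0.5, 1.0)
        with pytest.raises(GeometryError):
            WallParams(1.0, 1.0, 1.0, -0.5, 1.0)

    def test_ellipse_requires_major(self):
        with pytest.raises(GeometryError):
            Section(0, "glottis", "ellipse", 0.16, 5.0, None,
                    AIRWAY_WALL_PARAMS)

    def test_tube_spec_positive(self):
        with pytest.raises(GeometryError):
            TubeSpec(-0.1, 0.003)

    def test_out_of_range_tube_warns(self):
        with pytest.warns(UserWarning, match="calibration range"):
            TubeSpec(0.30, 0.003)
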