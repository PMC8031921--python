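"""Sectioned airway geometries for 1D aero-acoustic simulation.

An :class:`Airway` is an ordered (lung -> lips) list of short wall-backed tube
sections.  Circular sections describe the trachea, pharynx, mouth and any
flow-resistant tube at the lips; the five vocal-fold sections and the two
trachea-to-glottis transition sections are elliptical.  Named landmarks
(glottal entry/exit, epilarynx entry/exit, pharyngeal entry, tube entry) are
derived from the region tags and anchor the expansion reports.

Two generators are provided:

* :func:`build_model_airway` -- the reference male airway used for the
  expansion experiments: 36 tracheal + 2 transition + 5 glottal +
  44 supraglottal sections, with landmark cross-sections anchored to CT/MRI
  reference values (subglottal 255 mm^2, epilarynx 20 mm^2, pharyngeal entry
  155 mm^2, glottal entry/exit 4.7/6.3 mm^2), plus an optional lip tube.
* :func:`build_vowel_airway` -- parametric /i/-like (wide pharynx) and
  /a/-like (narrow pharynx) supraglottal shapes over the same subglottal
  template, used for the inertagram experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

from .constants import (
    AIRWAY_WALL,
    FOLD_DAMPING_RATIOS,
    FOLD_MAJOR_DIAMETER_MM,
    FOLD_WALL,
    GLOTTAL_SECTION_LENGTH_CM,
    SECTION_LENGTH_CM,
    ellipse_perimeter,
)

Region = Literal["trachea", "transition", "glottis", "epilarynx", "supraglottal", "nasal", "tube"]
Shape = Literal["circle", "ellipse"]

#: Region order along the airway (nasal stored inert, tube last).
REGION_ORDER: tuple[str, ...] = (
    "trachea", "transition", "glottis", "epilarynx", "supraglottal", "nasal", "tube",
)

#: Empirical calibration range of the tube-resistance fit (m).
TUBE_LENGTH_RANGE_M = (0.03, 0.24)
TUBE_DIAMETER_RANGE_M = (0.0018, 0.0097)


class GeometryError(ValueError):
    """Invalid airway geometry or malformed area-function input."""


@dataclass(frozen=True)
class WallParams:
    """Viscoelastic constants of a section's yielding wall.

    ``effective_depth_cm`` converts the Young's modulus into a stiffness per
    unit wall area (kappa = E / depth); see :mod:`sovt.walls`.
    """

    youngs_modulus_kpa: float
    shear_modulus_kpa: float
    mass_per_area_g_cm2: float
    damping_ratio: float
    effective_depth_cm: float

    def __post_init__(self) -> None:
        for name in ("youngs_modulus_kpa", "shear_modulus_kpa",
                     "mass_per_area_g_cm2", "effective_depth_cm"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"WallParams.{name} must be > 0")
        if self.damping_ratio < 0:
            raise GeometryError("WallParams.damping_ratio must be >= 0")


AIRWAY_WALL_PARAMS = WallParams(**AIRWAY_WALL)


def fold_wall_params(damping_ratio: float, f0_scale: float = 1.0) -> WallParams:
    """Vocal-fold wall constants, optionally pitch-scaled.

    ``f0_scale`` multiplies the elastic moduli and divides the surface mass so
    the natural tissue frequency scales linearly (130 Hz at scale 1).
    """
    return WallParams(
        youngs_modulus_kpa=FOLD_WALL["youngs_modulus_kpa"] * f0_scale,
        shear_modulus_kpa=FOLD_WALL["shear_modulus_kpa"] * f0_scale,
        mass_per_area_g_cm2=FOLD_WALL["mass_per_area_g_cm2"] / f0_scale,
        damping_ratio=damping_ratio,
        effective_depth_cm=FOLD_WALL["effective_depth_cm"],
    )


@dataclass(frozen=True)
class Section:
    """One short tube section with a yielding wall."""

    index: int
    region: str
    shape: str
    length_cm: float
    d_minor_mm: float
    d_major_mm: float | None
    wall: WallParams

    def __post_init__(self) -> None:
        if self.region not in REGION_ORDER:
            raise GeometryError(f"unknown region tag {self.region!r}")
        if self.shape not in ("circle", "ellipse"):
            raise GeometryError(f"unknown shape tag {self.shape!r}")
        if not self.length_cm > 0:
            raise GeometryError("section length must be > 0")
        if self.d_minor_mm < 0:
            raise GeometryError("minor diameter must be >= 0")
        if self.shape == "ellipse":
            if self.d_major_mm is None or self.d_major_mm < self.d_minor_mm:
                raise GeometryError("ellipse requires major diameter >= minor diameter")
        elif self.d_major_mm is not None:
            raise GeometryError("circle must not carry a major diameter")


def section_area(section: Section) -> float:
    """Cross-sectional area of a section in mm^2."""
    if section.shape == "circle":
        return math.pi * section.d_minor_mm**2 / 4.0
    return math.pi / 4.0 * section.d_major_mm * section.d_minor_mm


def section_perimeter(section: Section) -> float:
    """Wall perimeter of a section in mm."""
    if section.shape == "circle":
        return math.pi * section.d_minor_mm
    return ellipse_perimeter(section.d_major_mm, section.d_minor_mm)


@dataclass(frozen=True)
class TubeSpec:
    """A flow-resistant tube at the lips (SI units)."""

    length_m: float
    diameter_m: float

    def __post_init__(self) -> None:
        if not (self.length_m > 0 and self.diameter_m > 0):
            raise GeometryError("tube length and diameter must be > 0")
        lo, hi = TUBE_LENGTH_RANGE_M
        dlo, dhi = TUBE_DIAMETER_RANGE_M
        if not (lo <= self.length_m <= hi) or not (dlo <= self.diameter_m <= dhi):
            warnings.warn(
                f"tube {self.length_m*100:.1f} cm x {self.diameter_m*1000:.1f} mm is outside "
                "the empirical calibration range of the resistance fit",
                stacklevel=2,
            )


LANDMARK_KEYS = (
    "glottal_entry", "glottal_exit", "epilarynx_entry", "epilarynx_exit",
    "pharyngeal_entry", "tube_entry",
)


@dataclass
class Airway:
    """Ordered lung -> lips sequence of sections."""

    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        order = {r: i for i, r in enumerate(REGION_ORDER)}
        last = -1
        for sec in self.sections:
            rank = order[sec.region]
            if rank < last:
                raise GeometryError(
                    f"section {sec.index}: region {sec.region!r} out of order"
                )
            last = rank
            if sec.region == "glottis":
                expected = GLOTTAL_SECTION_LENGTH_CM
            else:
                expected = SECTION_LENGTH_CM
            if abs(sec.length_cm - expected) > 1e-6:
                raise GeometryError(
                    f"section {sec.index}: length {sec.length_cm} cm != {expected} cm"
                )

    # -- derived views ----------------------------------------------------

    def region_indices(self, region: str) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.region == region]

    @property
    def landmarks(self) -> dict[str, int]:
        """Named landmark -> section index (only landmarks that exist)."""
        marks: dict[str, int] = {}
        glottis = self.region_indices("glottis")
        if glottis:
            marks["glottal_entry"] = glottis[0]
            marks["glottal_exit"] = glottis[-1]
        epi = self.region_indices("epilarynx")
        if epi:
            marks["epilarynx_entry"] = epi[0]
            marks["epilarynx_exit"] = epi[-1]
        supra = self.region_indices("supraglottal")
        if supra:
            marks["pharyngeal_entry"] = supra[0]
        tube = self.region_indices("tube")
        if tube:
            marks["tube_entry"] = tube[0]
        return marks

    def axial_positions_cm(self) -> np.ndarray:
        """Axial position of each section's entry plane (cm from tracheal entry)."""
        lengths = np.array([s.length_cm for s in self.sections])
        return np.concatenate([[0.0], np.cumsum(lengths)[:-1]])

    def areas_mm2(self) -> np.ndarray:
        return np.array([section_area(s) for s in self.sections])

    def __len__(self) -> int:
        return len(self.sections)


# ---------------------------------------------------------------------------
# generators


def _n_sections(length_cm: float, what: str) -> int:
    n = length_cm / SECTION_LENGTH_CM
    if abs(n - round(n)) > 0.25:
        raise GeometryError(
            f"{what} length {length_cm} cm is not close to an integer number "
            f"of {SECTION_LENGTH_CM} cm sections"
        )
    return int(round(n))


def _circle_d(area_mm2: float) -> float:
    return math.sqrt(4.0 * area_mm2 / math.pi)


def _ellipse_minor(area_mm2: float, d_major_mm: float = FOLD_MAJOR_DIAMETER_MM) -> float:
    return 4.0 * area_mm2 / (math.pi * d_major_mm)


#: Pre-pressure landmark cross-sectional areas (mm^2) of the model airway.
DEFAULT_LANDMARK_AREAS: dict[str, float] = {
    "subglottal": 255.0,
    "glottal_entry": 4.7,
    "glottal_exit": 6.3,
    "epilarynx": 20.0,
    "pharyngeal_entry": 155.0,
}


def _make_tube_sections(tube: TubeSpec, start_index: int) -> list[Section]:
    n = max(1, int(round(tube.length_m * 100.0 / SECTION_LENGTH_CM)))
    d = tube.diameter_m * 1000.0
    return [
        Section(start_index + i, "tube", "circle", SECTION_LENGTH_CM, d, None,
                AIRWAY_WALL_PARAMS)
        for i in range(n)
    ]


def build_model_airway(
    landmark_areas: Mapping[str, float] | None = None,
    tube: TubeSpec | None = TubeSpec(0.10, 0.003),
    oral_diameter_mm: float = 25.0,
    glottal_profile: str = "bulging",
    f0_scale: float = 1.0,
    trachea_length_cm: float = 14.3,
    transition_length_cm: float = 0.79,
    epilarynx_length_cm: float = 2.38,
    pharynx_length_cm: float = 7.94,
    supraglottal_length_cm: float = 17.46,
) -> Airway:
    """Construct the reference model airway.

    36 tracheal, 2 transition, 5 glottal and 44 supraglottal sections
    (6 epilarynx + 20 pharyngeal + 18 oral); landmark areas default to the
    pre-pressure model column of the reference geometry.  A flow-resistant
    tube (default 3 mm x 10 cm) is appended at the lips unless ``tube`` is
    None.  The oral diameter is a configurable constant (25 mm): only its
    order of magnitude matters for the experiments.
    """
    areas = dict(DEFAULT_LANDMARK_AREAS)
    if landmark_areas:
        areas.update(landmark_areas)

    n_tra = _n_sections(trachea_length_cm, "trachea")
    n_tr = _n_sections(transition_length_cm, "transition")
    n_epi = _n_sections(epilarynx_length_cm, "epilarynx")
    n_pha = _n_sections(pharynx_length_cm, "pharynx")
    n_sup = _n_sections(supraglottal_length_cm, "supraglottal tract")
    n_oral = n_sup - n_epi - n_pha
    if n_oral <= 0:
        raise GeometryError("supraglottal length too short for epilarynx + pharynx")

    d_tra = _circle_d(areas["subglottal"])
    d_epi = _circle_d(areas["epilarynx"])
    d_pha = _circle_d(areas["pharyngeal_entry"])
    d_gl_entry = _ellipse_minor(areas["glottal_entry"])

    sections: list[Section] = []
    idx = 0
    for _ in range(n_tra):
        sections.append(Section(idx, "trachea", "circle", SECTION_LENGTH_CM,
                                d_tra, None, AIRWAY_WALL_PARAMS))
        idx += 1
    # transition: interpolate minor diameter tracheal -> glottal entry and
    # major diameter tracheal -> fold length, as ellipses
    for i in range(n_tr):
        t = (i + 1) / (n_tr + 1)
        d_minor = d_tra + t * (d_gl_entry - d_tra)
        d_major = d_tra + t * (FOLD_MAJOR_DIAMETER_MM - d_tra)
        d_major = max(d_major, d_minor)
        sections.append(Section(idx, "transition", "ellipse", SECTION_LENGTH_CM,
                                d_minor, d_major, AIRWAY_WALL_PARAMS))
        idx += 1
    glottal_minors = _glottal_minor_diameters(
        glottal_profile, areas["glottal_entry"], areas["glottal_exit"])
    for i in range(5):
        sections.append(Section(idx, "glottis", "ellipse", GLOTTAL_SECTION_LENGTH_CM,
                                glottal_minors[i], FOLD_MAJOR_DIAMETER_MM,
                                fold_wall_params(FOLD_DAMPING_RATIOS[i], f0_scale)))
        idx += 1
    for _ in range(n_epi):
        sections.append(Section(idx, "epilarynx", "circle", SECTION_LENGTH_CM,
                                d_epi, None, AIRWAY_WALL_PARAMS))
        idx += 1
    # pharynx: linear diameter ramp from the pharyngeal-entry landmark to the
    # oral diameter; mouth constant
    for i in range(n_pha):
        t = i / max(n_pha - 1, 1)
        d = d_pha + t * (oral_diameter_mm - d_pha)
        sections.append(Section(idx, "supraglottal", "circle", SECTION_LENGTH_CM,
                                d, None, AIRWAY_WALL_PARAMS))
        idx += 1
    for _ in range(n_oral):
        sections.append(Section(idx, "supraglottal", "circle", SECTION_LENGTH_CM,
                                oral_diameter_mm, None, AIRWAY_WALL_PARAMS))
        idx += 1
    if tube is not None:
        sections.extend(_make_tube_sections(tube, idx))
    return Airway(sections)


def _glottal_minor_diameters(profile: str, entry_area: float, exit_area: float) -> list[float]:
    """Five fold minor diameters (mm) for a named medial-surface profile."""
    if entry_area < 0 or exit_area < 0:
        raise GeometryError("glottal areas must be >= 0")
    d_entry = _ellipse_minor(entry_area)
    d_exit = _ellipse_minor(exit_area)
    t = np.linspace(0.0, 1.0, 5)
    linear = d_entry + t * (d_exit - d_entry)
    if profile == "rectangular":
        if not math.isclose(entry_area, exit_area, rel_tol=1e-9):
            raise GeometryError("rectangular profile requires entry area == exit area")
        return [d_entry] * 5
    if profile in ("convergent", "divergent"):
        return [float(x) for x in linear]
    if profile == "bulging":
        # medial bulge: interior sections narrower than the linear contour
        bulge = np.array([1.0, 0.85, 0.7, 0.85, 1.0])
        return [float(x) for x in linear * bulge]
    raise GeometryError(f"unknown glottal profile {profile!r}")


def set_glottal_profile(airway: Airway, profile: str,
                        entry_area_mm2: float, exit_area_mm2: float) -> Airway:
    """Return a copy of ``airway`` with the five fold minor diameters reset."""
    glottis = airway.region_indices("glottis")
    if len(glottis) != 5:
        raise GeometryError("airway does not contain five glottal sections")
    minors = _glottal_minor_diameters(profile, entry_area_mm2, exit_area_mm2)
    sections = list(airway.sections)
    for k, i in enumerate(glottis):
        sections[i] = replace(sections[i], d_minor_mm=minors[k])
    return Airway(sections)


def build_vowel_airway(
    pharynx: Literal["wide", "narrow"],
    epilarynx_area_cm2: float = 0.2,
    tube: TubeSpec | None = None,
    epilarynx_length_cm: float = 2.5,
    oral_diameter_mm: float | None = None,
) -> Airway:
    """Parametric vowel-like supraglottal shape over the model subglottal template.

    ``wide`` emulates an /i/-like configuration (wide pharynx ~3.8 cm^2,
    narrow oral cavity ~0.8 cm^2); ``narrow`` an /a/-like one (narrow pharynx
    ~0.95 cm^2, wide oral cavity ~4.9 cm^2).  Both share the same narrow
    epilarynx (default 0.2 cm^2 over ~2.5 cm) and the model trachea, and only
    the pharyngeal/oral sections differ between the two shapes.
    """
    if pharynx not in ("wide", "narrow"):
        raise GeometryError("pharynx must be 'wide' or 'narrow'")
    if not epilarynx_area_cm2 > 0:
        raise GeometryError("epilarynx area must be > 0")
    base = build_model_airway(tube=None)
    keep = [s for s in base.sections if s.region in ("trachea", "transition", "glottis")]

    n_epi = max(1, int(round(epilarynx_length_cm / SECTION_LENGTH_CM)))
    n_sup = 44
    n_pha = 20
    n_oral = n_sup - n_epi - n_pha
    d_epi = _circle_d(epilarynx_area_cm2 * 100.0)
    if pharynx == "wide":
        d_pharynx, d_oral = 22.0, 10.0
    else:
        d_pharynx, d_oral = 11.0, 25.0
    if oral_diameter_mm is not None:
        d_oral = oral_diameter_mm

    sections = list(keep)
    idx = len(sections)
    for _ in range(n_epi):
        sections.append(Section(idx, "epilarynx", "circle", SECTION_LENGTH_CM,
                                d_epi, None, AIRWAY_WALL_PARAMS))
        idx += 1
    # smooth piecewise-linear diameter profile: 4-section ramps into the
    # pharyngeal and oral plateaus
    ramp = 4
    for i in range(n_pha):
        t = min(i / ramp, 1.0)
        d = d_epi + t * (d_pharynx - d_epi)
        sections.append(Section(idx, "supraglottal", "circle", SECTION_LENGTH_CM,
                                d, None, AIRWAY_WALL_PARAMS))
        idx += 1
    for i in range(n_oral):
        t = min(i / ramp, 1.0)
        d = d_pharynx + t * (d_oral - d_pharynx)
        sections.append(Section(idx, "supraglottal", "circle", SECTION_LENGTH_CM,
                                d, None, AIRWAY_WALL_PARAMS))
        idx += 1
    if tube is not None:
        sections.extend(_make_tube_sections(tube, idx))
    return Airway(sections)


# ---------------------------------------------------------------------------
# serialization

_HEADER = "index\tregion\tshape\tlength_cm\td_minor_mm\td_major_mm\tE_kPa\tG_kPa\tm_g_cm2\tzeta"


def write_area_function(airway: Airway, destination) -> None:
    """Write an airway as a tab-separated area-function file."""
    close = False
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        fh = open(destination, "w")
        close = True
    else:
        fh = destination
    try:
        fh.write("# sovt area function, one row per section, lung -> lips\n")
        fh.write(_HEADER + "\n")
        for s in airway.sections:
            major = "" if s.d_major_mm is None else repr(s.d_major_mm)
            w = s.wall
            fh.write("\t".join([
                str(s.index), s.region, s.shape, repr(s.length_cm),
                repr(s.d_minor_mm), major, repr(w.youngs_modulus_kpa),
                repr(w.shear_modulus_kpa), repr(w.mass_per_area_g_cm2),
                repr(w.damping_ratio),
            ]) + "\n")
    finally:
        if close:
            fh.close()


def read_area_function(source) -> Airway:
    """Read an area-function file written by :func:`write_area_function`.

    The wall effective depth is restored from the region tag (fold depth for
    glottal sections, airway depth otherwise); all other fields round-trip
    bit-identically.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source)
        close = True
    else:
        fh = source
    try:
        sections: list[Section] = []
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if line != _HEADER:
                    raise GeometryError(f"line {lineno}: unexpected header {line!r}")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise GeometryError(f"line {lineno}: expected 10 fields, got {len(parts)}")
            try:
                idx = int(parts[0])
                region, shape = parts[1], parts[2]
                length = float(parts[3])
                d_minor = float(parts[4])
                d_major = float(parts[5]) if parts[5] else None
                depth = (FOLD_WALL["effective_depth_cm"] if region == "glottis"
                         else AIRWAY_WALL["effective_depth_cm"])
                wall = WallParams(float(parts[6]), float(parts[7]), float(parts[8]),
                                  float(parts[9]), depth)
                sections.append(Section(idx, region, shape, length, d_minor, d_major, wall))
            except (ValueError, GeometryError) as exc:
                raise GeometryError(f"line {lineno}: {exc}") from exc
        if not header_seen:
            raise GeometryError("missing area-function header")
        return Airway(sections)
    finally:
        if close:
            fh.close()
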