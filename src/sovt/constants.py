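"""Physical constants and canonical discretization of the airway model.

The airway is discretized into short tube sections whose length is tied to
the audio sampling rate of the wave-reflection solver: a traveling wave must
cross exactly one section per half sample period, so

    section_length = c / (2 * f_s)

With c = 350 m/s (warm, humid air) and f_s = 44100 Hz this gives 0.3968 cm,
the standard section length for 1D articulatory synthesis.
"""

import numpy as np

#: Speed of sound in warm humid airway air (m/s).
SPEED_OF_SOUND = 350.0

#: Density of warm humid airway air (kg/m^3).
AIR_DENSITY = 1.14

#: Dynamic viscosity of air (Pa s), used for acoustic boundary-layer losses.
AIR_VISCOSITY = 1.86e-5

#: Audio sampling rate of the time-domain solver (Hz).
SAMPLING_RATE = 44100.0

#: Acoustic section length (cm), c / (2 f_s) rounded to 4 decimals.
SECTION_LENGTH_CM = round(SPEED_OF_SOUND / (2.0 * SAMPLING_RATE) * 100.0, 4)

#: Axial length of one vocal-fold section (cm); five sections span 0.8 cm.
GLOTTAL_SECTION_LENGTH_CM = 0.16

#: Vocal-fold (ventral-dorsal) length = major diameter of fold ellipses (mm).
FOLD_MAJOR_DIAMETER_MM = 10.0

# Viscoelastic wall constants.  Airway walls are overdamped so that only the
# fold sections self-oscillate; fold constants give a 130 Hz natural tissue
# frequency through the effective-depth convention in `sovt.walls`.
AIRWAY_WALL = dict(
    youngs_modulus_kpa=9.62,
    shear_modulus_kpa=1.67,
    mass_per_area_g_cm2=1.5,
    damping_ratio=1.26,
    effective_depth_cm=1.0,
)
FOLD_WALL = dict(
    youngs_modulus_kpa=4.0,
    shear_modulus_kpa=1.0,
    mass_per_area_g_cm2=0.3,
    effective_depth_cm=0.2,
)
#: Fold damping ratios, lower three sections then upper two (entry -> exit).
FOLD_DAMPING_RATIOS = (0.2, 0.2, 0.2, 0.6, 0.6)


def ellipse_perimeter(d_major_mm: float, d_minor_mm: float) -> float:
    """Ramanujan approximation of the ellipse perimeter (mm)."""
    a = d_major_mm / 2.0
    b = d_minor_mm / 2.0
    h = ((a - b) / (a + b)) ** 2 if (a + b) > 0 else 0.0
    return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))
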