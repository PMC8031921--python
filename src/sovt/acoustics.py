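"""Frequency-domain acoustics: chained two-port input impedance and inertagrams.

Each airway section is a uniform transmission-line two-port

    [P_in; U_in] = [[cosh(gl), Zc sinh(gl)], [sinh(gl)/Zc, cosh(gl)]] [P_out; U_out]

optionally augmented with a series viscous boundary-layer resistance and a
yielding-wall shunt branch built from the section's wall constants.  The
supraglottal chain is terminated by a lumped piston radiation load, the
subglottal chain by a resistive-inertive load at the tracheal bifurcation.

The time convention is e^{+i omega t}, so inertive (mass-like) reactance is
positive.  An inertagram plots the inertance I = X / (2 pi f) of the
supraglottal input impedance where X > 0; compliant bands of the subglottal
impedance are entered as negative values below the zero line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AIR_DENSITY, AIR_VISCOSITY, SPEED_OF_SOUND
from .geometry import Airway, Section, section_area, section_perimeter
from .walls import damping_per_area, mass_per_area_si, stiffness_per_area

#: Default analysis grid: 10 Hz -- 5 kHz in 2 Hz steps.
DEFAULT_GRID = np.arange(10.0, 5002.0, 2.0)

#: Bifurcation termination defaults: R = 0.3 rho c / A_trachea and an
#: inertance placing the first subglottal compliant band near 700 Hz.
BIFURCATION_RESISTANCE_FACTOR = 0.3
BIFURCATION_INERTANCE = 60.0  # Pa s^2/m^3, deepest compliant reactance ~680 Hz

#: Fraction of the wall damping constant entering the acoustic shunt branch.
#: The wall ODE's damping ratio lumps all mechanical losses (chosen to keep
#: airway walls from self-oscillating); using it in full over-damps the
#: wall-cavity resonance and erases the low first resonance of semi-occluded
#: configurations, so the acoustic branch uses half of it.
WALL_SHUNT_DAMPING_SCALE = 0.5


class SingularSectionError(ValueError):
    """A zero-area section makes the chain matrix singular."""


@dataclass
class ImpedanceSpectrum:
    """Complex acoustic input impedance Z = R + iX over a frequency grid."""

    frequency_hz: np.ndarray
    impedance: np.ndarray  # complex, Pa s/m^3

    @property
    def resistance(self) -> np.ndarray:
        return self.impedance.real

    @property
    def reactance(self) -> np.ndarray:
        return self.impedance.imag


@dataclass
class Inertagram:
    """Signed inertance I = X/(2 pi f) over frequency, with resonance markers."""

    frequency_hz: np.ndarray
    inertance: np.ndarray            # supraglottal, >= 0
    subglottal_inertance: np.ndarray  # <= 0 where the subglottal side is compliant
    resonance_crossings_hz: list[float] = field(default_factory=list)

    @property
    def f1_hz(self) -> float | None:
        return self.resonance_crossings_hz[0] if self.resonance_crossings_hz else None


def radiation_impedance(opening_area_m2: float, frequency_hz) -> np.ndarray:
    """Lumped piston-in-baffle radiation load (parallel R-L), Pa s/m^3.

    Resistance R = 128 rho c / (9 pi^2 A) in parallel with the end-correction
    inertance L = rho (0.85 a) / A, a = sqrt(A/pi); |Z| -> 0 as f -> 0.
    """
    if not opening_area_m2 > 0:
        raise ValueError("opening area must be > 0")
    f = np.asarray(frequency_hz, dtype=float)
    a = np.sqrt(opening_area_m2 / np.pi)
    r = 128.0 * AIR_DENSITY * SPEED_OF_SOUND / (9.0 * np.pi**2 * opening_area_m2)
    ind = AIR_DENSITY * (8.0 * a / (3.0 * np.pi)) / opening_area_m2
    jwl = 1j * 2.0 * np.pi * f * ind
    return r * jwl / (r + jwl)


def _section_two_port(section: Section, omega: np.ndarray,
                      wall_losses: bool, viscous_losses: bool):
    """Per-frequency ABCD entries of one section."""
    area_m2 = section_area(section) * 1e-6
    if area_m2 <= 0:
        raise SingularSectionError(f"section {section.index} has zero area")
    length_m = section.length_cm / 100.0
    perim_m = section_perimeter(section) * 1e-3
    zc = AIR_DENSITY * SPEED_OF_SOUND / area_m2
    kl = omega / SPEED_OF_SOUND * length_m
    cos_kl, sin_kl = np.cos(kl), np.sin(kl)
    a = cos_kl.astype(complex)
    b = 1j * zc * sin_kl
    c = 1j * sin_kl / zc
    d = cos_kl.astype(complex)
    if viscous_losses:
        # series boundary-layer resistance, split symmetrically
        r = length_m * perim_m / area_m2**2 * np.sqrt(
            omega * AIR_DENSITY * AIR_VISCOSITY / 2.0)
        half = r / 2.0
        # [1, h; 0, 1] @ [a, b; c, d] @ [1, h; 0, 1]
        a2 = a + half * c
        b2 = b + half * (a + d) + half**2 * c
        d2 = d + half * c
        a, b, d = a2, b2, d2
    if wall_losses:
        # yielding-wall shunt at the input plane: Y = S_wall / z_w
        zw = (WALL_SHUNT_DAMPING_SCALE * damping_per_area(section.wall)
              + 1j * (omega * mass_per_area_si(section.wall)
                      - stiffness_per_area(section.wall) / omega))
        y = perim_m * length_m / zw
        # [1, 0; y, 1] @ [a, b; c, d]
        c = c + y * a
        d = d + y * b
    return a, b, c, d


def input_impedance(
    sections,
    frequency_hz,
    termination: np.ndarray | complex | None = None,
    wall_losses: bool = True,
    viscous_losses: bool = True,
) -> ImpedanceSpectrum:
    """Input impedance of a contiguous section range.

    ``sections`` are ordered from the input plane toward the termination.
    ``termination`` is the terminating impedance on the same grid (scalar,
    array, or None for an ideal open end Z = 0).  An empty range returns the
    termination unchanged.
    """
    f = np.asarray(frequency_hz, dtype=float)
    omega = 2.0 * np.pi * f
    a = np.ones_like(f, dtype=complex)
    b = np.zeros_like(f, dtype=complex)
    c = np.zeros_like(f, dtype=complex)
    d = np.ones_like(f, dtype=complex)
    for sec in sections:
        sa, sb, sc, sd = _section_two_port(sec, omega, wall_losses, viscous_losses)
        a, b, c, d = a * sa + b * sc, a * sb + b * sd, c * sa + d * sc, c * sb + d * sd
    if termination is None:
        zt = np.zeros_like(f, dtype=complex)
    else:
        zt = np.broadcast_to(np.asarray(termination, dtype=complex), f.shape)
    z = (a * zt + b) / (c * zt + d)
    return ImpedanceSpectrum(frequency_hz=f, impedance=z)


def supraglottal_impedance(airway: Airway, frequency_hz=DEFAULT_GRID,
                           wall_losses: bool = True,
                           viscous_losses: bool = True) -> ImpedanceSpectrum:
    """Impedance looking from the glottal exit toward the lips, terminated by
    the radiation load at the final opening."""
    secs = [s for s in airway.sections
            if s.region in ("epilarynx", "supraglottal", "tube")]
    if not secs:
        raise ValueError("airway has no supraglottal sections")
    area_m2 = section_area(secs[-1]) * 1e-6
    zrad = radiation_impedance(area_m2, frequency_hz)
    return input_impedance(secs, frequency_hz, zrad,
                           wall_losses=wall_losses, viscous_losses=viscous_losses)


def subglottal_impedance(airway: Airway, frequency_hz=DEFAULT_GRID,
                         termination: np.ndarray | complex | None = None,
                         wall_losses: bool = True,
                         viscous_losses: bool = True) -> ImpedanceSpectrum:
    """Impedance looking from the glottal entry toward the lungs.

    The chain runs from the glottal entry plane down the transition and
    tracheal sections to a resistive-inertive termination at the tracheal
    bifurcation (defaults chosen to give a compliant band below 1 kHz).
    """
    secs = [s for s in airway.sections if s.region in ("trachea", "transition")]
    if not secs:
        raise ValueError("airway has no tracheal sections")
    secs = list(reversed(secs))  # glottis side first
    if termination is None:
        f = np.asarray(frequency_hz, dtype=float)
        area_m2 = section_area(secs[-1]) * 1e-6
        r = BIFURCATION_RESISTANCE_FACTOR * AIR_DENSITY * SPEED_OF_SOUND / area_m2
        termination = r + 1j * 2.0 * np.pi * f * BIFURCATION_INERTANCE
    return input_impedance(secs, frequency_hz, termination,
                           wall_losses=wall_losses, viscous_losses=viscous_losses)


def make_inertagram(supraglottal: ImpedanceSpectrum,
                    subglottal: ImpedanceSpectrum | None = None) -> Inertagram:
    """Convert impedance spectra into an inertagram.

    Supraglottal inertance I = X/(2 pi f) where X > 0, else 0.  Subglottal
    compliant reactance is entered as an equivalent negative inertance below
    the zero line (the sub- and supraglottal flows are in antiphase).
    """
    f = supraglottal.frequency_hz
    omega = 2.0 * np.pi * f
    x = supraglottal.reactance
    inert = np.where(x > 0.0, x / omega, 0.0)
    if subglottal is not None:
        if (subglottal.frequency_hz.shape != f.shape
                or not np.allclose(subglottal.frequency_hz, f)):
            raise ValueError("supraglottal and subglottal grids differ")
        xs = subglottal.reactance
        sub = np.where(xs < 0.0, xs / omega, 0.0)
    else:
        sub = np.zeros_like(f)
    crossings = _downward_crossings(f, x)
    return Inertagram(frequency_hz=f, inertance=inert, subglottal_inertance=sub,
                      resonance_crossings_hz=crossings)


def _downward_crossings(f: np.ndarray, x: np.ndarray,
                        f_min: float = 20.0) -> list[float]:
    """Frequencies where the reactance crosses zero downward, linearly
    interpolated to sub-grid precision."""
    out = []
    for i in range(len(f) - 1):
        if f[i] < f_min:
            continue
        if x[i] > 0.0 and x[i + 1] <= 0.0:
            t = x[i] / (x[i] - x[i + 1])
            out.append(float(f[i] + t * (f[i + 1] - f[i])))
    return out


class F1NotDetected(RuntimeError):
    """No positive-inertance band with a downward crossing was found."""


def detect_f1(inertagram: Inertagram) -> float:
    """First acoustic resonance: the first sudden drop of the supraglottal
    inertance from a high value to zero (downward zero crossing above 20 Hz)."""
    below_2k = [c for c in inertagram.resonance_crossings_hz]
    if not below_2k:
        raise F1NotDetected("no downward inertance crossing found")
    mask = (inertagram.frequency_hz < 2000.0)
    if not np.any(inertagram.inertance[mask] > 0.0):
        raise F1NotDetected("no positive-inertance band below 2 kHz")
    return below_2k[0]


def mean_band_inertance(inertagram: Inertagram, f_lo: float, f_hi: float) -> float:
    """Mean supraglottal inertance over a frequency band (Pa s^2/m^3)."""
    m = (inertagram.frequency_hz >= f_lo) & (inertagram.frequency_hz <= f_hi)
    if not np.any(m):
        raise ValueError("empty frequency band")
    return float(np.mean(inertagram.inertance[m]))
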