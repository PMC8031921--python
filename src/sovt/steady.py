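"""Steady (mean-flow) aerodynamics of the semi-occluded airway.

The series flow network lung -> trachea -> glottis -> epilarynx -> tube
carries a single mean flow Q.  Tube-like segments (trachea, epilarynx, lip
tube) use an empirical flow-resistance fit calibrated on bench measurements
of tubes 3--24 cm long and 1.8--9.7 mm in diameter; the glottis is a
Bernoulli orifice with full kinetic loss.  Solving the network for Q at a
given lung pressure yields the mean pressure at every section, which is the
quasi-static oracle for the time-domain simulation's mean state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import AIR_DENSITY
from .geometry import (
    Airway,
    TubeSpec,
    TUBE_DIAMETER_RANGE_M,
    TUBE_LENGTH_RANGE_M,
    section_area,
)


class SteadySolveError(RuntimeError):
    """The network solve failed to converge."""


@dataclass
class SteadySolution:
    """Converged mean-flow state of the series network."""

    flow_l_s: float
    mean_pressure_kpa: np.ndarray  # per section, lung -> lips
    resistances: dict[str, float]  # Pa s/L at the converged flow

    @property
    def oral_pressure_kpa(self) -> float:
        """Mean pressure just upstream of the lip tube (or at the lips)."""
        return float(self._oral_pressure)

    _oral_pressure: float = 0.0


def tube_flow_resistance(length_m: float, diameter_m: float, flow_l_s: float,
                         warn_out_of_range: bool = True) -> float:
    """Empirical flow resistance of a narrow tube, in Pa s/L.

    R(Q) is affine in the flow: a kinetic component proportional to Q plus a
    constant (viscous) component, both steeply decreasing with diameter::

        R = (3.7631e-7 L/D^4.4997 + 1.0268e-6/D^4.0416) Q
          + (3.9913e-9 L/D^5.0089 + 8.0169e-7/D^3.7696)

    with L, D in m and Q in L/s.
    """
    if not (length_m > 0 and diameter_m > 0):
        raise ValueError("length and diameter must be > 0")
    if flow_l_s < 0:
        raise ValueError("flow must be >= 0")
    if warn_out_of_range:
        lo, hi = TUBE_LENGTH_RANGE_M
        dlo, dhi = TUBE_DIAMETER_RANGE_M
        if not (lo <= length_m <= hi and dlo <= diameter_m <= dhi):
            warnings.warn(
                f"tube {length_m:.3f} m x {diameter_m*1000:.1f} mm outside the "
                "empirical calibration range; resistance extrapolated",
                stacklevel=2,
            )
    L, D, Q = length_m, diameter_m, flow_l_s
    slope = 3.7631e-7 * L / D**4.4997 + 1.0268e-6 / D**4.0416
    const = 3.9913e-9 * L / D**5.0089 + 8.0169e-7 / D**3.7696
    return slope * Q + const


def orifice_resistance(area_mm2: float, flow_l_s: float,
                       kinetic_coefficient: float = 1.0) -> float:
    """Quasi-static Bernoulli orifice resistance (Pa s/L), linear in flow.

    Full kinetic loss (no downstream pressure recovery) by default:
    dP = k_t (rho/2) (Q/A)^2, so R = dP/Q.
    """
    if not area_mm2 > 0:
        raise ZeroDivisionError("orifice area must be > 0 (closed glottis)")
    a_m2 = area_mm2 * 1e-6
    q_m3s = flow_l_s * 1e-3
    # dP = k rho/2 (q/A)^2 in Pa; R = dP / Q with Q in L/s
    return kinetic_coefficient * AIR_DENSITY / 2.0 * q_m3s / a_m2**2 * 1e-3


_ALL_COMPONENTS = ("trachea", "glottis", "epilarynx", "tube")


def _component_geometry(airway: Airway):
    """Equivalent (length, diameter) of the tube-like components and the
    minimum glottal area."""
    geo = {}
    for region in ("trachea", "epilarynx", "tube"):
        idx = airway.region_indices(region)
        if not idx:
            continue
        secs = [airway.sections[i] for i in idx]
        length_m = sum(s.length_cm for s in secs) / 100.0
        mean_area_mm2 = float(np.mean([section_area(s) for s in secs]))
        diameter_m = np.sqrt(4.0 * mean_area_mm2 / np.pi) / 1000.0
        geo[region] = (length_m, diameter_m)
    glottis = airway.region_indices("glottis")
    if glottis:
        geo["glottis"] = min(section_area(airway.sections[i]) for i in glottis)
    return geo


def solve_steady_network(
    airway: Airway,
    lung_pressure_kpa: float,
    include: tuple[str, ...] = _ALL_COMPONENTS,
    kinetic_coefficient: float = 1.0,
) -> SteadySolution:
    """Solve sum_i R_i(Q) Q = P_lung for the mean flow and section pressures.

    ``include`` restricts which components are resistive (useful for oracle
    tests); excluded components drop no pressure.  Supraglottal sections
    downstream of the glottal minimum carry the post-glottal pressure (the
    glottal jet does not recover its kinetic head).
    """
    if lung_pressure_kpa < 0:
        raise ValueError("lung pressure must be >= 0")
    p_pa = lung_pressure_kpa * 1000.0
    geo = _component_geometry(airway)

    def drop(q: float) -> dict[str, float]:
        drops = {}
        for region in ("trachea", "epilarynx", "tube"):
            if region in geo and region in include:
                L, D = geo[region]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    drops[region] = tube_flow_resistance(L, D, q) * q
            else:
                drops[region] = 0.0
        if "glottis" in geo and "glottis" in include:
            drops["glottis"] = orifice_resistance(geo["glottis"], q,
                                                  kinetic_coefficient) * q
        else:
            drops["glottis"] = 0.0
        return drops

    def residual(q: float) -> float:
        return sum(drop(q).values()) - p_pa

    if p_pa == 0.0 or residual(0.0) >= 0.0:
        q_star = 0.0
    else:
        q_hi = 1.0
        for _ in range(60):
            if residual(q_hi) > 0:
                break
            q_hi *= 2.0
        else:
            raise SteadySolveError("could not bracket the flow solution")
        q_star = brentq(residual, 0.0, q_hi, xtol=1e-12, rtol=1e-12)
    if q_star > 0 and abs(residual(q_star)) > 1e-9 * max(p_pa, 1.0):
        raise SteadySolveError(
            f"network solve residual {residual(q_star):.3e} Pa at Q={q_star:.4f} L/s")

    drops = drop(q_star)
    resistances = {
        "R_t": drops["trachea"] / q_star if q_star else 0.0,
        "R_g": drops["glottis"] / q_star if q_star else 0.0,
        "R_e": drops["epilarynx"] / q_star if q_star else 0.0,
        "R_L": drops["tube"] / q_star if q_star else 0.0,
    }

    # per-section mean pressures by cumulative drops, lung -> lips
    n = len(airway.sections)
    pressures = np.zeros(n)
    p = p_pa
    tra = airway.region_indices("trachea") + airway.region_indices("transition")
    glo = airway.region_indices("glottis")
    epi = airway.region_indices("epilarynx")
    tube = airway.region_indices("tube")
    supra = airway.region_indices("supraglottal")
    d_tra = drops["trachea"] / max(len(tra), 1)
    for i in tra:
        pressures[i] = p - d_tra / 2.0
        p -= d_tra
    # glottis: Bernoulli static pressure at each fold section; downstream of
    # the minimum there is no recovery, so the post-glottal value is p - drop
    p_post_glottis = p - drops["glottis"]
    if glo:
        areas = np.array([section_area(airway.sections[i]) for i in glo])
        k_min = int(np.argmin(areas))
        q_m3s = q_star * 1e-3
        for k, i in enumerate(glo):
            if k <= k_min and areas[k] > 0:
                bern = p - kinetic_coefficient * AIR_DENSITY / 2.0 * (q_m3s / (areas[k] * 1e-6))**2
                pressures[i] = max(bern, p_post_glottis)
            else:
                pressures[i] = p_post_glottis
    p = p_post_glottis
    d_epi = drops["epilarynx"] / max(len(epi), 1)
    for i in epi:
        pressures[i] = p - d_epi / 2.0
        p -= d_epi
    for i in supra:
        pressures[i] = p
    oral = p
    d_tube = drops["tube"] / max(len(tube), 1)
    for i in tube:
        pressures[i] = p - d_tube / 2.0
        p -= d_tube
    sol = SteadySolution(flow_l_s=q_star, mean_pressure_kpa=pressures / 1000.0,
                         resistances=resistances)
    sol._oral_pressure = oral / 1000.0
    return sol


def resistance_curves(specs, flow_grid) -> pd.DataFrame:
    """Resistance-vs-flow curves for tubes and orifices.

    ``specs`` is a list of (label, TubeSpec) or (label, orifice_area_mm2)
    pairs; returns a long-format table ``flow_L_s, resistance_Pa_s_L, label``.
    """
    flow_grid = np.asarray(flow_grid, dtype=float)
    rows = []
    for label, spec in specs:
        for q in flow_grid:
            if isinstance(spec, TubeSpec):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = tube_flow_resistance(spec.length_m, spec.diameter_m, q)
            else:
                r = orifice_resistance(float(spec), q)
            rows.append((q, r, label))
    return pd.DataFrame(rows, columns=["flow_L_s", "resistance_Pa_s_L", "label"])
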