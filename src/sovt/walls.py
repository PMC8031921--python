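"""Viscoelastic wall mechanics of the airway sections.

Each section's wall is a damped second-order oscillator per unit wall area,

    m x'' + c x' + kappa x - kappa_s (x+ - 2x + x-) = P,

where x is the radial displacement (positive outward), P the fluid pressure
on the wall, kappa = E / effective_depth the stiffness per unit area,
c = 2 zeta sqrt(kappa m) the damping, and kappa_s a shear coupling between
axially adjacent wall sections of the same region.

The effective depths are fixed module constants, chosen once: 0.2 cm for the
fold sections (so that E = 4 kPa and m = 0.3 g/cm^2 give a 130 Hz natural
tissue frequency) and 1.0 cm for all other airway walls (so that a 2.5 kPa
tracheal pressure produces a ~66% tracheal area expansion, the right order
for a passively widening airway).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import Airway, GeometryError, WallParams


@dataclass
class WallState:
    """Dynamic radial wall state of one section."""

    displacement_mm: float = 0.0
    velocity_mm_s: float = 0.0


def stiffness_per_area(wall: WallParams) -> float:
    """Wall stiffness per unit area, kappa = E / effective_depth, in Pa/m."""
    return wall.youngs_modulus_kpa * 1000.0 / (wall.effective_depth_cm / 100.0)


def mass_per_area_si(wall: WallParams) -> float:
    """Surface mass density in kg/m^2 (1 g/cm^2 = 10 kg/m^2)."""
    return wall.mass_per_area_g_cm2 * 10.0


def damping_per_area(wall: WallParams) -> float:
    """Damping constant per unit area c = 2 zeta sqrt(kappa m), Pa s/m."""
    return 2.0 * wall.damping_ratio * np.sqrt(
        stiffness_per_area(wall) * mass_per_area_si(wall))


def shear_coupling_per_area(wall: WallParams, section_length_m: float) -> float:
    """Axial shear-coupling stiffness per unit area, Pa/m.

    kappa_s = G * effective_depth / dz^2 couples adjacent wall sections of
    the same region; it smooths the axial displacement profile without
    changing the uniform-pressure equilibrium.
    """
    g_pa = wall.shear_modulus_kpa * 1000.0
    depth_m = wall.effective_depth_cm / 100.0
    return g_pa * depth_m / section_length_m**2


def natural_frequency(wall: WallParams) -> float:
    """Undamped natural frequency f = (1/2pi) sqrt(kappa/m) in Hz."""
    return float(np.sqrt(stiffness_per_area(wall) / mass_per_area_si(wall))
                 / (2.0 * np.pi))


def quasi_static_expand(airway: Airway, mean_pressures_pa) -> Airway:
    """Expand every section radius by dr = P / kappa (elliptical major
    diameters unchanged)."""
    p = np.asarray(mean_pressures_pa, dtype=float)
    if p.shape != (len(airway.sections),):
        raise ValueError("one mean pressure per section required")
    sections = []
    for sec, pi in zip(airway.sections, p):
        dr_mm = pi / stiffness_per_area(sec.wall) * 1000.0
        d_new = max(sec.d_minor_mm + 2.0 * dr_mm, 0.0)
        if sec.shape == "ellipse":
            d_major = max(sec.d_major_mm, d_new)
        else:
            d_major = sec.d_major_mm
        sections.append(replace(sec, d_minor_mm=d_new, d_major_mm=d_major))
    return Airway(sections)


def quasi_static_equilibrium(airway: Airway, lung_pressure_kpa: float,
                             max_iter: int = 60, tol: float = 1e-10) -> Airway:
    """Self-consistent inflated state: fixed point of the steady network
    solve and the quasi-static expansion.

    Expansion lowers the network's flow resistances, which changes the
    pressure distribution, which changes the expansion; iterating the
    solve/expand pair from the rest geometry converges to the static
    equilibrium the time-domain simulation relaxes to when it does not
    oscillate.
    """
    from .steady import solve_steady_network

    current = airway
    prev = None
    for _ in range(max_iter):
        sol = solve_steady_network(current, lung_pressure_kpa)
        # pressures computed on the current geometry, displacement applied
        # to the rest geometry (linear walls: x = P / kappa); the lip tube
        # is rigid and keeps its rest bore
        current = quasi_static_expand(airway, sol.mean_pressure_kpa * 1000.0)
        sections = [rest if rest.region == "tube" else inflated
                    for rest, inflated in zip(airway.sections, current.sections)]
        current = Airway(sections)
        radii = np.array([s.d_minor_mm for s in current.sections])
        if prev is not None and np.max(np.abs(radii - prev)) < tol:
            break
        prev = radii
    return current


def step_wall(
    state: WallState,
    wall: WallParams,
    surface_pressure_pa: float,
    neighbors: tuple[WallState | None, WallState | None],
    dt_s: float,
    section_length_m: float = 0.003968,
    rest_minor_diameter_mm: float | None = None,
) -> WallState:
    """Advance one wall section by ``dt_s`` with semi-implicit Euler.

    ``neighbors`` are the (upstream, downstream) wall states of the same
    region, or None at a region boundary (zero shear force).  If
    ``rest_minor_diameter_mm`` is given, the lumen is floored at closure
    (minor diameter >= 0) with the velocity zeroed on contact.
    """
    if not (np.isfinite(state.displacement_mm) and np.isfinite(state.velocity_mm_s)):
        raise FloatingPointError("non-finite wall state")
    kappa = stiffness_per_area(wall)
    m = mass_per_area_si(wall)
    c = damping_per_area(wall)
    ks = shear_coupling_per_area(wall, section_length_m)
    x = state.displacement_mm / 1000.0
    v = state.velocity_mm_s / 1000.0
    shear = 0.0
    for nb in neighbors:
        if nb is not None:
            shear += ks * (nb.displacement_mm / 1000.0 - x)
    force = surface_pressure_pa - kappa * x + shear
    v = (v + dt_s * force / m) / (1.0 + dt_s * c / m)
    x = x + dt_s * v
    if rest_minor_diameter_mm is not None:
        floor = -rest_minor_diameter_mm / 2000.0
        if x < floor:
            x, v = floor, 0.0
    return WallState(displacement_mm=x * 1000.0, velocity_mm_s=v * 1000.0)


def stiffen_region(airway: Airway, region: str, youngs_modulus_kpa: float) -> Airway:
    """Return a copy with all sections of ``region`` set to a new Young's
    modulus (all other wall fields unchanged)."""
    idx = airway.region_indices(region)
    if not idx:
        raise GeometryError(f"airway has no sections in region {region!r}")
    sections = list(airway.sections)
    for i in idx:
        wall = replace(sections[i].wall, youngs_modulus_kpa=youngs_modulus_kpa)
        sections[i] = replace(sections[i], wall=wall)
    return Airway(sections)
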