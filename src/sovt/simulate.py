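"""Coupled time-domain simulation of self-sustained phonation at 44.1 kHz.

The airway is a wave-reflection (scattering) analog: forward and backward
traveling pressure waves cross one 0.3968 cm section per half sample period
(c = 350 m/s exactly).  At every junction the scattering update conserves
pressure and flow, optionally through a series resistance; yielding walls
inject/absorb volume velocity through their own second-order dynamics, which
also carries the slow passive expansion of the airway under the mean
pressure build-up.

The five short vocal-fold sections are handled aerodynamically rather than
as wave sections: a quasi-steady Bernoulli flow driven by the transglottal
pressure couples the subglottal and supraglottal wave chains, with flow
separation (>= 20% divergence) switching the fold surface load to the
supraglottal input pressure.  The lip tube carries the empirical
flow-resistance of the steady model, distributed over its junctions and
evaluated at the low-pass-filtered (mean) flow.

Everything is deterministic: no noise sources, fixed initial rest state,
lung pressure ramped over the onset time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import AIR_DENSITY, SAMPLING_RATE, SPEED_OF_SOUND
from .geometry import Airway, TubeSpec, fold_wall_params
from .steady import tube_flow_resistance
from .walls import (
    damping_per_area,
    mass_per_area_si,
    shear_coupling_per_area,
    stiffness_per_area,
)

RHO_C = AIR_DENSITY * SPEED_OF_SOUND

#: Flow separation threshold: separation at >= 20% area expansion above the
#: glottal minimum.
SEPARATION_RATIO = 1.2

#: Lung termination resistance as a fraction of the tracheal characteristic
#: impedance (partially absorbing pressure source).
LUNG_RESISTANCE_FACTOR = 0.2

#: Per-crossing wave attenuation.  Distributed losses are carried by the
#: yielding walls, the junction resistances and the terminations, so the
#: propagation itself is lossless by default (attenuation would also leak
#: the mean-flow component).
ATTENUATION = 1.0

#: Time constant (s) of the low-pass filter extracting the mean tube flow.
MEAN_FLOW_TAU = 0.010

#: Axial length of one glottal (fold) section (m), for the duct inertance.
FOLD_LENGTH_M = 0.0016

#: Total axial length of the glottal duct (m), for its empirical duct loss.
GLOTTAL_DUCT_LENGTH_M = 0.008


class SimulationUnstable(RuntimeError):
    def __init__(self, sample: int):
        super().__init__(f"non-finite signal at sample {sample}")
        self.sample = sample


@dataclass
class SimConfig:
    """Run configuration for :func:`simulate`."""

    lung_pressure_kpa: float = 2.5
    duration_s: float = 1.0
    f0_scale: float = 300.0 / 130.0
    epilarynx_stiffen_kpa: float | None = None
    tube: TubeSpec | None = TubeSpec(0.10, 0.003)
    onset_ramp_ms: float = 50.0
    mean_window_s: float = 0.100  # averaging window for the post state
    sampling_rate_hz: float = SAMPLING_RATE

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration must be > 0")
        if not self.f0_scale > 0:
            raise ValueError("f0_scale must be > 0")


@dataclass
class SimResult:
    """Time series and derived mean state of one simulation run."""

    time_s: np.ndarray
    glottal_area_mm2: np.ndarray      # minimum fold area
    glottal_flow_l_s: np.ndarray
    oral_pressure_pa: np.ndarray      # at the lip plane / tube entry
    radiated_pressure_pa: np.ndarray
    subglottal_pressure_pa: np.ndarray
    supraglottal_pressure_pa: np.ndarray  # epilarynx entry plane
    fold_area_mm2: np.ndarray         # (n_samples, 5)
    pre_area_mm2: np.ndarray          # per section, at rest
    mean_area_mm2: np.ndarray         # per section, final-window average
    mean_radius_mm: np.ndarray        # per section, final-window average
    config: SimConfig = field(repr=False, default=None)
    airway: Airway = field(repr=False, default=None)

    @property
    def sampling_rate_hz(self) -> float:
        return self.config.sampling_rate_hz if self.config else SAMPLING_RATE


def _apply_config_to_airway(airway: Airway, cfg: SimConfig) -> Airway:
    from .geometry import _make_tube_sections  # local: generator helper
    from .walls import stiffen_region

    sections = [s for s in airway.sections if s.region != "tube"]
    if cfg.tube is not None:
        sections = sections + _make_tube_sections(cfg.tube, len(sections))
    out = Airway(sections)
    if cfg.epilarynx_stiffen_kpa is not None:
        out = stiffen_region(out, "epilarynx", cfg.epilarynx_stiffen_kpa)
    # pitch scaling of the fold walls
    if abs(cfg.f0_scale - 1.0) > 1e-12:
        from dataclasses import replace
        secs = list(out.sections)
        for i in out.region_indices("glottis"):
            zeta = secs[i].wall.damping_ratio
            secs[i] = replace(secs[i], wall=fold_wall_params(zeta, cfg.f0_scale))
        out = Airway(secs)
    return out


class _Chain:
    """One wave-propagation chain (arrays indexed lung -> lips)."""

    def __init__(self, sections, dt2: float):
        self.sections = sections
        n = len(sections)
        self.n = n
        self.d0 = np.array([s.d_minor_mm for s in sections])  # rest minor diam
        self.d_major = np.array([s.d_major_mm if s.d_major_mm else s.d_minor_mm
                                 for s in sections])
        self.is_ellipse = np.array([s.shape == "ellipse" for s in sections])
        self.yielding = np.array([s.region != "tube" for s in sections])
        # fold sections do not use the local-wave volume sink: their pumped
        # volume escapes through the short incompressible duct to the much
        # lower tract impedances, not into the section's own (huge) local
        # characteristic impedance
        self.sink = np.array([s.region not in ("tube", "glottis")
                              for s in sections])
        self.length_m = np.array([s.length_cm / 100.0 for s in sections])
        # wall constants (per unit area, SI)
        self.kappa = np.array([stiffness_per_area(s.wall) for s in sections])
        self.mass = np.array([mass_per_area_si(s.wall) for s in sections])
        self.damp = np.array([damping_per_area(s.wall) for s in sections])
        self.ks = np.array([shear_coupling_per_area(s.wall, s.length_cm / 100.0)
                            for s in sections])
        regions = [s.region for s in sections]
        self.same_up = np.array([i > 0 and regions[i] == regions[i - 1]
                                 for i in range(n)])
        self.same_dn = np.array([i < n - 1 and regions[i] == regions[i + 1]
                                 for i in range(n)])
        self.x = np.zeros(n)   # wall displacement (m, outward)
        self.v = np.zeros(n)   # wall velocity (m/s)
        self.F = np.zeros(n)   # forward wave incident at right edge (Pa)
        self.B = np.zeros(n)   # backward wave incident at left edge (Pa)
        self.r_junction = np.zeros(max(n - 1, 0))  # series junction resistance
        self.update_areas()

    def update_areas(self) -> None:
        d = np.maximum(self.d0 + 2e3 * self.x, 1e-3)  # mm, floored
        area_mm2 = np.where(self.is_ellipse, np.pi / 4.0 * self.d_major * d,
                            np.pi / 4.0 * d * d)
        self.area = area_mm2 * 1e-6
        self.d_mm = d
        self.Z = RHO_C / self.area
        # wall surface = perimeter x length; circle perimeter is pi d, the
        # elliptical transition sections use the mean-diameter approximation
        perim_m = np.pi * (self.d_major + d) / 2.0 * 1e-3
        self.surface = perim_m * self.length_m

    def step_walls(self, dt: float, p_correction=None) -> None:
        p = self.F + self.B
        if p_correction is not None:
            p = p + p_correction
        shear = np.zeros(self.n)
        shear[self.same_up] += (self.ks * (np.roll(self.x, 1) - self.x))[self.same_up]
        shear[self.same_dn] += (self.ks * (np.roll(self.x, -1) - self.x))[self.same_dn]
        force = p - self.kappa * self.x + shear
        v_new = (self.v + dt * force / self.mass) / (1.0 + dt * self.damp / self.mass)
        mask = self.yielding
        self.v[mask] = v_new[mask]
        self.x[mask] += dt * self.v[mask]
        floor = -self.d0 / 2000.0
        hit = self.x < floor
        if np.any(hit):
            self.x[hit] = floor[hit]
            self.v[hit] = 0.0
        self.update_areas()
        # wall volume-velocity sink acting on both traveling waves
        uw = self.surface * self.v * (mask & self.sink)
        dp = 0.5 * self.Z * uw
        self.F -= dp
        self.B -= dp

    def scatter(self):
        """One half-sample scattering + propagation update.

        Returns the new (F, B) arrays with interior junctions resolved;
        boundary entries F[0] and B[-1] are left for the caller.
        """
        F, B, Z = self.F, self.B, self.Z
        U = 2.0 * (F[:-1] - B[1:]) / (Z[:-1] + Z[1:] + self.r_junction)
        Fn = np.empty_like(F)
        Bn = np.empty_like(B)
        Fn[1:] = (B[1:] + Z[1:] * U) * ATTENUATION
        Bn[:-1] = (F[:-1] - Z[:-1] * U) * ATTENUATION
        return Fn, Bn


@dataclass
class AcousticField:
    """Traveling-wave state of a section chain.

    ``forward[i]`` is the forward wave incident at the right edge of section
    i, ``backward[i]`` the backward wave incident at its left edge (Pa).
    """

    forward: np.ndarray
    backward: np.ndarray


def propagate(field: AcousticField, areas_m2, dt_s: float,
              junction_resistance=None) -> AcousticField:
    """One half-sample scattering/propagation update over interior junctions.

    At each junction the scattering conserves pressure and flow (reflection
    coefficient (A_i - A_{i+1})/(A_i + A_{i+1}) for equal-impedance waves),
    optionally through a series resistance.  Boundary entries (forward[0],
    backward[-1]) are carried over unchanged; terminations are the caller's
    responsibility.  ``dt_s`` must be 1/(2 f_s): the wave crosses exactly one
    section per call.
    """
    if not (np.isfinite(field.forward).all() and np.isfinite(field.backward).all()):
        raise FloatingPointError("non-finite acoustic field")
    a = np.asarray(areas_m2, dtype=float)
    if np.any(a <= 0):
        raise ValueError("areas must be > 0 in open regions")
    z = RHO_C / a
    r = np.zeros(len(a) - 1) if junction_resistance is None else \
        np.asarray(junction_resistance, dtype=float)
    f, b = field.forward, field.backward
    u = 2.0 * (f[:-1] - b[1:]) / (z[:-1] + z[1:] + r)
    fn = np.empty_like(f)
    bn = np.empty_like(b)
    fn[0] = f[0]
    bn[-1] = b[-1]
    fn[1:] = b[1:] + z[1:] * u
    bn[:-1] = f[:-1] - z[:-1] * u
    return AcousticField(forward=fn, backward=bn)


def glottal_flow(subglottal_pressure_pa: float, supraglottal_pressure_pa: float,
                 fold_areas_mm2) -> tuple[float, np.ndarray]:
    """Quasi-steady Bernoulli flow and fold surface pressures (static form).

    Returns (flow in L/s, per-section surface pressure in Pa).  The flow is
    driven through the minimum area with full kinetic loss; downstream of the
    separation point (area >= 1.2 x minimum) the wall pressure equals the
    supraglottal input pressure.
    """
    a = np.asarray(fold_areas_mm2, dtype=float) * 1e-6
    p_sub, p_sup = float(subglottal_pressure_pa), float(supraglottal_pressure_pa)
    if np.any(a <= 0):
        k = int(np.argmin(a))
        press = np.where(np.arange(len(a)) <= k, p_sub, p_sup)
        return 0.0, press
    a_min = float(a.min())
    dp = p_sub - p_sup
    q = math.copysign(a_min * math.sqrt(2.0 * abs(dp) / AIR_DENSITY), dp)  # m^3/s
    press = _fold_pressures(a, q, p_sub, p_sup)
    return q * 1e3, press


def _fold_pressures(a: np.ndarray, q: float, p_sub: float, p_sup: float,
                    dqdt: float = 0.0, viscous_drop: float = 0.0) -> np.ndarray:
    """Per-section fold surface pressures for flow q (m^3/s).

    Unsteady Bernoulli along the duct: static pressure at section i is the
    upstream stagnation pressure minus the kinetic head, minus the
    acceleration head of the air column up to i (cumulative inertance x
    dq/dt), minus the accumulated viscous duct loss.  Downstream of the
    separation point the jet pressure equals the supraglottal input
    pressure.
    """
    n = len(a)
    k_min = int(np.argmin(a))
    a_min = a[k_min]
    inert_cum = AIR_DENSITY * FOLD_LENGTH_M * np.cumsum(1.0 / a)
    # viscous loss accumulates ~ with the inverse-area weighting of a
    # fully developed narrow-duct flow
    w = np.cumsum(1.0 / a**2)
    visc_cum = viscous_drop * w / w[-1] if w[-1] > 0 else np.zeros(n)
    press = (p_sub - 0.5 * AIR_DENSITY * (q / a)**2 - inert_cum * dqdt
             - visc_cum * np.sign(q))
    if q >= 0:
        downstream = np.arange(n) > k_min
    else:
        downstream = np.arange(n) < k_min
    separated = downstream & (a >= SEPARATION_RATIO * a_min)
    press[separated] = p_sup
    return press


def simulate(airway: Airway, cfg: SimConfig) -> SimResult:
    """Run the coupled wall/flow/wave simulation and return its time series.

    The subglottal (trachea + transition) and supraglottal (epilarynx +
    tract + tube) airways are wave-propagation chains; the five short fold
    sections between them are an incompressible duct carrying a single
    unsteady flow (quasi-steady Bernoulli + empirical duct loss + air-column
    inertance) that couples the two chains.  Fold surface pressures follow
    the unsteady Bernoulli distribution with flow separation (>= 20%
    divergence) switching separated walls to the supraglottal input
    pressure.
    """
    airway = _apply_config_to_airway(airway, cfg)
    fs = cfg.sampling_rate_hz
    dt = 1.0 / fs
    dt2 = dt / 2.0
    n_samples = int(round(cfg.duration_s * fs))
    ramp_samples = max(int(round(cfg.onset_ramp_ms * 1e-3 * fs)), 1)

    sub_secs = [s for s in airway.sections if s.region in ("trachea", "transition")]
    fold_secs = [airway.sections[i] for i in airway.region_indices("glottis")]
    sup_secs = [s for s in airway.sections
                if s.region in ("epilarynx", "supraglottal", "tube")]
    if not (sub_secs and len(fold_secs) == 5 and sup_secs):
        raise ValueError("airway must contain trachea, five fold sections and "
                         "a supraglottal tract")

    sub = _Chain(sub_secs, dt2)
    sup = _Chain(sup_secs, dt2)

    tube_idx = [i for i, s in enumerate(sup_secs) if s.region == "tube"]
    if tube_idx:
        tube_len_m = sum(s.length_cm for s in sup_secs if s.region == "tube") / 100.0
        tube_diam_m = sup_secs[tube_idx[0]].d_minor_mm / 1000.0
        tube_junctions = [i - 1 for i in tube_idx]
        oral_idx = tube_idx[0] - 1
    else:
        tube_junctions = []
        oral_idx = sup.n - 1

    # fold state
    f_d0 = np.array([s.d_minor_mm for s in fold_secs])
    f_major = np.array([s.d_major_mm for s in fold_secs])
    f_kappa = np.array([stiffness_per_area(s.wall) for s in fold_secs])
    f_mass = np.array([mass_per_area_si(s.wall) for s in fold_secs])
    f_damp = np.array([damping_per_area(s.wall) for s in fold_secs])
    f_ks = np.array([shear_coupling_per_area(s.wall, s.length_cm / 100.0)
                     for s in fold_secs])
    fx = np.zeros(5)
    fv = np.zeros(5)

    # radiation load at the final opening (parallel R-L piston)
    a_end = sup.area[-1]
    rad_r = 128.0 * RHO_C / (9.0 * np.pi**2 * a_end)
    rad_l = AIR_DENSITY * 8.0 * math.sqrt(a_end / np.pi) / (3.0 * np.pi * a_end)
    u_l = 0.0

    lung_z = sub.Z[0]
    r_lung = LUNG_RESISTANCE_FACTOR * lung_z

    q_mean = 0.0  # low-passed tube flow (m^3/s)
    lp_alpha = dt2 / (MEAN_FLOW_TAU + dt2)

    t = np.arange(n_samples) / fs
    out_area = np.zeros(n_samples)
    out_flow = np.zeros(n_samples)
    out_oral = np.zeros(n_samples)
    out_rad = np.zeros(n_samples)
    out_psub = np.zeros(n_samples)
    out_psup = np.zeros(n_samples)
    out_folds = np.zeros((n_samples, 5))
    window = min(max(int(round(cfg.mean_window_s * fs)), 1), n_samples)
    n_total = len(airway.sections)
    sum_area = np.zeros(n_total)
    sum_radius = np.zeros(n_total)
    pre_area = airway.areas_mm2()

    sub_idx = [i for i, s in enumerate(airway.sections)
               if s.region in ("trachea", "transition")]
    fold_idx = airway.region_indices("glottis")
    sup_idx = [i for i, s in enumerate(airway.sections)
               if s.region in ("epilarynx", "supraglottal", "tube")]

    u_g = 0.0       # glottal flow, m^3/s
    u_out_prev = 0.0
    p_end = 0.0

    for n in range(n_samples):
        # onset: half-cosine lung pressure ramp
        if n < ramp_samples:
            p_lung = cfg.lung_pressure_kpa * 1000.0 * 0.5 * (
                1.0 - math.cos(math.pi * n / ramp_samples))
        else:
            p_lung = cfg.lung_pressure_kpa * 1000.0

        d = np.maximum(f_d0 + 2000.0 * fx, 0.0)
        fold_areas = np.pi / 4.0 * f_major * d  # mm^2
        a_min_m2 = float(fold_areas.min()) * 1e-6

        if tube_junctions:
            r_total = tube_flow_resistance(tube_len_m, tube_diam_m,
                                           abs(q_mean) * 1e3,
                                           warn_out_of_range=False) * 1e3
            sup.r_junction[tube_junctions] = r_total / len(tube_junctions)

        for _half in range(2):
            sub_Fn, sub_Bn = sub.scatter()
            sup_Fn, sup_Bn = sup.scatter()

            # lung boundary: pressure source with series resistance
            sub_Fn[0] = ((p_lung - sub.B[0] * (1.0 - r_lung / lung_z))
                         / (1.0 + r_lung / lung_z))

            # glottal coupling between the chain ends: unsteady Bernoulli
            # with the empirical duct loss (kinetic + viscous) and the
            # air-column inertance of the glottal duct
            f_inc = sub.F[-1]
            b_inc = sup.B[0]
            zs = sub.Z[-1]
            ze = sup.Z[0]
            if a_min_m2 <= 1e-12:
                u_g = 0.0
            else:
                areas_m2 = fold_areas * 1e-6
                l_g = AIR_DENSITY * float(np.sum(FOLD_LENGTH_M / areas_m2))
                d_eq = math.sqrt(4.0 * a_min_m2 / math.pi)
                slope = (3.7631e-7 * GLOTTAL_DUCT_LENGTH_M / d_eq**4.4997
                         + 1.0268e-6 / d_eq**4.0416)
                const = (3.9913e-9 * GLOTTAL_DUCT_LENGTH_M / d_eq**5.0089
                         + 8.0169e-7 / d_eq**3.7696)
                kq = slope * 1e6  # Pa per (m^3/s)^2
                bq = zs + ze + l_g / dt2 + const * 1e3
                delta = f_inc - b_inc + 0.5 * l_g / dt2 * u_g
                u_g = math.copysign(
                    (-bq + math.sqrt(bq * bq + 8.0 * kq * abs(delta))) / (2.0 * kq),
                    delta)
            sub_Bn[-1] = (f_inc - zs * u_g) * ATTENUATION
            sup_Fn[0] = (b_inc + ze * u_g) * ATTENUATION

            # radiation boundary at the final opening
            f_end = sup.F[-1]
            z_end = sup.Z[-1]
            denom = 1.0 / z_end + 1.0 / rad_r + dt2 / rad_l
            p_end = (2.0 * f_end / z_end - u_l) / denom
            u_l += dt2 * p_end / rad_l
            sup_Bn[-1] = (p_end - f_end) * ATTENUATION

            sub.F, sub.B = sub_Fn, sub_Bn
            sup.F, sup.B = sup_Fn, sup_Bn

            if tube_junctions:
                j = tube_junctions[0]
                u_tube = (sup.F[j] - sup.B[j]) / sup.Z[j]
                q_mean += lp_alpha * (u_tube - q_mean)

        # pressures at the chain ends for the fold load
        p_sub_node = sub.F[-1] + sub.B[-1]
        p_sup_node = sup.F[0] + sup.B[0]

        # fold surface pressures and wall update
        if a_min_m2 <= 1e-12:
            k = int(np.argmin(fold_areas))
            press = np.where(np.arange(5) <= k, p_sub_node, p_sup_node)
        else:
            d_eq = math.sqrt(4.0 * a_min_m2 / math.pi)
            visc = (3.9913e-9 * GLOTTAL_DUCT_LENGTH_M / d_eq**5.0089
                    + 8.0169e-7 / d_eq**3.7696) * 1e3 * abs(u_g)
            press = _fold_pressures(fold_areas * 1e-6, u_g, p_sub_node,
                                    p_sup_node, viscous_drop=visc)
        shear = np.zeros(5)
        shear[1:] += f_ks[1:] * (fx[:-1] - fx[1:])
        shear[:-1] += f_ks[:-1] * (fx[1:] - fx[:-1])
        force = press - f_kappa * fx + shear
        fv = (fv + dt * force / f_mass) / (1.0 + dt * f_damp / f_mass)
        fx = fx + dt * fv
        floor = -f_d0 / 2000.0
        hit = fx < floor
        if np.any(hit):
            fx[hit] = floor[hit]
            fv[hit] = 0.0

        # airway wall dynamics (slow expansion + vibration)
        sub.step_walls(dt)
        sup.step_walls(dt)

        # record
        out_area[n] = fold_areas.min()
        out_folds[n] = fold_areas
        out_flow[n] = u_g * 1e3
        out_oral[n] = sup.F[oral_idx] + sup.B[oral_idx]
        u_out = p_end / rad_r + u_l
        out_rad[n] = (u_out - u_out_prev) / dt * AIR_DENSITY / (4.0 * np.pi * 0.3)
        u_out_prev = u_out
        out_psub[n] = p_sub_node
        out_psup[n] = p_sup_node

        if n >= n_samples - window:
            d_now = np.maximum(f_d0 + 2000.0 * fx, 0.0)
            sum_area[sub_idx] += sub.area * 1e6
            sum_radius[sub_idx] += sub.d_mm / 2.0
            sum_area[fold_idx] += np.pi / 4.0 * f_major * d_now
            sum_radius[fold_idx] += d_now / 2.0
            sum_area[sup_idx] += sup.area * 1e6
            sum_radius[sup_idx] += sup.d_mm / 2.0

        if n % 2048 == 0 and not (np.isfinite(sub.F).all() and np.isfinite(sup.F).all()
                                  and np.isfinite(fx).all()):
            raise SimulationUnstable(n)

    if not (np.isfinite(out_oral).all() and np.isfinite(out_area).all()):
        raise SimulationUnstable(n_samples)

    return SimResult(
        time_s=t,
        glottal_area_mm2=out_area,
        glottal_flow_l_s=out_flow,
        oral_pressure_pa=out_oral,
        radiated_pressure_pa=out_rad,
        subglottal_pressure_pa=out_psub,
        supraglottal_pressure_pa=out_psup,
        fold_area_mm2=out_folds,
        pre_area_mm2=pre_area,
        mean_area_mm2=sum_area / window,
        mean_radius_mm=sum_radius / window,
        config=cfg,
        airway=airway,
    )

# ---------------------------------------------------------------------------
# signal analysis


class F0NotDetected(RuntimeError):
    """No dominant periodicity found in the analysis segment."""


def estimate_f0(series, fs: float = SAMPLING_RATE,
                f_min: float = 60.0, f_max: float = 1000.0) -> float:
    """Fundamental frequency by normalized autocorrelation with parabolic
    peak refinement.  Raises :class:`F0NotDetected` on aperiodic input."""
    x = np.asarray(series, dtype=float)
    if len(x) < int(0.2 * fs):
        raise ValueError("need at least 0.2 s of signal")
    x = x - x.mean()
    if np.max(np.abs(x)) < 1e-12:
        raise F0NotDetected("constant signal")
    nfft = int(2 ** np.ceil(np.log2(2 * len(x))))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[: len(x)]
    ac /= ac[0]
    lag_min = max(int(fs / f_max), 2)
    lag_max = min(int(fs / f_min), len(ac) - 2)
    if lag_max <= lag_min:
        raise F0NotDetected("segment too short for the search range")
    seg = ac[lag_min:lag_max]
    k = int(np.argmax(seg)) + lag_min
    if ac[k] < 0.4:
        raise F0NotDetected(f"max autocorrelation {ac[k]:.2f} below threshold")
    # genuine periodicity dips between correlation peaks; slow drift keeps
    # the autocorrelation high at every lag and must not be reported as f0
    if np.min(ac[lag_min:k + 1]) > 0.3:
        raise F0NotDetected("no correlation trough before the peak (aperiodic "
                            "or drifting signal)")
    # parabolic interpolation around the peak
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-30 else 0.0
    return float(fs / (k + delta))


@dataclass
class Spectrum:
    frequency_hz: np.ndarray
    magnitude_db: np.ndarray  # re maximum
    power: np.ndarray         # linear, arbitrary units


def spectrum(series, fs: float = SAMPLING_RATE) -> Spectrum:
    """Hann-windowed magnitude spectrum of a (steady) segment, in dB re max."""
    x = np.asarray(series, dtype=float)
    if len(x) < int(0.2 * fs):
        raise ValueError("need at least 0.2 s of signal")
    x = x - x.mean()
    w = np.hanning(len(x))
    spec = np.fft.rfft(x * w)
    power = np.abs(spec) ** 2
    ref = power.max()
    if ref <= 0:
        db = np.full_like(power, -200.0)
    else:
        db = 10.0 * np.log10(np.maximum(power / ref, 1e-20))
    f = np.fft.rfftfreq(len(x), 1.0 / fs)
    return Spectrum(frequency_hz=f, magnitude_db=db, power=power)


def band_energy(spec: Spectrum, f_lo: float, f_hi: float) -> float:
    """Integrated band magnitude in dB (re the spectrum's reference)."""
    if not f_lo < f_hi:
        raise ValueError("f_lo must be < f_hi")
    m = (spec.frequency_hz >= f_lo) & (spec.frequency_hz <= f_hi)
    if not np.any(m):
        raise ValueError("empty frequency band")
    total = spec.power[m].sum()
    ref = spec.power.max()
    if total <= 0 or ref <= 0:
        return -200.0
    return float(10.0 * np.log10(total / ref))


def write_wav(path, series, fs: float = SAMPLING_RATE) -> None:
    """Export a signal as 32-bit float RIFF/WAV."""
    from scipy.io import wavfile

    x = np.asarray(series, dtype=np.float32)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * 0.9
    wavfile.write(path, int(fs), x)
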