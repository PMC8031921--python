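# Methods

## The model

The package simulates human phonation with a semi-occluded vocal tract
(SOVT): voicing into a narrow flow-resistant tube held at the lips, the
computational analogue of straw phonation exercises.  The airway —
trachea, glottis, epilaryngeal tube, pharynx/mouth, lip tube — is a chain
of short tube sections (circular, or elliptical near the glottis), each
backed by a yielding viscoelastic wall.  The same geometry feeds three
solvers:

1. **Steady aerodynamics** (`sovt.steady`): a series flow network.
   Tube-like segments use an empirical flow-resistance law calibrated on
   bench measurements of tubes 3–24 cm long and 1.8–9.7 mm in bore,

   R = (3.7631·10⁻⁷ L/D^4.4997 + 1.0268·10⁻⁶/D^4.0416) Q
     + (3.9913·10⁻⁹ L/D^5.0089 + 8.0169·10⁻⁷/D^3.7696),

   with L, D in m, Q in L/s and R in Pa·s/L; the glottis is a Bernoulli
   orifice with full kinetic loss (k_t = 1).  `solve_steady_network` finds
   the flow at which the summed drops equal the lung pressure and assigns
   every section its mean pressure.

2. **Frequency-domain acoustics** (`sovt.acoustics`): chained 2×2
   transmission-line matrices per section, with series viscous
   boundary-layer resistance and a yielding-wall shunt branch, terminated
   by a lumped piston radiation load (R = 128ρc/9π²A in parallel with the
   0.85a end-correction inertance) at the lips and a resistive–inertive
   load at the tracheal bifurcation.  The input impedance Z = R + iX is
   converted to an inertagram I(f) = X/2πf (positive where inertive;
   subglottal compliant bands entered below the zero line), and the first
   resonance F1 is the first downward zero crossing of X above 20 Hz.

3. **Time-domain synthesis** (`sovt.simulate`): a wave-reflection
   (Kelly–Lochbaum) analog at f_s = 44.1 kHz.  The section length
   0.3968 cm equals c/2f_s with c = 350 m/s, so a traveling wave crosses
   one section per half sample; scattering at each junction conserves
   pressure and flow, optionally through a series resistance.  Air density
   is ρ = 1.14 kg/m³ (warm humid air).

## Walls

Each wall is a per-unit-area oscillator m·ẍ + c·ẋ + κx − κ_s∇²x = P with
κ = E/d_eff, c = 2ζ√(κm), and axial shear coupling
κ_s = G·d_eff/Δz² between adjacent sections of the same region.  Airway
walls use E = 9.62 kPa, G = 1.67 kPa, m = 1.5 g/cm², ζ = 1.26
(overdamped); fold sections use E = 4 kPa, G = 1 kPa, m = 0.3 g/cm² with
ζ = 0.2 on the lower three and 0.6 on the upper two sections.  The
effective depths are fixed once: 0.2 cm for the folds, which makes the
fold natural frequency (1/2π)√(κ/m) = 130 Hz exactly as the tissue
constants require, and 1.0 cm for all other walls, which makes a 2.5 kPa
tracheal pressure expand the tracheal cross-section by ≈66%, the right
order for passive airway widening.  Integration is semi-implicit Euler at
the audio rate with a displacement floor at lumen closure (velocity zeroed
on contact).  Pitch is set by a single factor that multiplies the fold
moduli and divides the fold surface mass, scaling the natural frequency
linearly; the reference configuration uses 300/130 ≈ 2.31.

## The glottal source

The five fold sections (1.6 mm each, elliptical with a fixed 10 mm major
axis) form an incompressible duct carrying one unsteady flow that couples
the subglottal and supraglottal wave chains.  The flow solve combines the
incident wave pressures and chain characteristic impedances with (a) the
kinetic loss at the minimum area, (b) the empirical duct loss of the
narrow-tube law applied to the 0.8 cm glottal duct at its instantaneous
equivalent bore, and (c) the air-column inertance ρΣ(l_i/A_i), integrated
implicitly.  Fold surface pressures follow the Bernoulli distribution
referenced to the subglottal stagnation pressure, with the duct's viscous
loss accumulated along the duct (weighted by 1/A²); where the duct
diverges by ≥20% above the minimum, the flow separates and the downstream
walls carry the supraglottal input pressure instead.  The default
pre-phonatory posture is medially bulged (interior sections at 70% of the
linear entry→exit contour, entry 4.7 mm², exit 6.3 mm²): near-rectangular
or slightly bulged postures are the ones that sustain oscillation, and
the bulge provides the alternating convergent/divergent geometry the
energy-transfer mechanism needs.

The lip tube is rigid; its empirical flow resistance, evaluated at the
low-pass-filtered (10 ms) mean flow, is distributed across its junctions
as series scattering resistances, so the mean-flow pressure drop and the
acoustic damping of the tube come from one law without double counting.
The lungs are a pressure source behind 0.2× the tracheal characteristic
impedance (a partially absorbing termination); lung pressure ramps over
50 ms (half cosine) and the first 200 ms are excluded from analysis
windows.  There are no noise sources: runs are bit-identical.

## What the experiments show — and a known limitation

With an open mouth at 2.5 kPa the model self-oscillates at ≈290–310 Hz
(fold natural frequency 300 Hz) with a closure-reaching glottal area
waveform — the classic behaviour of multi-mass fold models.

With the 3 mm lip tube the oral pressure builds to ≈1.9 kPa and the whole
airway widens passively (trachea +65%, pharyngeal entry +65%, epilarynx
exit +223%, fold entry +162%), but the simulation converges to a stable
inflated state instead of sustaining oscillation.  Energy audits with
prescribed fold motion show why: the published fold constants fix the
fold compliance at κ ≈ 4.6 MPa/m (reference pitch), so the built-up
pressures spread the folds to ≈11–13 mm² where the glottis is nearly
transparent to the flow; the aerodynamic work available per cycle is then
5–30% of the fold damping loss for every phasing, amplitude (including
collision) and frequency tested, whereas the open-mouth case reaches
≈80% and oscillates.  The reference study reports sustained oscillation
under these conditions; reproducing it evidently requires either an
additional driving mechanism or an effectively stiffer static fold
response than the printed constants imply.  Consequently the packaged
acceptance checks that depend on the oscillating semi-occluded state (its
fundamental frequency, the 3–4 kHz band-energy contrast between free and
stiffened epilarynx, and the two landmark expansions most sensitive to
the mean oral pressure) fail honestly, and the failure is documented
rather than masked.  All purely static, aerodynamic and acoustic results
— the expansion ordering across tube bores, the quasi-static oracle
agreement, the resistance curves, the inertagrams and F1 shifts — do not
depend on the oscillation and reproduce as expected.

## Numerical and design choices

- **Quasi-static oracle**: `walls.quasi_static_equilibrium` iterates the
  steady-network solve and the linear wall expansion (lip tube held
  rigid) to a fixed point; the time-domain mean radii agree with it to
  within 8% for all non-fold, non-tube sections.
- **Acoustic wall-loss**: the shunt branch uses half the wall ODE's
  damping constant (`WALL_SHUNT_DAMPING_SCALE = 0.5`).  The full
  time-domain value, which is deliberately overdamped to keep airway
  walls from self-oscillating, suppresses the wall–cavity resonance and
  erases the low first resonance of narrow-pharynx semi-occluded shapes.
- **Bifurcation termination**: R = 0.3ρc/A plus a 60 Pa·s²/m³ inertance,
  placing the deepest subglottal compliant reactance near 680 Hz.
- **Frequency grid**: 10 Hz–5 kHz in 2 Hz steps; F1 is refined below the
  grid step by linear interpolation of the reactance zero crossing.
- **Vowel-shape generator**: parametric stand-ins, not imaging data: wide
  pharynx 22 mm bore with a 10 mm mouth (/i/-like) vs narrow pharynx
  11 mm with a 25 mm mouth (/ɑ/-like), 4-section linear ramps between
  plateaus, identical subglottal template and epilarynx.  Only the
  qualitative F1/inertance contrasts of these shapes are meaningful.
- **Oral cavity of the model airway**: constant 25 mm bore (configurable);
  the reference only constrains it graphically.
- **Mean "post" state**: time averages over the final 100 ms of a run.
- **f0 estimation**: normalized autocorrelation over the final steady
  segment with parabolic peak refinement; a detection additionally
  requires a correlation trough before the peak so that slow drift is
  never reported as periodicity.
- **Problem sizes**: analyses use 0.5–1.0 s of simulated audio at
  44.1 kHz (the expansion state converges within ≈0.3 s; wall time a few
  seconds per simulated second).

## What the synthetic geometry does and does not emulate

The generator reproduces the landmark cross-sections, section counts and
lengths of the reference male airway and qualitative vowel contrasts.  It
does not represent 3D curvature, the piriform sinuses ("tube within a
tube" geometry), nasal acoustics (velum closed throughout), vertical
laryngeal motion, muscle activation, or nonlinear wall stiffening at
high pressure — so passing tests validate the 1D aero-acoustic chain, not
anatomical fidelity.
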