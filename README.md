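# sovt — phonation with semi-occluded vocal tracts

`sovt` is a computational model of human voice production aimed at the
physics of **semi-occluded vocal tract (SOVT) exercises** — phonating
through a narrow straw-like tube at the lips.  It is written for voice
scientists and speech-acoustics researchers who want a tested, scriptable
implementation of the full chain:

- a **sectioned airway** (trachea → five elliptical vocal-fold sections →
  epilaryngeal tube → pharynx/mouth → lip tube), every section backed by a
  yielding viscoelastic wall (per-area dynamics
  m·ẍ + c·ẋ + κx − κ_s∇²x = P, κ = E/d_eff);
- **steady aerodynamics**: the empirical narrow-tube resistance
  R(Q) = (3.7631·10⁻⁷L/D^4.4997 + 1.0268·10⁻⁶/D^4.0416)Q +
  (3.9913·10⁻⁹L/D^5.0089 + 8.0169·10⁻⁷/D^3.7696) in Pa·s/L, a Bernoulli
  glottal orifice, and a series network solve for the mean pressures;
- **frequency-domain acoustics**: chained 2×2 transmission-line sections
  with wall shunts, radiation and subglottal terminations, giving the
  input impedance Z = R + iX and its *inertagram* I = X/2πf, from which
  the first resonance F1 is read;
- **time-domain synthesis**: a wave-reflection (Kelly–Lochbaum) analog at
  44.1 kHz (section length c/2f_s = 0.3968 cm, c = 350 m/s) coupled to a
  self-oscillating five-section vocal-fold source with flow separation at
  ≥20% divergence.

The central scientific question is how a high-resistance oral
semi-occlusion reshapes the airway (passive widening under the built-up
intraoral pressure) and the source–filter interaction (impedance matching
by the narrow epilaryngeal tube).

## Worked example

Solve the steady series network for the reference airway (2.5 kPa lung
pressure, 3 mm × 10 cm lip tube):

```python
>>> from sovt import build_model_airway, solve_steady_network
>>> sol = solve_steady_network(build_model_airway(), 2.5)
>>> round(sol.flow_l_s, 3), round(sol.oral_pressure_kpa, 2)
(0.163, 1.36)
>>> {k: round(v) for k, v in sol.resistances.items()}
{'R_t': 6, 'R_g': 6269, 'R_e': 749, 'R_L': 8312}
```

The mean flow is 0.163 L/s; the lip tube (`R_L`, 8312 Pa·s/L) and the
glottis (`R_g`) dominate the network, and the tube's drop leaves 1.36 kPa
of steady pressure in the mouth — the pressure that pushes the airway
walls outward.  Compare the first acoustic resonance of a wide-pharynx
vowel shape with and without the tube:

```python
>>> from sovt import build_vowel_airway, supraglottal_impedance, \
...     make_inertagram, detect_f1, TubeSpec
>>> f1 = lambda t: detect_f1(make_inertagram(supraglottal_impedance(
...     build_vowel_airway("wide", 0.2, t))))
>>> round(f1(None)), round(f1(TubeSpec(0.08, 0.003)))
(404, 252)
```

Attaching the 3 mm × 8 cm tube lowers F1 from 404 Hz to 252 Hz: the tube
turns the tract into a Helmholtz-like resonator and extends the
inertive (positive-reactance) band downward, the regime in which the
supraglottal air column assists vocal-fold vibration.

## Analysis pipeline

Numbered drivers under `analysis/` reproduce the study end to end and
write their tables under `results/`:

| script | what it does |
| --- | --- |
| `01_build_geometry.py` | builds and exports all airway area functions |
| `02_steady_resistances.py` | resistance curves + network operating point |
| `03_inertagrams.py` | four vowel-shape inertagrams and the F1 table |
| `04_expansion.py` | airway expansion for 3/4/5/6 mm lip tubes |
| `05_epilarynx_control.py` | free vs stiffened epilaryngeal wall |

Each run writes a JSON manifest of its fully resolved configuration;
reruns are bit-identical.

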