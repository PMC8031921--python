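#!/usr/bin/env python
"""Steady flow-resistance curves and the series network operating point.

Tabulates the empirical tube resistance for the lip tube and for
epilaryngeal conduits of several diameters, plus Bernoulli orifice curves
for three glottal adduction levels, then solves the full series network
(trachea - glottis - epilarynx - tube) at the reference lung pressure.
"""

import argparse
from pathlib import Path

import numpy as np

from sovt.geometry import TubeSpec, build_model_airway
from sovt.steady import resistance_curves, solve_steady_network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--lung-pressure-kpa", type=float, default=2.5)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    grid = np.round(np.linspace(0.05, 0.45, 41), 4)
    specs = [
        ("lip tube 3 mm x 8 cm", TubeSpec(0.08, 0.003)),
        ("epilarynx 5 mm x 2.5 cm", TubeSpec(0.025, 0.005)),
        ("epilarynx 8 mm x 2.5 cm", TubeSpec(0.025, 0.008)),
        ("glottis 5 mm^2", 5.0),
        ("glottis 10 mm^2", 10.0),
        ("glottis 20 mm^2", 20.0),
    ]
    curves = resistance_curves(specs, grid)
    path = args.out / "resistance_curves.tsv"
    curves.to_csv(path, sep="\t", index=False)
    print(f"wrote {path} ({len(curves)} rows)")

    at = curves[np.isclose(curves.flow_L_s, 0.2)]
    for _, row in at.iterrows():
        print(f"  R({row.label}) at 0.2 L/s = {row.resistance_Pa_s_L:,.0f} Pa s/L")

    airway = build_model_airway()
    sol = solve_steady_network(airway, args.lung_pressure_kpa)
    print(f"series network at {args.lung_pressure_kpa} kPa: "
          f"Q = {sol.flow_l_s:.3f} L/s, oral pressure = "
          f"{sol.oral_pressure_kpa:.2f} kPa")
    print("  component resistances (Pa s/L):",
          {k: round(v) for k, v in sol.resistances.items()})


if __name__ == "__main__":
    main()
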