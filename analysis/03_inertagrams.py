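#!/usr/bin/env python
"""Inertagrams of vowel-like airways with and without an oral semi-occlusion.

Computes the supraglottal and subglottal input impedances of the wide- and
narrow-pharynx shapes (both with the 0.2 cm^2 x 2.5 cm epilarynx), with and
without a 3 mm x 8 cm lip tube, converts them to inertagrams, and reports
the first resonance F1 and the mean 3--4 kHz inertance.
"""

import argparse
import json
from pathlib import Path

from sovt.experiments import run_inertagram_experiment, write_inertagram_tsv
from sovt.geometry import TubeSpec


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/inertagrams"))
    ap.add_argument("--epilarynx-area-cm2", type=float, default=0.2)
    ap.add_argument("--tube-diameter-mm", type=float, default=3.0)
    ap.add_argument("--tube-length-cm", type=float, default=8.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tube = TubeSpec(args.tube_length_cm / 100.0, args.tube_diameter_mm / 1000.0)
    out = run_inertagram_experiment(args.epilarynx_area_cm2, tube)

    table = {}
    for (pharynx, occlusion), v in out.items():
        name = f"{pharynx}_{occlusion}"
        write_inertagram_tsv(args.out / f"{name}.tsv", v["inertagram"])
        table[name] = {"F1_Hz": round(v["f1_hz"], 1),
                       "mean_inertance_3_4kHz": round(v["band_inertance_3_4k"], 1)}
        print(f"{name:>14}: F1 = {v['f1_hz']:6.1f} Hz, "
              f"I(3-4 kHz) = {v['band_inertance_3_4k']:8.1f} Pa s^2/m^3")
    with open(args.out / "f1_table.json", "w") as fh:
        json.dump(table, fh, indent=2)
    print(f"wrote {args.out}/f1_table.json")


if __name__ == "__main__":
    main()
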