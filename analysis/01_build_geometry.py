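#!/usr/bin/env python
"""Build the reference airway geometries and export their area functions.

Writes the model airway (36 tracheal + 2 transition + 5 glottal + 44
supraglottal sections, with and without the 3 mm x 10 cm lip tube) and the
four vowel-like shapes used by the inertagram analysis, as tab-separated
area-function files under the output directory.
"""

import argparse
from pathlib import Path

from sovt.geometry import (
    TubeSpec,
    build_model_airway,
    build_vowel_airway,
    write_area_function,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/geometry"))
    ap.add_argument("--tube-diameter-mm", type=float, default=3.0)
    ap.add_argument("--tube-length-cm", type=float, default=10.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tube = TubeSpec(args.tube_length_cm / 100.0, args.tube_diameter_mm / 1000.0)
    airways = {
        "model": build_model_airway(tube=None),
        "model_with_tube": build_model_airway(tube=tube),
        "vowel_wide": build_vowel_airway("wide", 0.2, None),
        "vowel_wide_tube": build_vowel_airway("wide", 0.2, TubeSpec(0.08, 0.003)),
        "vowel_narrow": build_vowel_airway("narrow", 0.2, None),
        "vowel_narrow_tube": build_vowel_airway("narrow", 0.2, TubeSpec(0.08, 0.003)),
    }
    for name, airway in airways.items():
        path = args.out / f"{name}.tsv"
        write_area_function(airway, path)
        total = sum(s.length_cm for s in airway.sections)
        print(f"{name}: {len(airway)} sections, {total:.1f} cm -> {path}")


if __name__ == "__main__":
    main()
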