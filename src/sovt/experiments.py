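"""End-to-end experiments: airway expansion, epilarynx control, inertagrams.

Each experiment builds its airway from the packaged reference geometry, runs
the corresponding computation (time-domain simulation or frequency-domain
impedance analysis), and returns small report objects that the analysis
scripts serialize.  Every run is deterministic; a reproducibility manifest
(the fully resolved configuration) accompanies each report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .acoustics import (
    Inertagram,
    detect_f1,
    make_inertagram,
    mean_band_inertance,
    subglottal_impedance,
    supraglottal_impedance,
)
from .geometry import Airway, TubeSpec, build_model_airway, build_vowel_airway
from .simulate import SimConfig, SimResult, band_energy, simulate, spectrum

#: Landmarks reported in the expansion tables, with the tracheal mid section
#: standing in for the subglottal landmark.
REPORT_LANDMARKS = (
    "subglottal", "pharyngeal_entry", "epilarynx_exit", "epilarynx_entry",
    "glottal_exit", "glottal_entry",
)


@dataclass
class ExpansionReport:
    """Pre/post landmark areas of one simulation run."""

    tube_diameter_mm: float | None
    lung_pressure_kpa: float
    stiffen_epilarynx_kpa: float | None
    pre_area_mm2: dict[str, float]
    post_area_mm2: dict[str, float]
    percent_change: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.percent_change:
            self.percent_change = {
                k: percent_change(self.pre_area_mm2[k], self.post_area_mm2[k])
                for k in self.pre_area_mm2
            }

    def table(self) -> pd.DataFrame:
        rows = [(k, self.pre_area_mm2[k], self.post_area_mm2[k],
                 round(self.percent_change[k]))
                for k in self.pre_area_mm2]
        return pd.DataFrame(rows, columns=["landmark", "pre_mm2", "post_mm2",
                                           "pct_change"])


def percent_change(pre: float, post: float) -> float:
    """100 (post - pre) / pre; the reference value must be positive."""
    if not pre > 0:
        raise ValueError("pre value must be > 0")
    return 100.0 * (post - pre) / pre


def _landmark_indices(airway: Airway) -> dict[str, int]:
    marks = dict(airway.landmarks)
    trachea = airway.region_indices("trachea")
    out = {"subglottal": trachea[len(trachea) // 2]}
    for k in REPORT_LANDMARKS:
        if k in marks:
            out[k] = marks[k]
    return out


def expansion_report(result: SimResult) -> ExpansionReport:
    """Landmark pre/post areas of a finished run (post = final-window mean)."""
    idx = _landmark_indices(result.airway)
    cfg = result.config
    return ExpansionReport(
        tube_diameter_mm=cfg.tube.diameter_m * 1000.0 if cfg.tube else None,
        lung_pressure_kpa=cfg.lung_pressure_kpa,
        stiffen_epilarynx_kpa=cfg.epilarynx_stiffen_kpa,
        pre_area_mm2={k: float(result.pre_area_mm2[i]) for k, i in idx.items()},
        post_area_mm2={k: float(result.mean_area_mm2[i]) for k, i in idx.items()},
    )


def run_expansion_experiment(
    tube_diameters_mm=(3.0, 4.0, 5.0, 6.0),
    lung_pressure_kpa: float = 2.5,
    tube_length_cm: float = 10.0,
    duration_s: float = 1.0,
) -> tuple[list[ExpansionReport], pd.DataFrame, list[SimResult]]:
    """One full simulation per lip-tube diameter.

    Returns the per-run landmark reports, a table of the five fold minor
    diameters (pre and post) per tube diameter, and the raw results.
    """
    airway = build_model_airway(tube=None)
    reports, results, rows = [], [], []
    for d_mm in tube_diameters_mm:
        cfg = SimConfig(lung_pressure_kpa=lung_pressure_kpa,
                        duration_s=duration_s,
                        tube=TubeSpec(tube_length_cm / 100.0, d_mm / 1000.0))
        res = simulate(airway, cfg)
        reports.append(expansion_report(res))
        results.append(res)
        glottis = res.airway.region_indices("glottis")
        for k, i in enumerate(glottis):
            pre_d = res.airway.sections[i].d_minor_mm
            post_d = 2.0 * res.mean_radius_mm[i]
            rows.append((d_mm, k, pre_d, post_d))
    profile = pd.DataFrame(rows, columns=["tube_diameter_mm", "fold_section",
                                          "pre_minor_mm", "post_minor_mm"])
    return reports, profile, results


def run_epilarynx_control_experiment(
    lung_pressure_kpa: float = 2.5,
    stiffen_kpa: float = 100.0,
    duration_s: float = 1.0,
    band=(3000.0, 4000.0),
) -> dict:
    """Free vs stiffened epilarynx: paired runs and their 3--4 kHz contrast.

    Stiffening the epilaryngeal wall (100 kPa Young's modulus, standing in
    for aryepiglottic muscle action) prevents its passive expansion while the
    rest of the airway still widens.
    """
    airway = build_model_airway(tube=None)
    out = {}
    for label, stiff in (("free", None), ("stiffened", stiffen_kpa)):
        cfg = SimConfig(lung_pressure_kpa=lung_pressure_kpa,
                        duration_s=duration_s, epilarynx_stiffen_kpa=stiff)
        res = simulate(airway, cfg)
        fs = res.sampling_rate_hz
        tail = res.oral_pressure_pa[int(0.25 * len(res.oral_pressure_pa)):]
        spec = spectrum(tail, fs)
        out[label] = {
            "result": res,
            "report": expansion_report(res),
            "oral_spectrum": spec,
            "band_energy_db": band_energy(spec, *band),
        }
    out["band_energy_difference_db"] = (
        out["stiffened"]["band_energy_db"] - out["free"]["band_energy_db"])
    return out


def run_inertagram_experiment(
    epilarynx_area_cm2: float = 0.2,
    tube: TubeSpec = TubeSpec(0.08, 0.003),
) -> dict[tuple[str, str], dict]:
    """Inertagrams and first resonances for {wide, narrow} x {none, tube}.

    All four supraglottal shapes share the same narrow epilarynx and
    subglottal template; only the pharyngeal/oral configuration and the
    presence of the lip tube differ.
    """
    out = {}
    for pharynx in ("wide", "narrow"):
        for label, t in (("none", None), ("tube", tube)):
            airway = build_vowel_airway(pharynx, epilarynx_area_cm2, t)
            sup = supraglottal_impedance(airway)
            sub = subglottal_impedance(airway)
            ig = make_inertagram(sup, sub)
            out[(pharynx, label)] = {
                "airway": airway,
                "inertagram": ig,
                "f1_hz": detect_f1(ig),
                "band_inertance_3_4k": mean_band_inertance(ig, 3000.0, 4000.0),
            }
    return out


# ---------------------------------------------------------------------------
# serialization helpers


def manifest(cfg: SimConfig) -> dict:
    """Fully resolved run configuration for reproducibility."""
    d = dataclasses.asdict(cfg)
    if cfg.tube is not None:
        d["tube"] = {"length_m": cfg.tube.length_m, "diameter_m": cfg.tube.diameter_m}
    d["package_version"] = __version__
    return d


def write_report_json(path, reports: list[ExpansionReport]) -> None:
    payload = [dataclasses.asdict(r) for r in reports]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_inertagram_tsv(path, inertagram: Inertagram) -> None:
    df = pd.DataFrame({
        "frequency_Hz": inertagram.frequency_hz,
        "I": inertagram.inertance,
        "I_subglottal": inertagram.subglottal_inertance,
    })
    df.to_csv(path, sep="\t", index=False)
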