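"""Grade presets: distributions behind the synthetic mechanics and histology.

The preset library is a versioned YAML file shipped with the package.  Each
rejection grade (A0 native, A0 isograft, A1, A2, A3) carries

* a tissue-fraction target distribution (mean, SD of the per-animal TF),
* lung-level mechanics distributions (peripheral airway resistance,
  inter-compartment heterogeneity CV, closing-pressure distribution),
* a histology morphology recipe (alveolar cell count, vessel and infiltrate
  counts and sizes).

Mechanics and histology share the per-animal tissue fraction: tissue damping
and elastance scale as ``(TF / tf_ref) ** beta``, which makes log dynamic
elastance approximately linear in TF across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["HistologyPreset", "GradePreset", "PresetLibrary", "load_presets", "GRADE_LABELS"]

GRADE_LABELS = ("A0_native", "A0_iso", "A1", "A2", "A3")


@dataclass(frozen=True)
class HistologyPreset:
    """Morphology recipe for one grade's synthetic micrographs."""

    n_cells: int
    n_vessels: tuple
    vessel_r: tuple
    n_infiltrates: tuple
    infiltrate_r0: tuple
    n_consolidations: tuple = (0, 0)
    consolidation_r0: tuple = (0, 0)


@dataclass(frozen=True)
class GradePreset:
    label: str
    grade: int                      # ordinal A-grade, A0 -> 0 ... A3 -> 3
    tf_mean: float                  # per-animal tissue-fraction target, fraction
    tf_sd: float
    raw_lung_mean: float            # lung-level peripheral Raw, all open, cmH2O.s/mL
    raw_lung_sd: float
    het_cv: float                   # inter-compartment CV of Raw, G, H
    tf_shrink: float                # within-group attenuation of the TF coupling
    pc_mean: float                  # closing pressure, cmH2O
    pc_sd: float
    pc_max: float | None            # optional upper clip (A0: always open)
    histology: HistologyPreset


@dataclass(frozen=True)
class PresetLibrary:
    version: int
    tf_ref: float                   # reference TF of the coupling law
    beta: float                     # TF -> tissue-constant coupling exponent
    n_compartments: int
    h_lung_ref: float               # A0 all-open lung tissue elastance scale
    eta_mean: float
    eta_sd: float
    rc_mean: float
    rc_sd: float
    ic_mean: float
    ic_sd: float
    raw_peep_slope: float
    raw_peep_cap: float
    h_peep_slope: float
    grades: Mapping[str, GradePreset] = field(default_factory=dict)

    def __post_init__(self):
        # monotone severity: TF targets, heterogeneity and closing pressures
        # must not decrease from A0 to A3.
        order = [g for g in GRADE_LABELS if g in self.grades]
        for key in ("tf_mean", "het_cv", "pc_mean"):
            vals = [getattr(self.grades[g], key) for g in order]
            if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
                raise ValueError(f"preset invariant violated: {key} must be non-decreasing across grades, got {vals}")


def _pair(x) -> tuple:
    a, b = x
    return (a, b)


def load_presets(path: "str | Path | None" = None) -> PresetLibrary:
    """Load a preset library from YAML (default: the packaged presets)."""
    if path is None:
        text = resources.files("lungfot.data").joinpath("default_presets.yaml").read_text()
    else:
        text = Path(path).read_text()
    d = yaml.safe_load(text)
    common = d["mechanics_common"]
    grades = {}
    for label, g in d["grades"].items():
        mech = g["mechanics"]
        hist = g["histology"]
        grades[label] = GradePreset(
            label=label,
            grade=int(g["grade"]),
            tf_mean=float(g["tf"]["mean"]),
            tf_sd=float(g["tf"]["sd"]),
            raw_lung_mean=float(mech["raw_lung"]["mean"]),
            raw_lung_sd=float(mech["raw_lung"]["sd"]),
            het_cv=float(mech["het_cv"]),
            tf_shrink=float(mech.get("tf_shrink", 1.0)),
            pc_mean=float(mech["pc"]["mean"]),
            pc_sd=float(mech["pc"]["sd"]),
            pc_max=float(mech["pc"]["max"]) if "max" in mech["pc"] else None,
            histology=HistologyPreset(
                n_cells=int(hist["n_cells"]),
                n_vessels=_pair(hist["n_vessels"]),
                vessel_r=_pair(hist["vessel_r"]),
                n_infiltrates=_pair(hist["n_infiltrates"]),
                infiltrate_r0=_pair(hist["infiltrate_r0"]),
                n_consolidations=_pair(hist.get("n_consolidations", (0, 0))),
                consolidation_r0=_pair(hist.get("consolidation_r0", (0, 0))),
            ),
        )
    return PresetLibrary(
        version=int(d["version"]),
        tf_ref=float(d["tf_ref"]),
        beta=float(d["beta"]),
        n_compartments=int(common["n_compartments"]),
        h_lung_ref=float(common["h_lung_ref"]),
        eta_mean=float(common["eta_mean"]),
        eta_sd=float(common["eta_sd"]),
        rc_mean=float(common["rc_mean"]),
        rc_sd=float(common["rc_sd"]),
        ic_mean=float(common["ic_mean"]),
        ic_sd=float(common["ic_sd"]),
        raw_peep_slope=float(common["raw_peep_slope"]),
        raw_peep_cap=float(common["raw_peep_cap"]),
        h_peep_slope=float(common["h_peep_slope"]),
        grades=grades,
    )
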