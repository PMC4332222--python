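"""Shared fixtures: the default protocol and a fully analysed synthetic cohort.

The session-scoped cohort (fixed seed) is generated once and reused by the
property and acceptance tests: mechanics records for every animal at five
PEEP levels, estimated impedance spectra reduced to scalar indices, one
synthetic micrograph per animal measured by the morphometry pipeline.
"""

import numpy as np
import pandas as pd
import pytest

from lungfot.histology import generate_histology
from lungfot.impedance import estimate_impedance, to_mechanics
from lungfot.indices import extract_indices, indices_frame
from lungfot.morphometry import measure_animal, tf_frame
from lungfot.presets import load_presets
from lungfot.protocol import build_protocol
from lungfot.simulate import generate_cohort

COHORT_SEED = 0


@pytest.fixture(scope="session")
def default_protocol():
    return build_protocol()


@pytest.fixture(scope="session")
def preset_library():
    return load_presets()


@pytest.fixture(scope="session")
def cohort(preset_library):
    return generate_cohort(library=preset_library, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_indices(cohort, default_protocol):
    """Tidy index table: one row per (animal, PEEP), with grade metadata."""
    sets = [
        extract_indices(
            to_mechanics(estimate_impedance(rec, default_protocol)),
            grade_label=rec.grade_label,
        )
        for rec in cohort.records
    ]
    df = indices_frame(sets)
    return df.merge(
        cohort.metadata[["animal_id", "group", "grade", "tf_target"]], on="animal_id"
    )


@pytest.fixture(scope="session")
def cohort_histology(cohort, preset_library):
    """One micrograph per animal (the animal's own TF target) plus
    morphometry measurements: 15 random 256-px regions, Otsu threshold."""
    root = np.random.SeedSequence(COHORT_SEED)
    images = {}
    results = []
    for _, row in cohort.metadata.iterrows():
        gp = preset_library.grades[row["group"]]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(int(row["animal_index"]), 999))
        )
        img = generate_histology(gp, rng, tf_target=row["tf_target"])
        images[row["animal_id"]] = img
        results.append(measure_animal([img], animal_id=row["animal_id"], rng=rng))
    tf_df = tf_frame(results, groups=dict(zip(cohort.metadata["animal_id"], cohort.metadata["group"])))
    tf_df["tf_truth"] = tf_df["animal_id"].map({k: v.tf_truth for k, v in images.items()})
    return {"images": images, "tf": tf_df}


@pytest.fixture(scope="session")
def cohort_merged(cohort_indices, cohort_histology):
    """Per-animal table at PEEP 4: indices joined with measured TF."""
    at4 = cohort_indices[cohort_indices["peep_cmh2o"] == 4.0]
    return at4.merge(cohort_histology["tf"], on=["animal_id", "group"])
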