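"""End-to-end orchestration: simulate -> estimate -> indices -> histology ->
morphometry -> statistics -> report.

A run is fully determined by a :class:`RunConfig` (master seed included);
re-running the same config into the same directory is detected via the
manifest and skipped unless forced.  All randomness is derived
hierarchically from the master seed, so outputs are bit-identical across
re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .histology import generate_histology, write_image
from .impedance import estimate_impedance, to_mechanics
from .indices import extract_indices, indices_frame
from .morphometry import measure_animal, tf_frame
from .presets import load_presets
from .protocol import build_protocol
from .simulate import CohortDesign, DEFAULT_GROUP_SIZES, generate_cohort, write_record_csv
from .stats import correlate, grade_correlation, repeated_compare_groups

log = logging.getLogger("lungfot.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    peep_levels: tuple = (0.0, 2.0, 4.0, 6.0, 8.0)
    snr_db: float | None = 40.0
    window_s: float = 8.0
    fs_hz: float = 256.0
    n_components: int = 19
    f_min_hz: float = 0.5
    f_max_hz: float = 19.625
    vt_peak_to_peak_ml: float = 0.9
    preset_path: str | None = None
    image_size_px: int = 1024
    images_per_animal: int = 1
    n_regions: int = 15
    region_size_px: int = 256
    stats_peep: float = 4.0
    write_records: bool = True
    make_plots: bool = True

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        if "peep_levels" in d:
            d["peep_levels"] = tuple(d["peep_levels"])
        return cls(**d)


def _write_plots(outdir: Path, spectra_df: pd.DataFrame, idx_df: pd.DataFrame,
                 merged: pd.DataFrame, stats_peep: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = outdir / "report"
    rep.mkdir(exist_ok=True)

    # R_L and E_L vs frequency by group at the reference PEEP
    at = spectra_df[spectra_df["peep_cmh2o"] == stats_peep]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, col, label in ((axes[0], "r", "R_L (cmH2O.s/mL)"), (axes[1], "e", "E_L (cmH2O/mL)")):
        for grp, sub in at.groupby("group"):
            m = sub.groupby("f_hz")[col].mean()
            ax.plot(m.index, m.values, marker="o", ms=3, label=grp)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel(label)
        ax.set_xscale("log")
    axes[1].set_yscale("log")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(rep / "spectra_by_group.png", dpi=120)
    plt.close(fig)

    # indices vs PEEP
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, col in zip(axes, ("r_high", "e_low", "e_het")):
        for grp, sub in idx_df.groupby("group"):
            m = sub.groupby("peep_cmh2o")[col].median()
            ax.plot(m.index, m.values, marker="o", label=grp)
        ax.set_xlabel("PEEP (cmH2O)")
        ax.set_ylabel(col)
        ax.set_yscale("log")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(rep / "indices_vs_peep.png", dpi=120)
    plt.close(fig)

    # TF vs E_low and grade vs E_het scatter
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter(merged["tf_mean"], merged["e_low"])
    axes[0].set_yscale("log")
    axes[0].set_xlabel("tissue fraction (%)")
    axes[0].set_ylabel(f"E_low at PEEP {stats_peep:g} (cmH2O/mL)")
    axes[1].scatter(merged["grade"], merged["e_het"])
    axes[1].set_yscale("log")
    axes[1].set_xlabel("A-grade")
    axes[1].set_ylabel("E_het (cmH2O/mL)")
    fig.tight_layout()
    fig.savefig(rep / "correlations.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, outdir, force: bool = False) -> Path:
    """Run the full synthetic study; returns the run directory.

    Refuses to overwrite a partially written directory that lacks a
    manifest unless ``force`` is set; a directory holding a manifest for
    the identical config is treated as complete and returned untouched.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if outdir.exists() and any(outdir.iterdir()):
        if manifest_path.exists():
            prev = json.loads(manifest_path.read_text())
            if prev.get("config_digest") == config.digest() and not force:
                log.info("identical completed run found; skipping")
                return outdir
        elif not force:
            raise PipelineError(
                f"{outdir} holds partial output without a manifest; use force=True"
            )
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    protocol = build_protocol(
        window_s=config.window_s, fs_hz=config.fs_hz,
        n_components=config.n_components, f_min_hz=config.f_min_hz,
        f_max_hz=config.f_max_hz, vt_peak_to_peak_ml=config.vt_peak_to_peak_ml,
    )
    (outdir / "protocol.json").write_text(protocol.to_json())

    library = load_presets(config.preset_path)
    design = CohortDesign(
        group_sizes=dict(config.group_sizes), peep_levels=tuple(config.peep_levels),
        snr_db=config.snr_db, protocol=protocol,
    )
    cohort = generate_cohort(design, library, seed=config.seed)
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    log.info("simulated %d animals, %d records (%.1fs)",
             len(cohort.models), len(cohort.records), time.time() - t0)

    if config.write_records:
        recdir = outdir / "records"
        recdir.mkdir(exist_ok=True)
        for rec in cohort.records:
            write_record_csv(rec, recdir / f"{rec.animal_id}_peep{rec.peep_cmh2o:g}.csv")

    grade_of = dict(zip(cohort.metadata["animal_id"], cohort.metadata["grade"]))
    group_of = dict(zip(cohort.metadata["animal_id"], cohort.metadata["group"]))

    spectra_rows = []
    index_sets = []
    for rec in cohort.records:
        spec = estimate_impedance(rec, protocol)
        mech = to_mechanics(spec)
        df = mech.to_frame()
        df["animal_id"] = rec.animal_id
        df["group"] = group_of[rec.animal_id]
        df["peep_cmh2o"] = rec.peep_cmh2o
        spectra_rows.append(df)
        index_sets.append(extract_indices(mech, grade_label=rec.grade_label))
    spectra_df = pd.concat(spectra_rows, ignore_index=True)
    spectra_df.to_csv(outdir / "spectra.csv", index=False)
    idx_df = indices_frame(index_sets)
    idx_df["group"] = idx_df["animal_id"].map(group_of)
    idx_df["grade"] = idx_df["animal_id"].map(grade_of)
    idx_df.to_csv(outdir / "indices.csv", index=False)
    log.info("estimated %d spectra (%.1fs)", len(cohort.records), time.time() - t0)

    # histology + morphometry, sharing each animal's TF target with mechanics
    imgdir = outdir / "images"
    imgdir.mkdir(exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    tf_results = []
    manifest_images = []
    for _, row in cohort.metadata.iterrows():
        gp = library.grades[row["group"]]
        hist_ss = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(int(row["animal_index"]), 999)
        )
        rng = np.random.default_rng(hist_ss)
        images = [
            generate_histology(gp, rng, tf_target=row["tf_target"],
                               size_px=config.image_size_px)
            for _ in range(config.images_per_animal)
        ]
        for i, img in enumerate(images):
            path = imgdir / f"{row['animal_id']}_{i:02d}.png"
            write_image(img, path)
            manifest_images.append(str(path.name))
        tf_results.append(
            measure_animal(images, animal_id=row["animal_id"],
                           n_regions_per_image=config.n_regions,
                           region_size_px=config.region_size_px, rng=rng)
        )
    tf_df = tf_frame(tf_results, groups=group_of)
    tf_df.to_csv(outdir / "tf.csv", index=False)
    log.info("histology + morphometry done (%.1fs)", time.time() - t0)

    # statistics at the reference PEEP
    at = idx_df[idx_df["peep_cmh2o"] == config.stats_peep]
    merged = at.merge(tf_df, on=["animal_id", "group"])
    merged["grade"] = merged["animal_id"].map(grade_of)

    stats_out: dict = {"peep_cmh2o": config.stats_peep, "n_animals": int(len(merged))}
    tf_elow = correlate(merged["tf_mean"], merged["e_low"], log_y=True)
    sdtf_ehet = correlate(merged["tf_sd"], merged["e_het"], log_y=True)
    grade_ehet = grade_correlation(merged)
    stats_out["tf_vs_log_e_low"] = {"r": tf_elow.r, "r2": tf_elow.r2,
                                    "slope": tf_elow.slope, "p": tf_elow.p_values["pearson"]}
    stats_out["sd_tf_vs_log_e_het"] = {"r": sdtf_ehet.r, "r2": sdtf_ehet.r2,
                                       "p": sdtf_ehet.p_values["pearson"]}
    stats_out["grade_vs_e_het"] = {"r": grade_ehet.r, "r_s": grade_ehet.r_s,
                                   "p": grade_ehet.p_values["spearman"]}
    cell_counts = idx_df.groupby(["group", "peep_cmh2o"])["e_low"].count()
    if cell_counts.min() >= 2:
        # each animal is measured at every PEEP: split-plot repeated ANOVA
        anova = repeated_compare_groups(
            idx_df, "e_low", subject="animal_id", within="peep_cmh2o",
            between="group",
        )
        stats_out["anova_e_low"] = {
            str(k): float(v) for k, v in anova.anova["F"].dropna().items()
        }
    else:
        # the between-group stratum needs replicate animals per group
        stats_out["anova_e_low"] = None
    (outdir / "stats.json").write_text(json.dumps(stats_out, indent=2, sort_keys=True))

    if config.make_plots:
        _write_plots(outdir, spectra_df, idx_df, merged, config.stats_peep)

    manifest = {
        "package_version": __version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "config_digest": config.digest(),
        "n_animals": int(len(cohort.models)),
        "n_records": int(len(cohort.records)),
        "n_spectra": int(len(cohort.records)),
        "n_tf_rows": int(len(tf_df)),
        "images": manifest_images,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return outdir
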