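"""Forward simulation of grade-dependent left-lung impedance.

The generator is a heterogeneous constant-phase lung: a common central
airway (resistance Rc, inertance Ic) feeding N parallel tissue compartments.
Each compartment i has a peripheral airway resistance Raw_i, inertance
Iaw_i, and a constant-phase tissue element

    Z_ti(f) = (G_i - j H_i) / omega**alpha_i,   alpha_i = (2/pi) atan(H_i/G_i)

with tissue damping G and tissue elastance H (cmH2O/mL).  Recruitment is a
static threshold: a compartment participates at a given PEEP iff
PEEP >= Pc_i, its closing pressure; the recruitment maneuvers that precede
each measurement are taken to reset any history, so there is no hysteresis.
A lung with no open compartment at the measurement PEEP is *unmeasurable*
(the severe-rejection exclusion).

Two mild PEEP couplings beyond recruitment are included so the cohort
reproduces the observed PEEP trends of the indices (airway dilation of
Raw/Rc saturating at PEEP 4, and a small linear softening of G and H with
PEEP); see docs/methods.md.

Pressure records are built in the frequency domain: because the multi-sine
forcing is bin-aligned, P(f_k) = Z_L(f_k) Q(f_k) at the protocol bins is an
exact linear time-invariant response, and additive white Gaussian noise on
pressure sets the SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .presets import GRADE_LABELS, GradePreset, PresetLibrary, load_presets
from .protocol import MultiSineProtocol, build_protocol, synthesize_forcing

__all__ = [
    "CompartmentParams",
    "LungModel",
    "PressureFlowRecord",
    "CohortDesign",
    "Cohort",
    "UnmeasurableLungError",
    "compartment_impedance",
    "lung_impedance",
    "sample_lung",
    "simulate_record",
    "generate_cohort",
    "stratified_tf_targets",
    "write_record_csv",
    "read_record_csv",
    "write_record_hdf5",
    "read_record_hdf5",
]


class UnmeasurableLungError(RuntimeError):
    """No compartment is open at the requested PEEP; impedance is undefined."""


@dataclass(frozen=True)
class CompartmentParams:
    """One parallel lung unit: peripheral airway plus constant-phase tissue."""

    raw: float          # peripheral airway resistance, cmH2O.s/mL
    iaw: float          # peripheral inertance, cmH2O.s^2/mL
    g: float            # tissue damping, cmH2O/mL
    h: float            # tissue elastance, cmH2O/mL
    pc: float           # closing pressure, cmH2O

    def __post_init__(self):
        if self.g <= 0 or self.h <= 0:
            raise ValueError("tissue constants G and H must be positive")

    @property
    def alpha(self) -> float:
        """Constant-phase exponent, (2/pi)*atan(H/G); in (0, 1)."""
        return (2.0 / math.pi) * math.atan(self.h / self.g)


def compartment_impedance(params: CompartmentParams, f_hz) -> np.ndarray:
    """Complex input impedance of one compartment at frequency f (Hz)."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f
    a = params.alpha
    return params.raw + 1j * omega * params.iaw + (params.g - 1j * params.h) / omega**a


@dataclass(frozen=True)
class LungModel:
    """Central airway plus N constant-phase compartments with opening gates."""

    rc: float
    ic: float
    compartments: tuple
    grade_label: str = "A0_native"
    tf_animal: float | None = None       # tissue fraction driving G,H scaling
    raw_peep_slope: float = 0.05
    raw_peep_cap: float = 4.0
    h_peep_slope: float = 0.012

    def __post_init__(self):
        if len(self.compartments) < 1:
            raise ValueError("a lung needs at least one compartment")

    def open_mask(self, peep_cmh2o: float) -> np.ndarray:
        return np.array([peep_cmh2o >= c.pc for c in self.compartments])

    def n_open(self, peep_cmh2o: float) -> int:
        return int(self.open_mask(peep_cmh2o).sum())

    def is_measurable(self, peep_cmh2o: float) -> bool:
        return self.n_open(peep_cmh2o) > 0


def _peep_factors(model: LungModel, peep: float) -> tuple:
    relief_r = 1.0 / (1.0 + model.raw_peep_slope * min(max(peep, 0.0), model.raw_peep_cap))
    relief_h = max(1.0 - model.h_peep_slope * max(peep, 0.0), 0.5)
    return relief_r, relief_h


def lung_impedance(model: LungModel, f_hz, peep_cmh2o: float) -> np.ndarray:
    """Total input impedance Z_L(f) at the given PEEP.

    Z_L = Rc + j omega Ic + [sum over open compartments of 1/Z_i]^-1.
    Raises :class:`UnmeasurableLungError` when every compartment is closed.
    """
    f = np.asarray(f_hz, dtype=float)
    mask = model.open_mask(peep_cmh2o)
    if not mask.any():
        raise UnmeasurableLungError(
            f"no open compartment at PEEP {peep_cmh2o} cmH2O for grade {model.grade_label}"
        )
    relief_r, relief_h = _peep_factors(model, peep_cmh2o)
    omega = 2.0 * np.pi * f
    y = np.zeros(f.shape, dtype=complex)
    for comp, is_open in zip(model.compartments, mask):
        if not is_open:
            continue
        eff = CompartmentParams(
            raw=comp.raw * relief_r,
            iaw=comp.iaw,
            g=comp.g * relief_h,      # scaling G and H together keeps alpha fixed
            h=comp.h * relief_h,
            pc=comp.pc,
        )
        y += 1.0 / compartment_impedance(eff, f)
    return model.rc * relief_r + 1j * omega * model.ic + 1.0 / y


def _tnorm(rng: np.random.Generator, mean: float, sd: float,
           low: float = -np.inf, high: float = np.inf, size=None):
    """Truncated normal draw(s) driven by a numpy Generator."""
    if sd <= 0:
        return np.full(size, mean) if size else mean
    a, b = (low - mean) / sd, (high - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def stratified_tf_targets(
    preset: GradePreset, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-animal TF targets as a stratified sample of the group distribution.

    Quantile midpoints of the truncated normal (randomly assigned to
    animals) make every synthetic cohort reproduce the group's printed TF
    mean and spread by construction rather than only in expectation.
    """
    if n < 1:
        raise ValueError("need at least one animal")
    lo, hi = 0.05, 0.95
    a, b = (lo - preset.tf_mean) / preset.tf_sd, (hi - preset.tf_mean) / preset.tf_sd
    u = (np.arange(n) + 0.5) / n
    targets = sps.truncnorm.ppf(u, a, b, loc=preset.tf_mean, scale=preset.tf_sd)
    return rng.permutation(targets)


def sample_lung(
    library: PresetLibrary,
    grade: str,
    rng: np.random.Generator,
    tf: float | None = None,
) -> LungModel:
    """Draw one animal's lung model from the grade preset.

    The per-animal tissue fraction ``tf`` (drawn from the grade's TF
    distribution when not supplied) scales tissue damping and elastance as
    ``(tf_eff / tf_ref) ** beta`` where ``tf_eff`` shrinks the within-group
    TF deviation by the grade's ``tf_shrink``; compartment-to-compartment
    dispersion follows the grade's heterogeneity CV.  Deterministic given
    the rng state.
    """
    if grade not in library.grades:
        raise ValueError(f"unknown grade label {grade!r}; expected one of {sorted(library.grades)}")
    gp: GradePreset = library.grades[grade]
    n = library.n_compartments

    if tf is None:
        tf = float(_tnorm(rng, gp.tf_mean, gp.tf_sd, 0.05, 0.95))
    if not 0.0 < tf < 1.0:
        raise ValueError("tissue fraction must lie in (0, 1)")

    # the group mean follows the full coupling law; the within-group TF
    # deviation is attenuated so per-group elastance scatter matches the
    # printed group SDs rather than the TF scatter amplified by beta
    tf_eff = gp.tf_mean + gp.tf_shrink * (tf - gp.tf_mean)
    scale = (tf_eff / library.tf_ref) ** library.beta
    h_lung = library.h_lung_ref * scale
    cv = gp.het_cv

    h_i = _tnorm(rng, n * h_lung, cv * n * h_lung, low=0.05 * n * h_lung, size=n)
    eta_i = _tnorm(rng, library.eta_mean, library.eta_sd, low=0.05, high=0.95, size=n)
    raw_mean = n * gp.raw_lung_mean
    raw_i = _tnorm(rng, raw_mean, max(cv * raw_mean, n * gp.raw_lung_sd), low=0.05 * raw_mean, size=n)
    pc_i = rng.normal(gp.pc_mean, gp.pc_sd, size=n)
    if gp.pc_max is not None:
        pc_i = np.minimum(pc_i, gp.pc_max)
    if pc_i.min() > -0.5:
        # guarantee measurability at zero PEEP: the best-ventilated unit
        # (central, patent) never closes within the study range
        pc_i[np.argmin(pc_i)] = -1.0

    rc = float(_tnorm(rng, library.rc_mean, library.rc_sd, low=0.005))
    ic = float(_tnorm(rng, library.ic_mean, library.ic_sd, low=1e-6))

    comps = tuple(
        CompartmentParams(raw=float(raw_i[k]), iaw=0.0,
                          g=float(eta_i[k] * h_i[k]), h=float(h_i[k]), pc=float(pc_i[k]))
        for k in range(n)
    )
    return LungModel(
        rc=rc, ic=ic, compartments=comps, grade_label=grade, tf_animal=tf,
        raw_peep_slope=library.raw_peep_slope,
        raw_peep_cap=library.raw_peep_cap,
        h_peep_slope=library.h_peep_slope,
    )


@dataclass(frozen=True)
class PressureFlowRecord:
    """One forced-oscillation measurement: flow in, pressure out."""

    t: np.ndarray               # s
    q: np.ndarray               # flow, mL/s
    p: np.ndarray               # airway-opening pressure, cmH2O
    fs_hz: float
    peep_cmh2o: float
    animal_id: str = ""
    grade_label: str = ""
    snr_db: float | None = None
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.t) == len(self.q) == len(self.p)):
            raise ValueError("t, q, p must have equal length")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.p))):
            raise ValueError("record contains non-finite samples")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "flow": self.q, "pressure": self.p})


def simulate_record(
    model: LungModel,
    protocol: MultiSineProtocol,
    peep_cmh2o: float,
    snr_db: float | None = None,
    rng: np.random.Generator | None = None,
    n_windows: int = 1,
    animal_id: str = "",
) -> PressureFlowRecord:
    """Simulate a pressure-flow record under multi-sine forcing.

    The pressure is the exact frequency-domain response at the protocol
    bins; ``snr_db=None`` (or inf) means noiseless, otherwise white Gaussian
    noise is added to pressure at the requested SNR.  ``n_windows`` tiles
    the periodic forcing so segment-averaged estimators have independent
    noise realisations per window.
    """
    if not model.is_measurable(peep_cmh2o):
        raise UnmeasurableLungError(
            f"lung not measurable at PEEP {peep_cmh2o} cmH2O"
        )
    wav = synthesize_forcing(protocol)
    nwin = protocol.n_samples
    kbins = np.asarray([int(round(k)) for k in protocol.k_indices])

    qf = np.fft.rfft(wav.flow)
    z = lung_impedance(model, protocol.freqs_hz, peep_cmh2o)
    pf = np.zeros_like(qf)
    pf[kbins] = z * qf[kbins]
    p1 = np.fft.irfft(pf, n=nwin)

    q = np.tile(wav.flow, n_windows)
    p = np.tile(p1, n_windows)
    t = np.arange(nwin * n_windows) / protocol.fs_hz

    if snr_db is not None and np.isfinite(snr_db):
        if rng is None:
            raise ValueError("noisy simulation requires an rng")
        sigma = float(np.sqrt(np.mean(p1**2))) * 10.0 ** (-snr_db / 20.0)
        p = p + rng.normal(0.0, sigma, size=p.shape)

    return PressureFlowRecord(
        t=t, q=q, p=p, fs_hz=protocol.fs_hz, peep_cmh2o=peep_cmh2o,
        animal_id=animal_id, grade_label=model.grade_label, snr_db=snr_db,
        meta={"n_windows": n_windows, "tf_animal": model.tf_animal},
    )


DEFAULT_GROUP_SIZES = {"A0_native": 6, "A0_iso": 6, "A1": 4, "A2": 7, "A3": 6}


@dataclass(frozen=True)
class CohortDesign:
    """Study design: group sizes, PEEP ladder, noise level, forcing."""

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    peep_levels: tuple = (0.0, 2.0, 4.0, 6.0, 8.0)
    snr_db: float | None = 40.0
    n_windows: int = 1
    protocol: MultiSineProtocol | None = None

    def resolved_protocol(self) -> MultiSineProtocol:
        return self.protocol if self.protocol is not None else build_protocol()


@dataclass
class Cohort:
    design: CohortDesign
    models: Mapping[str, LungModel]
    records: Sequence[PressureFlowRecord]
    metadata: pd.DataFrame              # one row per animal

    def records_for(self, animal_id: str):
        return [r for r in self.records if r.animal_id == animal_id]


def generate_cohort(
    design: CohortDesign | None = None,
    library: PresetLibrary | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate the full synthetic mechanics cohort.

    One lung model per animal and one record per PEEP level.  All
    randomness derives hierarchically from ``seed`` (per-animal streams for
    the model draw and per-PEEP noise), so the same seed reproduces the
    cohort bit-for-bit.
    """
    design = design or CohortDesign()
    library = library or load_presets()
    protocol = design.resolved_protocol()

    rows = []
    models: dict = {}
    records: list = []
    root = np.random.SeedSequence(seed)
    animal_idx = 0
    for grade in GRADE_LABELS:
        n_animals = int(design.group_sizes.get(grade, 0))
        if n_animals < 1:
            continue
        group_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(7000, GRADE_LABELS.index(grade)))
        )
        tf_targets = stratified_tf_targets(library.grades[grade], n_animals, group_rng)
        for j in range(n_animals):
            animal_ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(animal_idx,))
            model_rng = np.random.default_rng(animal_ss.spawn(1)[0])
            model = sample_lung(library, grade, model_rng, tf=float(tf_targets[j]))
            animal_id = f"{grade}-{j + 1:02d}"
            models[animal_id] = model
            for ip, peep in enumerate(design.peep_levels):
                noise_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=root.entropy, spawn_key=(animal_idx, 1 + ip))
                )
                rec = simulate_record(
                    model, protocol, peep, snr_db=design.snr_db,
                    rng=noise_rng, n_windows=design.n_windows, animal_id=animal_id,
                )
                records.append(rec)
            rows.append(
                {
                    "animal_id": animal_id,
                    "group": grade,
                    "grade": library.grades[grade].grade,
                    "tf_target": model.tf_animal,
                    "animal_index": animal_idx,
                }
            )
            animal_idx += 1
    metadata = pd.DataFrame(rows)
    return Cohort(design=design, models=models, records=records, metadata=metadata)


# ---------------------------------------------------------------------------
# record I/O

def write_record_csv(record: PressureFlowRecord, path) -> None:
    df = record.to_frame()
    header = (
        f"# fs_hz={record.fs_hz} peep_cmh2o={record.peep_cmh2o} "
        f"animal_id={record.animal_id} grade={record.grade_label} snr_db={record.snr_db}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_record_csv(path) -> PressureFlowRecord:
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
    fs = float(meta.get("fs_hz", 1.0 / np.median(np.diff(df["t"].to_numpy()))))
    snr = meta.get("snr_db", "None")
    return PressureFlowRecord(
        t=df["t"].to_numpy(), q=df["flow"].to_numpy(), p=df["pressure"].to_numpy(),
        fs_hz=fs, peep_cmh2o=float(meta.get("peep_cmh2o", np.nan)),
        animal_id=meta.get("animal_id", ""), grade_label=meta.get("grade", ""),
        snr_db=None if snr in ("None", "inf") else float(snr),
    )


def write_record_hdf5(record: PressureFlowRecord, path, group: str = "record") -> None:
    import h5py

    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for name, arr in (("t", record.t), ("flow", record.q), ("pressure", record.p)):
            g.create_dataset(name, data=arr)
        g.attrs["fs_hz"] = record.fs_hz
        g.attrs["peep_cmh2o"] = record.peep_cmh2o
        g.attrs["animal_id"] = record.animal_id
        g.attrs["grade_label"] = record.grade_label
        g.attrs["snr_db"] = np.nan if record.snr_db is None else record.snr_db


def read_record_hdf5(path, group: str = "record") -> PressureFlowRecord:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[group]
        snr = float(g.attrs["snr_db"])
        return PressureFlowRecord(
            t=g["t"][()], q=g["flow"][()], p=g["pressure"][()],
            fs_hz=float(g.attrs["fs_hz"]), peep_cmh2o=float(g.attrs["peep_cmh2o"]),
            animal_id=str(g.attrs["animal_id"]), grade_label=str(g.attrs["grade_label"]),
            snr_db=None if np.isnan(snr) else snr,
        )
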