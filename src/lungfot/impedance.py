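"""Impedance estimation from pressure-flow records at the protocol bins.

Because the multi-sine components are bin-aligned with the analysis window,
the default estimator is an exact-bin DFT over full windows with a
rectangular taper: Z(f_k) = P(f_k)/Q(f_k), unbiased for the synthetic
generator.  A Welch-style segment-averaged cross-spectral estimator
(Z = S_qp/S_qq with per-bin coherence) is available for imported data; bins
whose coherence falls below a threshold are flagged, never dropped.

Sign conventions: inspiratory flow positive, pressure and flow referenced
at the airway opening; resistance R_L = Re(Z), reactance X_L = Im(Z), and
dynamic elastance E_L = -omega * X_L with omega = 2*pi*f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .protocol import MultiSineProtocol

__all__ = [
    "ImpedanceSpectrum",
    "MechanicsSpectra",
    "EstimationError",
    "estimate_impedance",
    "to_mechanics",
]


class EstimationError(RuntimeError):
    """Raised when a record cannot support impedance estimation."""


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex Z_L at the protocol frequencies, with optional coherence."""

    freqs_hz: np.ndarray
    z: np.ndarray                        # complex, cmH2O.s/mL
    coherence: np.ndarray | None = None  # gamma^2 in [0, 1], None for exact-bin DFT
    low_coherence: np.ndarray | None = None
    peep_cmh2o: float = float("nan")
    animal_id: str = ""

    def __post_init__(self):
        if len(self.freqs_hz) != len(self.z):
            raise ValueError("freqs and z length mismatch")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite impedance values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"f_hz": self.freqs_hz, "re_z": self.z.real, "im_z": self.z.imag}
        )
        if self.coherence is not None:
            df["coherence"] = self.coherence
        return df


@dataclass(frozen=True)
class MechanicsSpectra:
    """R_L, X_L and E_L derived from an impedance spectrum."""

    freqs_hz: np.ndarray
    r: np.ndarray       # resistance, cmH2O.s/mL
    x: np.ndarray       # reactance, cmH2O.s/mL
    e: np.ndarray       # dynamic elastance -omega*X, cmH2O/mL
    peep_cmh2o: float = float("nan")
    animal_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f_hz": self.freqs_hz, "r": self.r, "x": self.x, "e": self.e}
        )


def _bin_indices(protocol: MultiSineProtocol) -> np.ndarray:
    return np.asarray([int(round(k)) for k in protocol.k_indices])


def estimate_impedance(
    record,
    protocol: MultiSineProtocol,
    method: str = "dft",
    coherence_min: float = 0.9,
    detrend: bool = False,
) -> ImpedanceSpectrum:
    """Estimate Z_L(f) at the protocol frequencies from one record.

    ``method="dft"`` (default): exact-bin DFT averaged coherently over the
    full windows the record contains.  ``method="welch"``: segment-averaged
    cross-spectra over non-overlapping rectangular windows with per-bin
    coherence; bins with coherence below ``coherence_min`` are flagged in
    ``low_coherence``.
    """
    q = np.asarray(record.q, dtype=float)
    p = np.asarray(record.p, dtype=float)
    if abs(record.fs_hz - protocol.fs_hz) > 1e-9:
        raise EstimationError(
            f"record fs {record.fs_hz} Hz does not match protocol fs {protocol.fs_hz} Hz"
        )
    nwin = protocol.n_samples
    nseg = len(q) // nwin
    if nseg < 1:
        raise EstimationError("record shorter than one protocol window")
    if detrend:
        q = spsig.detrend(q, type="linear")
        p = spsig.detrend(p, type="linear")
    kbins = _bin_indices(protocol)

    if method == "dft":
        qf = np.fft.rfft(q[: nseg * nwin].reshape(nseg, nwin), axis=1).mean(axis=0)
        pf = np.fft.rfft(p[: nseg * nwin].reshape(nseg, nwin), axis=1).mean(axis=0)
        qk, pk = qf[kbins], pf[kbins]
        floor = np.max(np.abs(qf)) * 1e-12
        if np.any(np.abs(qk) <= floor):
            dead = protocol.freqs_hz[np.abs(qk) <= floor]
            raise EstimationError(f"no excitation at bin(s) {dead} Hz")
        z = pk / qk
        coh = lowc = None
    elif method == "welch":
        kwargs = dict(
            fs=record.fs_hz, window="boxcar", nperseg=nwin, noverlap=0, detrend=False
        )
        _, s_qp = spsig.csd(q, p, **kwargs)
        _, s_qq = spsig.welch(q, **kwargs)
        _, s_pp = spsig.welch(p, **kwargs)
        qk = s_qq[kbins]
        floor = np.max(s_qq) * 1e-24
        if np.any(qk <= floor):
            dead = protocol.freqs_hz[qk <= floor]
            raise EstimationError(f"no excitation at bin(s) {dead} Hz")
        z = s_qp[kbins] / qk
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(s_qp[kbins]) ** 2 / (qk * s_pp[kbins])
        coh = np.clip(np.nan_to_num(coh, nan=1.0), 0.0, 1.0)
        lowc = coh < coherence_min
    else:
        raise ValueError(f"unknown method {method!r}")

    return ImpedanceSpectrum(
        freqs_hz=protocol.freqs_hz, z=z, coherence=coh, low_coherence=lowc,
        peep_cmh2o=getattr(record, "peep_cmh2o", float("nan")),
        animal_id=getattr(record, "animal_id", ""),
    )


def to_mechanics(spectrum: ImpedanceSpectrum) -> MechanicsSpectra:
    """Split Z into resistance/reactance and derive E_L = -omega X_L."""
    omega = 2.0 * np.pi * spectrum.freqs_hz
    return MechanicsSpectra(
        freqs_hz=spectrum.freqs_hz,
        r=spectrum.z.real.copy(),
        x=spectrum.z.imag.copy(),
        e=-omega * spectrum.z.imag,
        peep_cmh2o=spectrum.peep_cmh2o,
        animal_id=spectrum.animal_id,
    )
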