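"""Multi-sine forced-oscillation protocol design and waveform synthesis.

A forced-oscillation measurement superimposes a small-amplitude multi-sine
volume perturbation on the airway during a pause of regular ventilation.
The perturbation is a sum of sinusoids whose frequencies are exact integer
multiples of the reciprocal window length (bin-aligned, so a DFT over one
window sees no spectral leakage) and are pairwise *non-harmonic*: no
component frequency is an integer multiple of another, which keeps the
harmonic distortion products of one component from landing on another
component's bin.

The default protocol is 19 components between 0.5 and 19.625 Hz delivered
over an 8 s window, with a peak-to-peak volume excursion equal to the
ventilator tidal volume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "MultiSineProtocol",
    "ForcingWaveforms",
    "ProtocolError",
    "ProtocolReport",
    "build_protocol",
    "synthesize_forcing",
    "validate_protocol",
    "schroeder_phases",
]


class ProtocolError(ValueError):
    """Raised when a protocol cannot be constructed or is structurally invalid."""


def schroeder_phases(n: int) -> np.ndarray:
    """Schroeder's quadratic phase schedule, phi_i = -pi*i*(i-1)/n (i = 1..n).

    Keeps the crest factor of an equal-amplitude multi-sine low without
    any numerical optimisation.
    """
    i = np.arange(1, n + 1, dtype=float)
    return -np.pi * i * (i - 1.0) / n


@dataclass(frozen=True)
class MultiSineProtocol:
    """The forcing design: window, component bins, phases and amplitude scale.

    Frequencies are represented by their bin multipliers ``k_indices`` with
    ``freqs_hz = k_indices / window_s``; a valid protocol has integer
    multipliers only, but non-integer values are representable so that
    :func:`validate_protocol` can report the violation.
    """

    window_s: float = 8.0
    fs_hz: float = 256.0
    k_indices: tuple = (4, 5, 6, 7, 9, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 157)
    phases_rad: tuple = ()
    vt_peak_to_peak_ml: float = 0.9

    def __post_init__(self):
        if not self.phases_rad:
            object.__setattr__(
                self, "phases_rad", tuple(schroeder_phases(len(self.k_indices)))
            )
        if len(self.phases_rad) != len(self.k_indices):
            raise ProtocolError("phases_rad and k_indices must have equal length")

    @property
    def base_df_hz(self) -> float:
        """Frequency resolution of the window, 1/window_s."""
        return 1.0 / self.window_s

    @property
    def freqs_hz(self) -> np.ndarray:
        return np.asarray(self.k_indices, dtype=float) * self.base_df_hz

    @property
    def n_components(self) -> int:
        return len(self.k_indices)

    @property
    def n_samples(self) -> int:
        return int(round(self.window_s * self.fs_hz))

    def to_json(self) -> str:
        return json.dumps(
            {
                "window_s": self.window_s,
                "fs_hz": self.fs_hz,
                "k_indices": list(self.k_indices),
                "phases_rad": list(self.phases_rad),
                "vt_peak_to_peak_ml": self.vt_peak_to_peak_ml,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MultiSineProtocol":
        d = json.loads(text)
        return cls(
            window_s=d["window_s"],
            fs_hz=d["fs_hz"],
            k_indices=tuple(d["k_indices"]),
            phases_rad=tuple(d["phases_rad"]),
            vt_peak_to_peak_ml=d["vt_peak_to_peak_ml"],
        )

    def with_vt(self, vt_ml: float) -> "MultiSineProtocol":
        return replace(self, vt_peak_to_peak_ml=vt_ml)


def _as_bin(f_hz: float, base_df_hz: float, name: str) -> int:
    k = f_hz / base_df_hz
    if abs(k - round(k)) > 1e-9:
        raise ProtocolError(
            f"{name}={f_hz} Hz is not an integer multiple of the bin width {base_df_hz} Hz"
        )
    return int(round(k))


def _harmonic_pair(a: int, b: int) -> bool:
    lo, hi = (a, b) if a <= b else (b, a)
    return hi % lo == 0


def build_protocol(
    window_s: float = 8.0,
    fs_hz: float = 256.0,
    n_components: int = 19,
    f_min_hz: float = 0.5,
    f_max_hz: float = 19.625,
    include_hz: Sequence[float] = (0.75,),
    vt_peak_to_peak_ml: float = 0.9,
) -> MultiSineProtocol:
    """Construct a non-harmonic, bin-aligned multi-sine protocol.

    Component selection is deterministic: the bins of ``f_min_hz``,
    ``f_max_hz`` (and, when there is room, each frequency in ``include_hz``)
    are forced in, then a greedy scan over ascending bin multipliers accepts
    every k that is neither an integer multiple nor a divisor of an already
    accepted k, stopping at ``n_components``.

    Raises :class:`ProtocolError` naming the violated constraint when the
    request cannot be satisfied.
    """
    if window_s <= 0 or fs_hz <= 0:
        raise ProtocolError("window_s and fs_hz must be positive")
    if n_components < 2:
        raise ProtocolError("n_components must be at least 2")
    if fs_hz <= 2.0 * f_max_hz:
        raise ProtocolError(
            f"sampling rate {fs_hz} Hz must exceed twice the top frequency {f_max_hz} Hz"
        )
    base = 1.0 / window_s
    k_min = _as_bin(f_min_hz, base, "f_min_hz")
    k_max = _as_bin(f_max_hz, base, "f_max_hz")
    if k_min < 1 or k_max <= k_min:
        raise ProtocolError("need 0 < f_min_hz < f_max_hz")

    forced = [k_min, k_max]
    if n_components > 2:
        for f in include_hz:
            k = _as_bin(f, base, "include_hz")
            if k_min < k < k_max and k not in forced:
                forced.append(k)
            if len(forced) >= n_components:
                break
    for i, a in enumerate(forced):
        for b in forced[i + 1 :]:
            if _harmonic_pair(a, b):
                raise ProtocolError(
                    f"forced bins {a} and {b} are harmonically related"
                )

    accepted = list(forced)
    for k in range(k_min, k_max + 1):
        if len(accepted) >= n_components:
            break
        if k in accepted:
            continue
        if any(_harmonic_pair(k, a) for a in accepted):
            continue
        accepted.append(k)
    if len(accepted) < n_components:
        raise ProtocolError(
            f"cannot place {n_components} pairwise non-harmonic components in "
            f"bins {k_min}..{k_max}; only {len(accepted)} fit"
        )
    accepted.sort()
    return MultiSineProtocol(
        window_s=window_s,
        fs_hz=fs_hz,
        k_indices=tuple(accepted),
        phases_rad=tuple(schroeder_phases(len(accepted))),
        vt_peak_to_peak_ml=vt_peak_to_peak_ml,
    )


class ForcingWaveforms(NamedTuple):
    t: np.ndarray
    volume: np.ndarray  # mL, about the end-expiratory volume
    flow: np.ndarray    # mL/s, analytic derivative of volume


def synthesize_forcing(
    protocol: MultiSineProtocol,
    rng_or_phases: "np.random.Generator | Sequence[float] | None" = None,
) -> ForcingWaveforms:
    """Synthesize one window of the volume and flow forcing waveforms.

    ``v(t) = A * sum_i sin(2 pi f_i t + phi_i)`` with A chosen so the sampled
    peak-to-peak volume excursion equals ``vt_peak_to_peak_ml`` exactly; the
    flow is the analytic derivative (sum of cosines), not a finite difference.

    ``rng_or_phases`` overrides the protocol phases: a Generator draws
    uniform random phases, an array-like is used verbatim.
    """
    report = validate_protocol(protocol)
    if not report.all_ok:
        raise ProtocolError(f"invalid protocol: {report.failures()}")
    if protocol.vt_peak_to_peak_ml <= 0:
        raise ProtocolError("vt_peak_to_peak_ml must be positive")

    if rng_or_phases is None:
        phases = np.asarray(protocol.phases_rad, dtype=float)
    elif isinstance(rng_or_phases, np.random.Generator):
        phases = rng_or_phases.uniform(0.0, 2.0 * np.pi, protocol.n_components)
    else:
        phases = np.asarray(rng_or_phases, dtype=float)
        if phases.shape != (protocol.n_components,):
            raise ProtocolError("explicit phases must have one entry per component")

    t = np.arange(protocol.n_samples) / protocol.fs_hz
    omega = 2.0 * np.pi * protocol.freqs_hz
    arg = np.outer(omega, t) + phases[:, None]
    unit_v = np.sin(arg).sum(axis=0)
    unit_q = (omega[:, None] * np.cos(arg)).sum(axis=0)
    amp = protocol.vt_peak_to_peak_ml / (unit_v.max() - unit_v.min())
    return ForcingWaveforms(t=t, volume=amp * unit_v, flow=amp * unit_q)


@dataclass(frozen=True)
class ProtocolReport:
    """Per-invariant pass/fail report from :func:`validate_protocol`."""

    checks: dict
    messages: dict

    @property
    def all_ok(self) -> bool:
        return all(self.checks.values())

    def failures(self) -> dict:
        return {k: self.messages[k] for k, ok in self.checks.items() if not ok}


def validate_protocol(protocol: MultiSineProtocol) -> ProtocolReport:
    """Check every structural invariant of a protocol; reporting only."""
    checks: dict = {}
    msgs: dict = {}

    ks = np.asarray(protocol.k_indices, dtype=float)
    integral = np.all(np.abs(ks - np.round(ks)) < 1e-9) and np.all(ks >= 1)
    checks["bin_aligned"] = bool(integral)
    msgs["bin_aligned"] = (
        "all frequencies are integer multiples of 1/window_s"
        if integral
        else f"non-integer bin multipliers: {ks[np.abs(ks - np.round(ks)) >= 1e-9]}"
    )

    ascending = bool(np.all(np.diff(ks) > 0))
    checks["distinct_ascending"] = ascending
    msgs["distinct_ascending"] = "k_indices distinct and ascending" if ascending else "k_indices not strictly ascending"

    nonharm = True
    offender = None
    if integral:
        kk = [int(round(k)) for k in ks]
        for i, a in enumerate(kk):
            for b in kk[i + 1 :]:
                if _harmonic_pair(a, b):
                    nonharm, offender = False, (a, b)
                    break
            if not nonharm:
                break
    checks["non_harmonic"] = nonharm
    msgs["non_harmonic"] = (
        "no component is an integer multiple of another"
        if nonharm
        else f"harmonically related bins: {offender}"
    )

    nyq = protocol.fs_hz > 2.0 * float(protocol.freqs_hz.max(initial=0.0))
    checks["nyquist"] = bool(nyq)
    msgs["nyquist"] = "fs exceeds twice the top frequency" if nyq else "fs too low for the top frequency"

    nphase = len(protocol.phases_rad) == protocol.n_components
    checks["phases"] = nphase
    msgs["phases"] = "one phase per component" if nphase else "phase count mismatch"

    int_samples = abs(protocol.window_s * protocol.fs_hz - protocol.n_samples) < 1e-9
    checks["integer_samples"] = bool(int_samples)
    msgs["integer_samples"] = "window holds an integer number of samples" if int_samples else "window_s*fs_hz is not an integer"

    return ProtocolReport(checks=checks, messages=msgs)
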