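"""Scalar indices condensing a mechanics spectrum.

Four indices summarise the frequency dependence of lung mechanics at one
PEEP:

* ``R_high`` — resistance at the highest measured frequency(ies), dominated
  by airway resistance (configurable ``n_high``, default the single top
  frequency);
* ``E_low``  — dynamic elastance at the lowest frequency (0.5 Hz), sensitive
  to tissue stiffness and derecruitment;
* ``E_max``  — the highest absolute value of E_L over the measured bins
  (the absolute value guards against negative E_L when inertance dominates
  at high frequency);
* ``E_het``  — E_max - E_low, an index of mechanical heterogeneity.

E_max >= |E_low| by construction, so E_het is always non-negative when
E_low is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impedance import MechanicsSpectra

__all__ = ["IndexSet", "IndexError_", "extract_indices", "indices_frame"]


class IndexError_(ValueError):
    """Raised when a spectrum cannot yield the requested indices."""


@dataclass(frozen=True)
class IndexSet:
    r_high: float       # cmH2O.s/mL
    e_low: float        # cmH2O/mL
    e_max: float        # cmH2O/mL
    e_het: float        # cmH2O/mL
    peep_cmh2o: float = float("nan")
    animal_id: str = ""
    grade_label: str = ""

    def __post_init__(self):
        if self.e_het < -1e-9:
            raise ValueError("E_het must be non-negative")


def extract_indices(
    spectra: MechanicsSpectra,
    n_high: int = 1,
    f_low_hz: float = 0.5,
    grade_label: str = "",
) -> IndexSet:
    """Reduce a mechanics spectrum to (R_high, E_low, E_max, E_het).

    ``n_high`` averages resistance over that many of the highest measured
    frequencies.  Raises :class:`IndexError_` when the low-frequency bin is
    absent or ``n_high`` exceeds the number of bins.
    """
    f = np.asarray(spectra.freqs_hz, dtype=float)
    if n_high < 1 or n_high > len(f):
        raise IndexError_(f"n_high={n_high} outside 1..{len(f)}")
    low = np.where(np.abs(f - f_low_hz) < 1e-9)[0]
    if len(low) == 0:
        raise IndexError_(f"spectrum has no bin at {f_low_hz} Hz")

    order = np.argsort(f)
    e_low = float(spectra.e[low[0]])
    e_max = float(np.max(np.abs(spectra.e)))
    r_high = float(np.mean(spectra.r[order][-n_high:]))
    return IndexSet(
        r_high=r_high, e_low=e_low, e_max=e_max, e_het=e_max - e_low,
        peep_cmh2o=spectra.peep_cmh2o, animal_id=spectra.animal_id,
        grade_label=grade_label,
    )


def indices_frame(index_sets) -> pd.DataFrame:
    """Tidy table, one row per (animal, PEEP)."""
    return pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "grade_label": s.grade_label,
                "peep_cmh2o": s.peep_cmh2o,
                "r_high": s.r_high,
                "e_low": s.e_low,
                "e_max": s.e_max,
                "e_het": s.e_het,
            }
            for s in index_sets
        ]
    )
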