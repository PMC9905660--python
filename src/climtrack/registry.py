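"""Species registry and the packaged Foxe Basin / Rasmussen Lowlands reference table.

The published study surveyed 12 shorebird species in two mid-Arctic regions
of Nunavut, 25 years apart.  The printed per-species summary — species
temperature index (STI, mean June temperature over the North American
breeding range) and the percent of 64 plots occupied in each survey era —
is shipped as a small CSV fixture so the headline change-vs-STI regression
can be reproduced without any external downloads.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import RegistryError

#: Four-letter codes of the 12 study species, in STI order.
STUDY_SPECIES: tuple[str, ...] = (
    "REKN", "RUTU", "BASA", "BBPL", "BBSA", "WRSA",
    "REPH", "PESA", "DUNL", "AMGP", "SESA", "STSA",
)

#: Number of 16-ha plots surveyed per era in the study (28 Rasmussen + 36 Foxe Basin).
STUDY_N_PLOTS: int = 64


class SpeciesRegistry:
    """A declared set of valid species codes.

    An *open* registry accepts any code (used for synthetic data); a closed
    registry raises :class:`RegistryError` for codes outside its set.
    """

    def __init__(self, codes: set[str] | frozenset[str] | None = None):
        self._codes = frozenset(codes) if codes is not None else None

    @property
    def open(self) -> bool:
        return self._codes is None

    @property
    def codes(self) -> frozenset[str] | None:
        return self._codes

    def check(self, code: str) -> str:
        if self._codes is not None and code not in self._codes:
            raise RegistryError(f"unknown species code {code!r}")
        return code

    @classmethod
    def study(cls) -> "SpeciesRegistry":
        return cls(set(STUDY_SPECIES))

    @classmethod
    def open_registry(cls) -> "SpeciesRegistry":
        return cls(None)


def load_reference_table() -> pd.DataFrame:
    """Return the packaged per-species reference summary.

    Columns: ``common_name``, ``code``, ``sti_degc``, ``occ_early_pct``,
    ``occ_late_pct``, ``pct_change_printed`` (string; ``"Inf"`` for the two
    species absent in the early era).  Rows are sorted by STI ascending.
    """
    ref = resources.files("climtrack.data").joinpath("foxe_rasmussen_reference.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"pct_change_printed": str})
    return df


def reconstruct_occupied_counts(occ_pct: np.ndarray | pd.Series, n_plots: int = STUDY_N_PLOTS) -> np.ndarray:
    """Invert a printed occupancy percentage back to an occupied-plot count.

    The published table prints ``100 * k / n_plots`` rounded to one decimal,
    so ``round(pct * n_plots / 100)`` recovers the integer count exactly
    (e.g. 7.8% of 64 plots -> 5).  Rounding is half-away-from-zero.
    """
    x = np.asarray(occ_pct, dtype=float) * n_plots / 100.0
    return np.floor(x + 0.5).astype(int)
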