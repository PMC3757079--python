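"""Per-residue C-alpha root-mean-square fluctuation after partial alignment.

Conformers are superposed onto the first conformer of the subset over a
chosen alignment range (residues 1-17 by default, the rigid N-terminal
helix region), the mean C-alpha position per residue is computed, and
RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2). Because the folds differ in
flexibility, profiles are computed separately per super-family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import kabsch_superpose
from .model_io import Ensemble

DEFAULT_ALIGN_RANGE = (1, 17)


@dataclass
class RMSFProfile:
    """Per-residue C-alpha RMSF (A) for one conformer subset."""

    values: np.ndarray          # (L,) RMSF per residue, A
    align_range: tuple[int, int]
    label: str = ""
    n_conformers: int = 0

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "residue": np.arange(1, len(self.values) + 1),
            "rmsf_A": self.values,
        })
        df["label"] = self.label
        df["n"] = self.n_conformers
        return df


def _aligned_ca(ensemble: Ensemble, align_range: tuple[int, int]) -> np.ndarray:
    L = len(ensemble.sequence)
    lo, hi = align_range
    if not (1 <= lo <= hi <= L):
        raise ValueError(f"alignment range {align_range} outside 1..{L}")
    sel = np.arange(lo - 1, hi)
    X = ensemble.ca_array()
    ref = X[0, sel]
    out = np.empty_like(X)
    for t in range(X.shape[0]):
        R, tr, _ = kabsch_superpose(X[t, sel], ref)
        out[t] = X[t] @ R.T + tr
    return out


def rmsf(ensemble: Ensemble,
         align_range: tuple[int, int] = DEFAULT_ALIGN_RANGE,
         label: str = "") -> RMSFProfile:
    """RMSF of every C-alpha after aligning conformers on ``align_range``.

    Requires at least two conformers; the first conformer of the subset
    is the superposition reference.
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least 2 conformers")
    X = _aligned_ca(ensemble, align_range)
    mean = X.mean(axis=0)
    sq = ((X - mean) ** 2).sum(axis=2).mean(axis=0)
    return RMSFProfile(np.sqrt(sq), align_range, label, len(ensemble))


def rmsf_by_superfamily(ensemble: Ensemble, labels: Sequence[str],
                        align_range: tuple[int, int] = DEFAULT_ALIGN_RANGE
                        ) -> tuple[list[RMSFProfile], list[str]]:
    """One RMSF profile per super-family present in ``labels``.

    Labels with fewer than two conformers cannot define a fluctuation and
    are omitted; their names are returned as warning records.
    """
    if len(labels) != len(ensemble):
        raise ValueError("one label per conformer is required")
    profiles = []
    warnings = []
    for lab in dict.fromkeys(labels):  # preserve first-appearance order
        idx = [i for i, l in enumerate(labels) if l == lab]
        if len(idx) < 2:
            warnings.append(f"label {lab!r} has {len(idx)} conformer(s); omitted")
            continue
        profiles.append(rmsf(ensemble.subset(idx), align_range, label=lab))
    return profiles, warnings
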