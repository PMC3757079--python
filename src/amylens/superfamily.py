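"""Rule-based merge of structural families into the three super-families
(helix-coil, helix-hairpin, beta-hairpin) and abundance statistics.

The classification keys on the aggregate secondary structure of the
N-terminal part (residues 1-17) and the C-terminal part (residues 18-37):
a conformer is helix-rich when its N-part contains more helix than sheet
residues (otherwise it is a beta-hairpin); a helix-rich conformer is a
helix-hairpin when its C-part contains more than four sheet residues
(the minimal 2:2 beta-hairpin), otherwise a helix-coil.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blockstats import BlockPartition, make_blocks
from .cluster import ClusterResult
from .secstruct import CLASS_OF_CODE

SUPERFAMILY_LABELS = ("helix-coil", "helix-hairpin", "beta-hairpin")

N_PART = (1, 17)
C_PART = (18, 37)
MIN_HAIRPIN_SHEET = 4  # strictly more than this many C-part sheet residues


def classify_superfamily(ss: str, n_part: tuple[int, int] = N_PART,
                         c_part: tuple[int, int] = C_PART) -> str:
    """Map one secondary-structure string to its super-family label."""
    L = c_part[1]
    if len(ss) != L:
        raise ValueError(f"expected SS string of length {L}, got {len(ss)}")
    n_slice = ss[n_part[0] - 1:n_part[1]]
    c_slice = ss[c_part[0] - 1:c_part[1]]
    n_helix = sum(1 for c in n_slice if CLASS_OF_CODE[c] == "helix")
    n_sheet = sum(1 for c in n_slice if CLASS_OF_CODE[c] == "sheet")
    if n_helix <= n_sheet:
        return "beta-hairpin"
    c_sheet = sum(1 for c in c_slice if CLASS_OF_CODE[c] == "sheet")
    if c_sheet > MIN_HAIRPIN_SHEET:
        return "helix-hairpin"
    return "helix-coil"


def classify_families(result: ClusterResult, ss_strings: Sequence[str],
                      granularity: str = "centroid") -> list[str]:
    """Per-conformer super-family labels from a cluster result.

    ``centroid`` granularity classifies each family's centroid and lets
    every member inherit that label (the families-merge reading);
    ``frame`` granularity classifies each conformer from its own SS
    string.
    """
    if len(ss_strings) != result.n:
        raise ValueError("one SS string per clustered structure is required")
    if granularity == "frame":
        return [classify_superfamily(s) for s in ss_strings]
    if granularity != "centroid":
        raise ValueError(f"unknown granularity {granularity!r}")
    labels = [""] * result.n
    for fam in result.families:
        lab = classify_superfamily(ss_strings[fam.centroid])
        for m in fam.members:
            labels[m] = lab
    return labels


@dataclass
class SuperFamilyReport:
    """Per-super-family abundance (mean +/- std over the last blocks).

    ``table`` rows: label, abundance, std, members, centroid. The region
    convention used by the classifier is recorded alongside.
    """

    table: pd.DataFrame
    last_k: int
    n_conformers: int
    n_part: tuple[int, int] = N_PART
    c_part: tuple[int, int] = C_PART

    def abundance(self, label: str) -> float:
        row = self.table[self.table["label"] == label]
        return float(row["abundance"].iloc[0]) if len(row) else 0.0


def superfamily_abundance(labels: Sequence[str],
                          blocks: Optional[BlockPartition] = None,
                          last_k: int = 3,
                          cluster_result: Optional[ClusterResult] = None
                          ) -> SuperFamilyReport:
    """Super-family abundances with block-wise dispersion.

    The abundance of each label is its fraction within each of the last
    ``last_k`` blocks; the reported value is the mean over those blocks
    and the std the sample standard deviation (ddof=1) over them. When no
    block partition is given the ensemble is divided into ``last_k``
    equal consecutive blocks.
    """
    n = len(labels)
    if blocks is None:
        blocks = make_blocks(n, last_k)
    if blocks.n_frames != n:
        raise ValueError("block partition does not cover the label list")
    if last_k > blocks.n_blocks:
        raise ValueError("fewer blocks than last_k")
    labels = list(labels)
    present = [lab for lab in SUPERFAMILY_LABELS if lab in labels]
    tail = blocks.ranges[-last_k:]
    per_block = {lab: [] for lab in present}
    for lo, hi in tail:
        block = labels[lo:hi]
        for lab in present:
            per_block[lab].append(sum(1 for x in block if x == lab) / len(block))
    rows = []
    for lab in present:
        vals = np.array(per_block[lab])
        centroid = _representative_centroid(lab, labels, cluster_result)
        rows.append({
            "label": lab,
            "abundance": float(vals.mean()),
            "std": float(vals.std(ddof=1)) if last_k > 1 else 0.0,
            "members": int(sum(1 for x in labels if x == lab)),
            "centroid": centroid,
        })
    table = pd.DataFrame(rows)
    return SuperFamilyReport(table, last_k, n)


def _representative_centroid(label: str, labels: Sequence[str],
                             result: Optional[ClusterResult]) -> int:
    """Centroid of the largest family whose centroid carries ``label``."""
    if result is None:
        return -1
    for fam in result.families:  # formation order = decreasing size
        if labels[fam.centroid] == label:
            return fam.centroid
    return -1
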