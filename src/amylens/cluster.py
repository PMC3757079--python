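"""Kabsch superposition, pairwise C-alpha RMSD and greedy neighbor-count
clustering of conformer ensembles into structural families.

The clustering follows the classic trajectory-clustering protocol: count
neighbors within an RMSD cutoff (default 3.0 A), take the structure with
the most neighbors as a family centroid, remove it together with its
neighbors, and repeat on the remainder until every structure is assigned.
Neighbor counts are recomputed after each removal; ties on the count are
broken by the lowest structure index, which makes the partition
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model_io import Conformation, Ensemble

DEFAULT_CUTOFF = 3.0  # A, pairwise C-alpha RMSD dissimilarity threshold


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of two (m, 3) point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``. The
    rotation is proper (determinant +1; reflections are corrected).

    Raises
    ------
    ValueError
        For fewer than 3 points or a degenerate (collinear) selection.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must share shape (m, 3)")
    if P.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    # collinearity check: rank of the centered sets
    if min(np.linalg.matrix_rank(P0, tol=1e-8), np.linalg.matrix_rank(Q0, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd


def superpose_conformation(mobile: Conformation, reference: Conformation,
                           residue_selection: Optional[Sequence[int]] = None
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition over selected C-alpha atoms (1-based residues)."""
    sel = _selection_index(mobile.n_residues, residue_selection)
    return kabsch_superpose(mobile.ca[sel], reference.ca[sel])


def _selection_index(L: int, residue_selection: Optional[Sequence[int]]) -> np.ndarray:
    if residue_selection is None:
        return np.arange(L)
    idx = np.asarray(list(residue_selection), dtype=int) - 1
    if len(idx) == 0:
        raise ValueError("empty residue selection")
    if idx.min() < 0 or idx.max() >= L:
        raise ValueError("residue selection outside 1..L")
    return idx


@dataclass
class RMSDMatrix:
    """Symmetric pairwise C-alpha RMSD matrix with its atom selection."""

    values: np.ndarray
    selection: str = "all"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if np.any(np.abs(v - v.T) > 1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("RMSD matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("RMSD entries must be >= 0")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def rmsd_matrix(ensemble: Ensemble,
                residue_selection: Optional[Sequence[int]] = None,
                block_pairs: int = 200_000) -> RMSDMatrix:
    """All-against-all C-alpha RMSD after optimal superposition per pair.

    Each entry is the Kabsch-minimized RMSD over the selected C-alpha
    atoms; pairs are evaluated once and mirrored. Computation is batched
    (vectorized 3x3 SVDs) for speed.
    """
    sel = _selection_index(len(ensemble.sequence), residue_selection)
    X = ensemble.ca_array()[:, sel, :]
    n, m, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    G = np.einsum("nij,nij->n", Xc, Xc)  # squared norms
    out = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    for s in range(0, len(iu), block_pairs):
        i = iu[s:s + block_pairs]
        j = ju[s:s + block_pairs]
        H = np.einsum("pmi,pmj->pij", Xc[i], Xc[j])
        S = np.linalg.svd(H, compute_uv=False)
        sign = np.sign(np.linalg.det(H))
        sign[sign == 0] = 1.0
        tr = S[:, 0] + S[:, 1] + sign * S[:, 2]
        sq = np.clip((G[i] + G[j] - 2.0 * tr) / m, 0.0, None)
        out[i, j] = out[j, i] = np.sqrt(sq)
    label = "all" if residue_selection is None else f"{len(sel)} residues"
    return RMSDMatrix(out, selection=label)


@dataclass
class Family:
    """One structural family: member indices and its centroid."""

    members: list[int]
    centroid: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    """Partition of an ensemble into structural families.

    Families are in formation order, which for the greedy neighbor-count
    algorithm is also non-increasing size order.
    """

    families: list[Family]
    cutoff: float
    n: int

    def assignments(self) -> np.ndarray:
        """Per-structure family index (0-based, formation order)."""
        out = np.full(self.n, -1, dtype=int)
        for k, fam in enumerate(self.families):
            out[fam.members] = k
        return out


def daura_cluster(matrix: RMSDMatrix, cutoff: float = DEFAULT_CUTOFF) -> ClusterResult:
    """Greedy neighbor-count clustering at an RMSD cutoff.

    Iteratively, among unassigned structures, the one with the most
    unassigned neighbors within ``cutoff`` becomes a centroid and forms a
    family with those neighbors; counts are recomputed after each removal.
    Ties are broken by the lowest structure index. Every structure ends up
    in exactly one family (singletons form one-member families).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    D = matrix.values
    n = matrix.n
    adj = D < cutoff
    np.fill_diagonal(adj, True)
    active = np.ones(n, dtype=bool)
    families: list[Family] = []
    while active.any():
        counts = np.where(active, (adj & active).sum(axis=1), -1)
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(adj[centroid] & active)[0]
        families.append(Family(members.tolist(), centroid))
        active[members] = False
    return ClusterResult(families, float(cutoff), n)


def top_families(result: ClusterResult, min_fraction: float = 0.01,
                 max_k: int = 15) -> list[Family]:
    """Most populated families: fraction >= ``min_fraction``, at most ``max_k``."""
    keep = [f for f in result.families if f.size / result.n >= min_fraction]
    keep.sort(key=lambda f: -f.size)
    return keep[:max_k]
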