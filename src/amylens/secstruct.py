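"""Secondary-structure assignment from backbone coordinates.

Two assignment modes are provided:

* ``hbond`` — a DSSP-style pattern assigner on Kabsch-Sander backbone
  hydrogen bonds (alpha-helix from consecutive i->i+4 bonds, 3-10 helix
  from i->i+3, sheet from bridge ladders, turns from single turn bonds);
* ``dihedral`` — a Ramachandran-region assigner against the generator's
  canonical helix/strand/turn dihedrals, used for ground-truthing
  synthetic ensembles.

Codes: H (alpha-helix), G (3-10 helix), E (strand), B (isolated bridge),
T (turn), C (coil). Aggregate classes: helix = {H, G}, sheet = {E, B},
turn = {T}, coil = {C}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _tables
from ._geometry import angular_distance
from .model_io import C_, H_, N_, O_, Conformation, Ensemble

SS_CODES = "HGEBTC"
CLASS_OF_CODE = {"H": "helix", "G": "helix", "E": "sheet", "B": "sheet",
                 "T": "turn", "C": "coil"}
CLASSES = ("helix", "sheet", "turn", "coil")

KS_Q1Q2_FACTOR = 0.084 * 332.0  # kcal/mol * A, Kabsch-Sander prefactor
KS_CUTOFF = -0.5                # kcal/mol
KS_NO_BOND_DISTANCE = 7.0       # A, N...O beyond which no bond is evaluated
MIN_ATOM_SEPARATION = 0.3       # A, below this the geometry is unphysical


def hbond_energy(n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray) -> float:
    """Kabsch-Sander electrostatic hydrogen-bond energy in kcal/mol.

    ``n``/``h`` are the donor amide N and H positions, ``c``/``o`` the
    acceptor carbonyl C and O. Returns 0 when N...O >= 7 A. A bond is
    declared when the energy is below -0.5 kcal/mol.
    """
    r_on = float(np.linalg.norm(o - n))
    if r_on >= KS_NO_BOND_DISTANCE:
        return 0.0
    r_ch = float(np.linalg.norm(c - h))
    r_oh = float(np.linalg.norm(o - h))
    r_cn = float(np.linalg.norm(c - n))
    if min(r_on, r_ch, r_oh, r_cn) < MIN_ATOM_SEPARATION:
        raise ValueError("near-coincident atoms in hydrogen-bond geometry")
    return KS_Q1Q2_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def hbond_matrix(conf: Conformation) -> np.ndarray:
    """Boolean matrix A[acceptor, donor] of backbone H-bonds (0-based).

    Donors without an amide H (residue 1, prolines, unset H slots) never
    donate; pairs with |i - j| < 2 are not evaluated.
    """
    X = conf.coords
    L = conf.n_residues
    has_h = ~np.isnan(X[:, H_, 0])
    A = np.zeros((L, L), dtype=bool)
    for acc in range(L):
        o = X[acc, O_]
        c = X[acc, C_]
        for don in range(L):
            if abs(don - acc) < 2 or not has_h[don]:
                continue
            e = hbond_energy(X[don, N_], X[don, H_], c, o)
            if e < KS_CUTOFF:
                A[acc, don] = True
    return A


def _assign_hbond(conf: Conformation) -> str:
    A = hbond_matrix(conf)
    L = conf.n_residues
    ss = np.array(list("C" * L))

    def turn_bond(i, k):
        return i + k < L and A[i, i + k]

    # alpha helix: two consecutive i->i+4 turns cover residues i+1..i+4
    helix4 = np.array([turn_bond(i, 4) for i in range(L)])
    is_h = np.zeros(L, dtype=bool)
    for i in range(L - 1):
        if helix4[i] and helix4[i + 1]:
            is_h[i + 1:i + 5] = True

    # bridges (antiparallel and parallel), excluding near-diagonal
    def hb(acc, don):
        return 0 <= acc < L and 0 <= don < L and A[acc, don]

    bridge = np.zeros((L, L), dtype=bool)
    for i in range(L):
        for j in range(i + 3, L):
            anti = (A[i, j] and A[j, i]) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            para = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            if anti or para:
                bridge[i, j] = bridge[j, i] = True

    # ladders: bridges with a neighboring bridge on an adjacent diagonal
    in_ladder = np.zeros((L, L), dtype=bool)
    for i in range(L):
        for j in range(i + 3, L):
            if not bridge[i, j]:
                continue
            for di, dj in ((1, -1), (1, 1), (-1, 1), (-1, -1)):
                p, q = i + di, j + dj
                if 0 <= p < L and 0 <= q < L and bridge[p, q]:
                    in_ladder[i, j] = in_ladder[j, i] = True
                    break

    is_e = in_ladder.any(axis=1)
    is_b = bridge.any(axis=1) & ~is_e

    # 3-10 helix from two consecutive i->i+3 turns
    helix3 = np.array([turn_bond(i, 3) for i in range(L)])
    is_g = np.zeros(L, dtype=bool)
    for i in range(L - 1):
        if helix3[i] and helix3[i + 1]:
            is_g[i + 1:i + 4] = True

    # turns: any single i->i+3/4/5 bond marks the enclosed residues
    is_t = np.zeros(L, dtype=bool)
    for i in range(L):
        for k in (3, 4, 5):
            if turn_bond(i, k):
                is_t[i + 1:i + k] = True

    ss[is_t] = "T"
    ss[is_g] = "G"
    ss[is_b] = "B"
    ss[is_e] = "E"
    ss[is_h] = "H"
    return "".join(ss)


_TURN_ANCHORS = tuple(_tables.BETA_TURN_PHI_PSI) + tuple(
    v for tbl in _tables.TURN_DIHEDRALS.values() for v in tbl
)


def _assign_dihedral(conf: Conformation) -> str:
    phi, psi, _ = conf.backbone_dihedrals()
    tol = _tables.DIHEDRAL_TOLERANCE
    ss = []

    def near(target, f, s):
        df = angular_distance(f, target[0])
        ds = angular_distance(s, target[1])
        return np.hypot(df, ds) <= tol

    for i in range(conf.n_residues):
        f, s = phi[i], psi[i]
        if not (np.isfinite(f) and np.isfinite(s)):
            ss.append("C")
        elif near(_tables.HELIX_PHI_PSI, f, s):
            ss.append("H")
        elif near(_tables.STRAND_PHI_PSI, f, s):
            ss.append("E")
        elif any(near(t, f, s) for t in _TURN_ANCHORS):
            ss.append("T")
        else:
            ss.append("C")
    return "".join(ss)


def assign_ss(conf: Conformation, mode: str = "hbond") -> str:
    """Per-residue secondary-structure string for one conformation."""
    if mode == "hbond":
        return _assign_hbond(conf)
    if mode == "dihedral":
        return _assign_dihedral(conf)
    raise ValueError(f"unknown assignment mode {mode!r}")


def aggregate_class(code: str) -> str:
    """Map a one-letter SS code to its aggregate class."""
    return CLASS_OF_CODE[code]


@dataclass
class SSProfile:
    """Per-residue class propensities and ensemble-level class fractions."""

    per_residue: pd.DataFrame  # index: residue 1..L, columns: CLASSES
    fractions: dict[str, float]
    mode: str
    n_conformers: int

    def merged_3class(self) -> dict[str, float]:
        """Helix / sheet / turn+coil fractions (turn and coil pooled)."""
        return {
            "helix": self.fractions["helix"],
            "sheet": self.fractions["sheet"],
            "turn+coil": self.fractions["turn"] + self.fractions["coil"],
        }


def ss_profile(ensemble: Ensemble, mode: str = "hbond",
               ss_strings: list[str] | None = None) -> SSProfile:
    """Position-dependent class propensities over an ensemble.

    Per residue, the frequency of each aggregate class across conformers;
    ensemble fractions are the residue-averaged propensities. Precomputed
    ``ss_strings`` may be passed to avoid re-assignment.
    """
    if ss_strings is None:
        ss_strings = [assign_ss(c, mode) for c in ensemble]
    L = len(ensemble.sequence)
    counts = np.zeros((L, len(CLASSES)))
    class_idx = {c: k for k, c in enumerate(CLASSES)}
    for s in ss_strings:
        for i, code in enumerate(s):
            counts[i, class_idx[CLASS_OF_CODE[code]]] += 1
    props = counts / len(ss_strings)
    df = pd.DataFrame(props, index=np.arange(1, L + 1), columns=CLASSES)
    df.index.name = "residue"
    fractions = {c: float(df[c].mean()) for c in CLASSES}
    return SSProfile(df, fractions, mode, len(ss_strings))
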