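"""Core domain types and multi-model PDB / FASTA input-output.

The objects here describe one 37-residue amylin-like peptide
(`PeptideSequence`), a single backbone conformer (`Conformation`) and an
ordered collection of conformers (`Ensemble`), plus readers/writers for
multi-model PDB files and tagged single-entry FASTA sequence records.

Residue indexing is 1-based everywhere, matching the conventional
"residues 1-37" numbering of the peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from ._geometry import dihedral, reconstruct_amide_h

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_3TO1 = {v: k for k, v in _1TO3.items()}

#: atom slots of the backbone representation, in storage order
ATOM_NAMES = ("N", "H", "CA", "C", "O", "CB")
_ELEMENTS = ("N", "H", "C", "C", "O", "C")

N_, H_, CA_, C_, O_, CB_ = range(6)


class SequenceMismatchError(ValueError):
    """PDB residue identity disagrees with the supplied sequence."""


class MissingAtomError(ValueError):
    """A required backbone heavy atom is absent from a PDB model."""


@dataclass(frozen=True)
class PeptideSequence:
    """One peptide variant: residues, terminal chemistry, disulfide topology.

    Parameters
    ----------
    residues : str
        One-letter amino-acid codes, N- to C-terminus.
    c_amidated : bool
        True when the C-terminus is an amide (no carboxylate charge).
    disulfide : tuple of int, optional
        1-based indices of a single intrachain Cys-Cys bond.
    name : str
        Variant label, e.g. ``"human"``.
    """

    residues: str
    c_amidated: bool = False
    disulfide: Optional[tuple[int, int]] = None
    name: str = ""

    def __post_init__(self):
        bad = [r for r in self.residues if r not in AA_ALPHABET]
        if bad:
            raise ValueError(f"unknown residue code(s): {bad}")
        if self.disulfide is not None:
            i, j = self.disulfide
            if i == j:
                raise ValueError("disulfide indices must be distinct")
            for k in (i, j):
                if not 1 <= k <= len(self.residues):
                    raise ValueError(f"disulfide index {k} outside 1..{len(self.residues)}")
                if self.residues[k - 1] != "C":
                    raise ValueError(f"disulfide residue {k} is {self.residues[k-1]}, not C")

    def __len__(self) -> int:
        return len(self.residues)

    def has_amide_h(self, i: int) -> bool:
        """Whether residue ``i`` (1-based) carries a backbone amide H."""
        return i > 1 and self.residues[i - 1] != "P"


@dataclass
class Conformation:
    """Backbone coordinates of one conformer.

    ``coords`` has shape (L, 6, 3) with the atom axis ordered as
    ``ATOM_NAMES`` = (N, H, CA, C, O, CB); absent atoms (amide H of
    residue 1 and of prolines, CB of glycine) are NaN rows.
    """

    coords: np.ndarray
    label: str = ""
    flags: tuple = ()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (6, 3):
            raise ValueError("coords must have shape (L, 6, 3)")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def ca(self) -> np.ndarray:
        """(L, 3) array of C-alpha positions."""
        return self.coords[:, CA_, :]

    def backbone_dihedrals(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-residue (phi, psi, omega) in degrees; undefined entries NaN.

        omega[i] is the CA(i-1)-C(i-1)-N(i)-CA(i) torsion, NaN for i=1.
        """
        L = self.n_residues
        phi = np.full(L, np.nan)
        psi = np.full(L, np.nan)
        omega = np.full(L, np.nan)
        X = self.coords
        for i in range(L):
            if i > 0:
                phi[i] = dihedral(X[i - 1, C_], X[i, N_], X[i, CA_], X[i, C_])
                omega[i] = dihedral(X[i - 1, CA_], X[i - 1, C_], X[i, N_], X[i, CA_])
            if i < L - 1:
                psi[i] = dihedral(X[i, N_], X[i, CA_], X[i, C_], X[i + 1, N_])
        return phi, psi, omega

    def validate(self, sequence: Optional[PeptideSequence] = None) -> None:
        """Check bonded-geometry and steric invariants; raise on violation."""
        X = self.coords
        d_nca = np.linalg.norm(X[:, CA_] - X[:, N_], axis=1)
        d_cac = np.linalg.norm(X[:, C_] - X[:, CA_], axis=1)
        if np.any((d_nca < 1.2) | (d_nca > 1.8)):
            raise ValueError("N-CA bond length outside 1.2-1.8 A")
        if np.any((d_cac < 1.2) | (d_cac > 1.8)):
            raise ValueError("CA-C bond length outside 1.2-1.8 A")
        if self.min_interatomic_distance() < 0.5:
            raise ValueError("atoms closer than 0.5 A")
        if sequence is not None and len(sequence) != self.n_residues:
            raise ValueError("sequence length does not match coordinates")

    def min_interatomic_distance(self, exclude_bonded: bool = True) -> float:
        """Smallest distance between any two (non-directly-bonded) atoms."""
        present = ~np.isnan(self.coords[:, :, 0])
        ri, ai = np.nonzero(present)
        pts = self.coords[ri, ai]
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if exclude_bonded:
            bonded = np.zeros((6, 6), dtype=bool)
            for a, b in ((N_, H_), (N_, CA_), (CA_, C_), (C_, O_), (CA_, CB_)):
                bonded[a, b] = bonded[b, a] = True
            same = ri[:, None] == ri[None, :]
            mask = same & bonded[ai[:, None], ai[None, :]]
            peptide = (
                (ri[None, :] - ri[:, None] == 1)
                & (ai[:, None] == C_)
                & (ai[None, :] == N_)
            )
            mask |= peptide | peptide.T
            d[mask] = np.inf
        return float(d.min())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        """Return a rigidly moved copy (NaN slots stay NaN)."""
        out = self.coords @ rotation.T + translation
        return Conformation(out, label=self.label, flags=self.flags)


@dataclass
class Ensemble:
    """Ordered conformations of one peptide, with optional timestamps."""

    sequence: PeptideSequence
    conformations: list[Conformation]
    times: Optional[np.ndarray] = None  # ns, monotone
    temperature: Optional[float] = None  # Kelvin annotation

    def __post_init__(self):
        if len(self.conformations) < 1:
            raise ValueError("ensemble must contain at least one conformation")
        L = len(self.sequence)
        for c in self.conformations:
            if c.n_residues != L:
                raise ValueError("conformation length does not match sequence")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.conformations):
                raise ValueError("times length mismatch")
            if np.any(np.diff(self.times) < 0):
                raise ValueError("timestamps must be monotone")

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.conformations)

    def __getitem__(self, i: int) -> Conformation:
        return self.conformations[i]

    def ca_array(self) -> np.ndarray:
        """(n, L, 3) stack of C-alpha coordinates."""
        return np.stack([c.ca for c in self.conformations])

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        return Ensemble(
            self.sequence,
            [self.conformations[i] for i in indices],
            times=None if self.times is None else self.times[list(indices)],
            temperature=self.temperature,
        )


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write a multi-model PDB file (one MODEL per conformation)."""
    if not str(path):
        raise ValueError("empty output path")
    seq = ensemble.sequence
    L = len(seq)
    mask = ~np.isnan(ensemble.conformations[0].coords[:, :, 0])
    n_atoms = int(mask.sum())
    template = struc.AtomArray(n_atoms)
    res_id = []
    res_name = []
    atom_name = []
    element = []
    for i in range(L):
        for a in range(6):
            if mask[i, a]:
                res_id.append(i + 1)
                res_name.append(_1TO3[seq.residues[i]])
                atom_name.append(ATOM_NAMES[a])
                element.append(_ELEMENTS[a])
    template.res_id = np.array(res_id)
    template.res_name = np.array(res_name)
    template.atom_name = np.array(atom_name)
    template.element = np.array(element)
    template.chain_id = np.full(n_atoms, "A")
    template.hetero = np.full(n_atoms, False)
    coords = np.stack(
        [c.coords[mask] for c in ensemble.conformations]
    )
    stack = struc.AtomArrayStack(len(ensemble), n_atoms)
    for annot in ("res_id", "res_name", "atom_name", "element", "chain_id", "hetero"):
        setattr(stack, annot, getattr(template, annot))
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble(path, sequence: PeptideSequence) -> Ensemble:
    """Read a multi-model PDB into an `Ensemble`.

    Residues are matched to ``sequence`` by index; missing amide hydrogens
    are rebuilt geometrically in the C(i-1)-N-CA plane.

    Raises
    ------
    SequenceMismatchError
        If a residue name disagrees with the sequence.
    MissingAtomError
        If a backbone heavy atom (N, CA, C, O) is absent, reporting the
        model and residue index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    L = len(sequence)
    confs = []
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m)
        coords = np.full((L, 6, 3), np.nan)
        for i in range(1, L + 1):
            sel = atoms.res_id == i
            if not np.any(sel):
                raise MissingAtomError(f"model {m}, residue {i}: residue absent")
            names = atoms.atom_name[sel]
            rname = atoms.res_name[sel][0]
            expected = _1TO3[sequence.residues[i - 1]]
            if rname != expected:
                raise SequenceMismatchError(
                    f"model {m}, residue {i}: file has {rname}, sequence expects {expected}"
                )
            xyz = atoms.coord[sel]
            for a, aname in enumerate(ATOM_NAMES):
                hit = names == aname
                if np.any(hit):
                    coords[i - 1, a] = xyz[np.argmax(hit)]
            for a, aname in ((N_, "N"), (CA_, "CA"), (C_, "C"), (O_, "O")):
                if np.any(np.isnan(coords[i - 1, a])):
                    raise MissingAtomError(f"model {m}, residue {i}: missing atom {aname}")
        for i in range(2, L + 1):
            if sequence.has_amide_h(i) and np.any(np.isnan(coords[i - 1, H_])):
                coords[i - 1, H_] = reconstruct_amide_h(
                    coords[i - 1, N_], coords[i - 1, CA_], coords[i - 2, C_]
                )
        confs.append(Conformation(coords, label=f"model_{m}"))
    return Ensemble(sequence, confs)


# ---------------------------------------------------------------------------
# FASTA sequence records
# ---------------------------------------------------------------------------

def write_sequence(seq: PeptideSequence, path) -> None:
    """Write a single-entry FASTA with ``amidated=``/``ss_bond=`` header tags."""
    tags = [seq.name or "peptide"]
    tags.append(f"amidated={'true' if seq.c_amidated else 'false'}")
    if seq.disulfide:
        tags.append(f"ss_bond={seq.disulfide[0]}-{seq.disulfide[1]}")
    with open(path, "w") as fh:
        fh.write(">" + " ".join(tags) + "\n")
        fh.write(seq.residues + "\n")


def read_sequence(path) -> PeptideSequence:
    """Read a tagged single-entry FASTA sequence record."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError("not a FASTA record")
    header = lines[0][1:].split()
    residues = "".join(lines[1:])
    name = header[0] if header and "=" not in header[0] else ""
    amidated = False
    disulfide = None
    for tag in header:
        if tag.startswith("amidated="):
            amidated = tag.split("=", 1)[1].lower() == "true"
        elif tag.startswith("ss_bond="):
            i, j = tag.split("=", 1)[1].split("-")
            disulfide = (int(i), int(j))
    return PeptideSequence(residues, c_amidated=amidated, disulfide=disulfide, name=name)


# ---------------------------------------------------------------------------
# Formal charge
# ---------------------------------------------------------------------------

#: default protonation convention at neutral pH: basic K/R charged, His
#: neutral, acidic D/E deprotonated, free N-terminus protonated, C-terminus
#: carboxylate unless amidated.
DEFAULT_PROTONATION = {
    "K": 1, "R": 1, "H": 0, "D": -1, "E": -1,
    "nterm": 1, "cterm": -1,
}


def formal_charge(seq: PeptideSequence, convention: Optional[dict] = None) -> int:
    """Signed formal charge of the peptide under a protonation convention.

    ``convention`` maps residue letters and the special keys ``"nterm"`` /
    ``"cterm"`` to integer charges. An amidated C-terminus contributes 0
    regardless of the ``"cterm"`` entry.
    """
    conv = dict(DEFAULT_PROTONATION)
    if convention:
        conv.update(convention)
    q = conv.get("nterm", 0)
    if not seq.c_amidated:
        q += conv.get("cterm", 0)
    for r in seq.residues:
        q += conv.get(r, 0)
    return int(q)
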