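"""Seeded synthetic conformer ensembles of a 37-residue amylin-like peptide.

Ensembles are mixtures of three backbone motifs observed for IAPP
monomers:

* ``helix-coil``    — coil 1-7, alpha-helix 8-17, long coil 18-37;
* ``helix-hairpin`` — the same N-terminal helix plus a short C-terminal
  beta-hairpin (strands 25-27 and 33-36, loop 28-31);
* ``beta-hairpin``  — an extended hairpin (strands 9-17 and 23-33,
  turn 18-22).

Conformers are built residue-by-residue from internal coordinates
(ideal bond lengths/angles, per-residue phi/psi), jittered in dihedral
space, and hairpin motifs are refined by local coordinate descent so the
intended cross-strand hydrogen bonds actually form. Every draw is
controlled by a single integer seed; identical seeds give bit-identical
ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _tables
from ._geometry import (
    ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_C_N_CA, ANGLE_N_CA_C,
    BOND_CA_C, BOND_C_N, BOND_C_O, BOND_N_CA,
    amide_h_fast, cbeta_fast, place_cbeta, place_fast, reconstruct_amide_h,
)
from .model_io import (
    CA_, C_, CB_, H_, N_, O_,
    Conformation, Ensemble, PeptideSequence,
)

MOTIF_LABELS = ("helix-coil", "helix-hairpin", "beta-hairpin")

#: per-variant preset mixture weights (super-family abundances of the
#: four IAPP variants; the non-amyloidogenic rat/pig ensembles carry no
#: beta-hairpin component)
VARIANT_WEIGHTS = {
    "pig": {"helix-coil": 0.87, "helix-hairpin": 0.13},
    "rat": {"helix-coil": 0.87, "helix-hairpin": 0.13},
    "cat": {"helix-coil": 0.28, "helix-hairpin": 0.25, "beta-hairpin": 0.47},
    "human": {"helix-coil": 0.15, "helix-hairpin": 0.09, "beta-hairpin": 0.75},
}

#: preset sequences (one-letter), all amidated with a 2-7 disulfide.
#: human/rat/cat are the literature variants; the pig entry applies the
#: two pig-defining substitutions (S20R, N31K) on the rat scaffold and is
#: an approximation of the true pig sequence.
VARIANT_SEQUENCES = {
    "human": "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY",
    "rat":   "KCNTATCATQRLANFLVRSSNNLGPVLPPTNVGSNTY",
    "cat":   "KCNTATCATQRLANFLIRSSNNLGAILSPTNVGSNTY",
    "pig":   "KCNTATCATQRLANFLVRSRNNLGPVLPPTKVGSNTY",
}


def preset_sequence(variant: str) -> PeptideSequence:
    """PeptideSequence for a named variant preset."""
    if variant not in VARIANT_SEQUENCES:
        raise ValueError(f"unknown variant preset {variant!r}")
    return PeptideSequence(
        VARIANT_SEQUENCES[variant], c_amidated=True, disulfide=(2, 7), name=variant
    )


@dataclass(frozen=True)
class Segment:
    """A contiguous residue range with one dihedral regime."""

    start: int  # 1-based inclusive
    stop: int   # 1-based inclusive
    kind: str   # helix | strand | turn | coil
    sigma: float = 0.0


@dataclass(frozen=True)
class MotifSpec:
    """Dihedral blueprint of one motif.

    ``segments`` covers residues 1..L without overlap. ``closure_residues``
    is the inclusive range whose phi/psi are refined for hairpin closure;
    ``strands`` the two strand ranges defining the cross-strand register.
    """

    label: str
    segments: tuple[Segment, ...]
    closure_residues: Optional[tuple[int, int]] = None
    strands: Optional[tuple[tuple[int, int], tuple[int, int]]] = None

    def __post_init__(self):
        covered = []
        for s in self.segments:
            if s.sigma < 0:
                raise ValueError("jitter sigma must be >= 0")
            covered.extend(range(s.start, s.stop + 1))
        if sorted(covered) != list(range(1, max(covered) + 1)):
            raise ValueError("segments must cover 1..L without overlap")

    @property
    def n_residues(self) -> int:
        return max(s.stop for s in self.segments)


def make_motif(label: str, sigma: float = 0.0, n_residues: int = 37) -> MotifSpec:
    """Canonical MotifSpec for one of the three motif labels.

    Helix segments use (-57, -47), strand segments (-139, 135); turn and
    loop segments take the bundled closure-refined turn dihedrals, coil
    segments are sampled per conformer from the bundled coil set.
    """
    L = n_residues
    if label == "helix-coil":
        segs = (
            Segment(1, 7, "coil", sigma),
            Segment(8, 17, "helix", sigma),
            Segment(18, L, "coil", sigma),
        )
        return MotifSpec(label, segs)
    if label == "helix-hairpin":
        segs = (
            Segment(1, 7, "coil", sigma),
            Segment(8, 17, "helix", sigma),
            Segment(18, 24, "coil", sigma),
            Segment(25, 27, "strand", sigma),
            Segment(28, 32, "turn", sigma),
            Segment(33, 36, "strand", sigma),
            Segment(37, L, "coil", sigma),
        )
        return MotifSpec(label, segs, closure_residues=(28, 32),
                         strands=((25, 27), (33, 36)))
    if label == "beta-hairpin":
        segs = (
            Segment(1, 8, "coil", sigma),
            Segment(9, 17, "strand", sigma),
            Segment(18, 22, "turn", sigma),
            Segment(23, 33, "strand", sigma),
            Segment(34, L, "coil", sigma),
        )
        return MotifSpec(label, segs, closure_residues=(18, 22),
                         strands=((9, 17), (23, 33)))
    raise ValueError(f"unknown motif label {label!r}")


@dataclass(frozen=True)
class MixtureSpec:
    """A weighted mixture of motifs to sample into an ensemble."""

    components: tuple[tuple[MotifSpec, float], ...]
    n_conformers: int
    seed: int
    block_structure: Optional[int] = None

    def __post_init__(self):
        w = np.array([wt for _, wt in self.components], dtype=float)
        if np.any(w < 0):
            raise ValueError("mixture weights must be >= 0")
        if w.sum() <= 0:
            raise ValueError("mixture weights must not all be zero")
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([wt for _, wt in self.components], dtype=float)
        return w / w.sum()


def variant_mixture(variant: str, n_conformers: int, sigma: float = 3.0,
                    seed: int = 0, block_structure: Optional[int] = None) -> MixtureSpec:
    """MixtureSpec for a named variant preset at the preset weights."""
    weights = VARIANT_WEIGHTS[variant]
    comps = tuple(
        (make_motif(lbl, sigma), w) for lbl, w in weights.items()
    )
    return MixtureSpec(comps, n_conformers, seed, block_structure)


# ---------------------------------------------------------------------------
# Chain construction
# ---------------------------------------------------------------------------

def _backbone_positions(phi: np.ndarray, psi: np.ndarray, omega: np.ndarray,
                        upto: Optional[int] = None,
                        prefix: Optional[tuple] = None):
    """N/CA/C positions for residues 0..upto-1 (0-based) by NeRF extension.

    ``prefix`` optionally supplies already-built (N, CA, C, start) arrays so
    the chain is only rebuilt from residue ``start`` on.
    """
    L = len(phi)
    m = L if upto is None else upto
    if prefix is None:
        N = np.empty((m, 3))
        CA = np.empty((m, 3))
        C = np.empty((m, 3))
        N[0] = (0.0, 0.0, 0.0)
        CA[0] = (BOND_N_CA, 0.0, 0.0)
        theta = np.deg2rad(ANGLE_N_CA_C)
        C[0] = (BOND_N_CA - BOND_CA_C * np.cos(theta),
                BOND_CA_C * np.sin(theta), 0.0)
        start = 1
    else:
        N0, CA0, C0, start = prefix
        N = np.empty((m, 3))
        CA = np.empty((m, 3))
        C = np.empty((m, 3))
        N[:start] = N0[:start]
        CA[:start] = CA0[:start]
        C[:start] = C0[:start]
    phi = [float(x) for x in phi]
    psi = [float(x) for x in psi]
    omega = [float(x) for x in omega]
    i0 = start - 1
    n_ = (N[i0, 0], N[i0, 1], N[i0, 2])
    ca_ = (CA[i0, 0], CA[i0, 1], CA[i0, 2])
    c_ = (C[i0, 0], C[i0, 1], C[i0, 2])
    for i in range(start, m):
        n2 = place_fast(*n_, *ca_, *c_, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca2 = place_fast(*ca_, *c_, *n2, BOND_N_CA, ANGLE_C_N_CA, omega[i])
        c2 = place_fast(*c_, *n2, *ca2, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        N[i] = n2
        CA[i] = ca2
        C[i] = c2
        n_, ca_, c_ = n2, ca2, c2
    return N, CA, C


def _place_oxygen(N, CA, C, psi, i, L):
    psi_i = float(psi[i])
    if i == L - 1 or not np.isfinite(psi_i):
        psi_i = 150.0  # virtual psi for the terminal carbonyl
    return place_fast(
        N[i, 0], N[i, 1], N[i, 2], CA[i, 0], CA[i, 1], CA[i, 2],
        C[i, 0], C[i, 1], C[i, 2], BOND_C_O, ANGLE_CA_C_O, psi_i - 180.0,
    )


def build_chain(seq: PeptideSequence, phi, psi, omega=None) -> Conformation:
    """Build an all-atom backbone Conformation from per-residue dihedrals.

    Parameters
    ----------
    seq : PeptideSequence
    phi, psi : array-like, length L, degrees
        ``phi[0]`` and ``psi[-1]`` may be NaN (they are undefined).
    omega : array-like, optional
        Peptide-bond torsion preceding each residue; defaults to 180
        (all-trans).

    The recomputed dihedrals of the returned conformation match the
    inputs to well below 1e-4 degrees; the carbonyl O lies in the
    CA-C-N(i+1) plane.
    """
    L = len(seq)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if len(phi) != L or len(psi) != L:
        raise ValueError(f"need {L} phi/psi values, got {len(phi)}/{len(psi)}")
    if omega is None:
        omega = np.full(L, 180.0)
    else:
        omega = np.asarray(omega, dtype=float)
        if len(omega) != L:
            raise ValueError(f"need {L} omega values, got {len(omega)}")
    N, CA, C = _backbone_positions(phi, psi, omega)
    coords = np.full((L, 6, 3), np.nan)
    coords[:, N_] = N
    coords[:, CA_] = CA
    coords[:, C_] = C
    for i in range(L):
        coords[i, O_] = _place_oxygen(N, CA, C, psi, i, L)
        if seq.has_amide_h(i + 1):
            coords[i, H_] = amide_h_fast(
                N[i, 0], N[i, 1], N[i, 2], CA[i, 0], CA[i, 1], CA[i, 2],
                C[i - 1, 0], C[i - 1, 1], C[i - 1, 2],
            )
        if seq.residues[i] != "G":
            coords[i, CB_] = cbeta_fast(
                N[i, 0], N[i, 1], N[i, 2], CA[i, 0], CA[i, 1], CA[i, 2],
                C[i, 0], C[i, 1], C[i, 2],
            )
    return Conformation(coords)


# ---------------------------------------------------------------------------
# Dihedral drawing
# ---------------------------------------------------------------------------

def _base_dihedrals(motif: MotifSpec, rng: Optional[np.random.Generator],
                    seq: Optional[PeptideSequence] = None):
    """Target (phi, psi) arrays for a motif; coil residues need ``rng``.

    With ``seq`` given, hairpin turn segments use the sequence-adapted
    closure-refined dihedrals (cached per motif/sequence) instead of the
    raw bundled table, so registers shifted by prolines still close.
    """
    L = motif.n_residues
    phi = np.empty(L)
    psi = np.empty(L)
    coil_set = np.asarray(_tables.COIL_PHI_PSI)
    for seg in motif.segments:
        idx = np.arange(seg.start - 1, seg.stop)
        if seg.kind == "helix":
            phi[idx], psi[idx] = _tables.HELIX_PHI_PSI
        elif seg.kind == "strand":
            phi[idx], psi[idx] = _tables.STRAND_PHI_PSI
        elif seg.kind == "turn":
            table = _tables.TURN_DIHEDRALS[motif.label]
            if len(table) != len(idx):
                raise ValueError("turn table length mismatch")
            for k, i in enumerate(idx):
                phi[i], psi[i] = table[k]
        elif seg.kind == "coil":
            if rng is None:
                picks = np.zeros(len(idx), dtype=int)
            else:
                picks = rng.integers(0, len(coil_set), size=len(idx))
            phi[idx] = coil_set[picks, 0]
            psi[idx] = coil_set[picks, 1]
        else:
            raise ValueError(f"unknown segment kind {seg.kind!r}")
    if seq is not None and motif.closure_residues is not None:
        for i, f, s in _refined_closure(motif, seq):
            phi[i - 1], psi[i - 1] = f, s
    return phi, psi


def _jitter(motif: MotifSpec, phi, psi, rng: np.random.Generator):
    phi = phi.copy()
    psi = psi.copy()
    for seg in motif.segments:
        if seg.sigma > 0:
            idx = np.arange(seg.start - 1, seg.stop)
            phi[idx] += rng.normal(0.0, seg.sigma, size=len(idx))
            psi[idx] += rng.normal(0.0, seg.sigma, size=len(idx))
    return phi, psi


# ---------------------------------------------------------------------------
# Hairpin closure
# ---------------------------------------------------------------------------

HBOND_TARGET = 1.95  # A, ideal O...H distance
KS_CUTOFF = -0.5     # kcal/mol, Kabsch-Sander hydrogen-bond threshold


def hbond_pairs(motif: MotifSpec, seq: PeptideSequence) -> list[tuple[int, int]]:
    """Intended cross-strand H-bonded residue pairs, innermost first.

    In an antiparallel hairpin, directly H-bonded pairs alternate along
    the register. Two alternations (register offsets 0 and 1, allowing a
    one-residue spill past the nominal strand bounds) are scored by the
    number of realizable donor directions — prolines donate nothing — and
    the better one is returned.
    """
    if motif.strands is None:
        return []
    (a1, b1), (a2, b2) = motif.strands
    L = len(seq)
    best, best_score = None, -1
    for off in (0, 1):
        pairs = []
        i, j = b1 - off, a2 + off
        while i >= a1 - 1 and j <= min(b2 + 1, L) and i >= 1:
            pairs.append((i, j))
            i -= 2
            j += 2
        score = sum(
            int(seq.has_amide_h(i)) + int(seq.has_amide_h(j)) for i, j in pairs
        )
        if score > best_score:
            best, best_score = pairs, score
    return best


def _pair_directions(pairs, seq):
    """(donor, acceptor) 1-based index tuples, innermost first."""
    dirs = []
    for i, j in pairs:
        if seq.has_amide_h(i):
            dirs.append((i, j))
        if seq.has_amide_h(j):
            dirs.append((j, i))
    return dirs


def _closure_geometry(N, CA, C, psi, directions, L):
    """O...H distances for each (donor, acceptor) direction."""
    out = np.empty(len(directions))
    for k, (don, acc) in enumerate(directions):
        d, a = don - 1, acc - 1
        hx, hy, hz = amide_h_fast(
            N[d, 0], N[d, 1], N[d, 2], CA[d, 0], CA[d, 1], CA[d, 2],
            C[d - 1, 0], C[d - 1, 1], C[d - 1, 2],
        )
        ox, oy, oz = _place_oxygen(N, CA, C, psi, a, L)
        out[k] = np.sqrt((ox - hx) ** 2 + (oy - hy) ** 2 + (oz - hz) ** 2)
    return out


def _ks_energies(conf: Conformation, directions) -> np.ndarray:
    from .secstruct import hbond_energy  # local import, no cycle at module load

    X = conf.coords
    out = np.empty(len(directions))
    for k, (don, acc) in enumerate(directions):
        out[k] = hbond_energy(
            X[don - 1, N_], X[don - 1, H_], X[acc - 1, C_], X[acc - 1, O_]
        )
    return out


def closure_ok(conf: Conformation, motif: MotifSpec, seq: PeptideSequence) -> bool:
    """Whether the two innermost realizable cross-strand H-bonds are formed."""
    pairs = hbond_pairs(motif, seq)
    if not pairs:
        return True
    dirs = _pair_directions(pairs, seq)
    if len(dirs) < 2:
        return False
    try:
        e = _ks_energies(conf, dirs[:2])
    except ValueError:
        return False  # degenerate geometry cannot count as closed
    return bool(np.all(e < KS_CUTOFF))


def refine_closure(conf: Conformation, motif: MotifSpec, seq: PeptideSequence,
                   max_iter: int = 500, steric: bool = True,
                   steps=(20.0, 10.0, 5.0, 2.0, 1.0, 0.5)) -> Conformation:
    """Refine the closure residues' phi/psi to form the cross-strand H-bonds.

    Coordinate descent minimizes the sum of |d(O...H) - 1.95 A| over the
    intended cross-strand donor/acceptor directions (plus a soft steric
    penalty unless ``steric`` is disabled for warm starts). Motifs without
    a closure range are returned unchanged. Non-convergence (the innermost
    bonds still above the Kabsch-Sander cutoff) is flagged with
    ``"unclosed"`` on the returned conformation rather than raised.
    """
    if motif.closure_residues is None:
        return conf
    pairs = hbond_pairs(motif, seq)
    dirs = _pair_directions(pairs, seq)
    phi, psi, omega = conf.backbone_dihedrals()
    omega = np.where(np.isfinite(omega), omega, 180.0)

    def converged(p, q):
        cand = build_chain(seq, p, q, omega)
        return closure_ok(cand, motif, seq) and cand.min_interatomic_distance() >= 0.5

    phi2, psi2 = _refine_dihedrals(phi, psi, omega, motif, dirs, len(seq),
                                   max_iter, seq=seq if steric else None,
                                   stop_check=converged,
                                   residue_range=closure_range(motif, seq),
                                   steps=steps)
    out = build_chain(seq, phi2, psi2, omega)
    out.label = conf.label
    if not closure_ok(out, motif, seq):
        out.flags = conf.flags + ("unclosed",)
    else:
        out.flags = conf.flags
    return out


CLASH_WEIGHT = 5.0  # steric penalty weight in the closure objective


def _steric_penalty(N, CA, C, psi, seq, m, L):
    """Soft-core repulsion over backbone, carbonyl O, amide H and CB atoms.

    Pairs separated by more than one residue are penalized linearly below
    a contact distance of r_i + r_j (1.0 A heavy, 0.75 A hydrogen) so the
    closure search cannot collapse the strands onto each other.
    """
    pts = [N[:m], CA[:m], C[:m]]
    res = [np.arange(m)] * 3
    rad = [np.full(m, 1.0)] * 3
    extra_pts, extra_res, extra_rad = [], [], []
    for i in range(m):
        extra_pts.append(_place_oxygen(N, CA, C, psi, i, L))
        extra_res.append(i)
        extra_rad.append(1.0)
        if i >= 1 and seq.has_amide_h(i + 1):
            extra_pts.append(reconstruct_amide_h(N[i], CA[i], C[i - 1]))
            extra_res.append(i)
            extra_rad.append(0.75)
        if seq.residues[i] != "G":
            extra_pts.append(place_cbeta(N[i], CA[i], C[i]))
            extra_res.append(i)
            extra_rad.append(1.0)
    P = np.concatenate([np.concatenate(pts), np.asarray(extra_pts)])
    R = np.concatenate([np.concatenate(rad), np.asarray(extra_rad)])
    I = np.concatenate([np.concatenate(res), np.asarray(extra_res)])
    d = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
    contact = R[:, None] + R[None, :]
    np.fill_diagonal(d, np.inf)
    d[np.abs(I[:, None] - I[None, :]) <= 1] = np.inf
    overlap = np.clip(contact - d, 0.0, None)
    return 0.5 * float(overlap.sum())  # each pair counted twice


def _refine_dihedrals(phi, psi, omega, motif, directions, L, max_iter=500,
                      seq=None, stop_check=None, residue_range=None,
                      steps=(20.0, 10.0, 5.0, 2.0, 1.0, 0.5)):
    """Coordinate descent over the closure residues' phi/psi (degrees)."""
    lo, hi = motif.closure_residues if residue_range is None else residue_range
    m = max(max(d, a) for d, a in directions) if directions else hi
    m = min(m + 1, L)  # residues needed by the objective
    phi = phi.copy()
    psi = psi.copy()
    phi[0] = phi[0] if np.isfinite(phi[0]) else -60.0
    psi[-1] = psi[-1] if np.isfinite(psi[-1]) else 150.0
    prefix = _backbone_positions(phi, psi, omega, upto=lo - 1)
    fixed = (prefix[0], prefix[1], prefix[2], lo - 1)

    def objective():
        N, CA, C = _backbone_positions(phi, psi, omega, upto=m, prefix=fixed)
        d = _closure_geometry(N, CA, C, psi, directions, L)
        val = float(np.sum(np.abs(d - HBOND_TARGET)))
        if seq is not None:
            val += CLASH_WEIGHT * _steric_penalty(N, CA, C, psi, seq, m, L)
        return val

    params = [(r - 1, arr) for r in range(lo, hi + 1) for arr in (phi, psi)]
    best = objective()
    for _ in range(max_iter):
        improved = False
        for idx, arr in params:
            base = arr[idx]
            cand_best, val_best = base, best
            for s in steps:
                for delta in (s, -s):
                    arr[idx] = base + delta
                    v = objective()
                    if v < val_best - 1e-9:
                        cand_best, val_best = base + delta, v
            arr[idx] = cand_best
            if val_best < best - 1e-9:
                best = val_best
                improved = True
        if stop_check is not None and stop_check(phi, psi):
            break
        if not improved:
            break
    return phi, psi


#: cache of sequence-adapted closure-refined dihedral overrides,
#: keyed by (motif label, residue string)
_CLOSURE_CACHE: dict[tuple[str, str], tuple] = {}


def closure_range(motif: MotifSpec, seq: PeptideSequence) -> tuple[int, int]:
    """Effective closure residue range for a motif and sequence.

    When prolines shift the cross-strand register by one (offset-1
    pairs), the innermost strand residues become part of the loop, so the
    refinable range extends one residue into each strand.
    """
    lo, hi = motif.closure_residues
    pairs = hbond_pairs(motif, seq)
    if pairs and motif.strands is not None:
        (a1, b1), (a2, b2) = motif.strands
        if pairs[0][0] != b1:  # shifted register
            lo, hi = lo - 1, hi + 1
    return lo, hi


def _refined_closure(motif: MotifSpec, seq: PeptideSequence,
                     max_iter: int = 300) -> tuple:
    """Closure-residue (index, phi, psi) overrides that close the hairpin.

    Starts from the bundled turn table (and, as fallbacks, the other
    motifs' tables) and runs the closure refinement once per
    motif/sequence combination; the result is cached for the process.
    Deterministic, so sampling stays bit-reproducible.
    """
    key = (motif.label, seq.residues)
    if key in _CLOSURE_CACHE:
        return _CLOSURE_CACHE[key]
    lo, hi = closure_range(motif, seq)
    pairs = hbond_pairs(motif, seq)
    dirs = _pair_directions(pairs, seq)
    L = motif.n_residues
    omega = np.full(L, 180.0)
    tlo, thi = motif.closure_residues
    span = hi - lo + 1
    preferred = []
    if span != thi - tlo + 1 and f"{motif.label}-shifted" in _tables.TURN_DIHEDRALS:
        preferred.append(_tables.TURN_DIHEDRALS[f"{motif.label}-shifted"])
    seeds = preferred + [_tables.TURN_DIHEDRALS[motif.label]] + [
        tbl for lbl, tbl in _tables.TURN_DIHEDRALS.items()
        if lbl not in (motif.label, f"{motif.label}-shifted")
    ]
    def fully_closed(conf):
        try:
            return bool(np.all(_ks_energies(conf, dirs) < KS_CUTOFF))
        except ValueError:
            return False

    best = None
    best_closed = False
    for seed_table in seeds:
        phi0, psi0 = _base_dihedrals(motif, None)
        if len(seed_table) == span:
            rng_seed = range(lo - 1, hi)
        elif len(seed_table) == thi - tlo + 1:
            rng_seed = range(tlo - 1, thi)
        else:
            continue
        for k, i in enumerate(rng_seed):
            phi0[i], psi0[i] = seed_table[k]

        def ok(p, q):
            cand = build_chain(seq, p, q, omega)
            return fully_closed(cand) and cand.min_interatomic_distance() >= 0.6

        if ok(phi0, psi0):
            phi, psi = phi0, psi0  # the bundled table already closes
        else:
            phi, psi = _refine_dihedrals(phi0, psi0, omega, motif, dirs, L,
                                         max_iter, seq=seq, stop_check=ok,
                                         residue_range=(lo, hi))
        conf = build_chain(seq, phi, psi, omega)
        overrides = tuple(
            (i, float(phi[i - 1]), float(psi[i - 1])) for i in range(lo, hi + 1)
        )
        if fully_closed(conf):
            best = overrides
            break
        if closure_ok(conf, motif, seq) and not best_closed:
            best, best_closed = overrides, True
        elif best is None:
            best = overrides  # least-bad fallback
    _CLOSURE_CACHE[key] = best
    return best


# ---------------------------------------------------------------------------
# Ensemble sampling
# ---------------------------------------------------------------------------

def sample_ensemble(mix: MixtureSpec, seq: PeptideSequence,
                    max_retries: int = 25) -> tuple[Ensemble, list[str]]:
    """Draw a seeded conformer ensemble from a motif mixture.

    Per conformer: a component is drawn at the mixture weights, each
    dihedral jittered by Normal(0, sigma), the chain built, hairpin
    closure refined when the quick H-bond check fails, and sterically
    clashing draws (atoms closer than 0.5 A) rejected and redrawn. If
    every retry fails, the least-clashing draw is kept and flagged
    (``clashed`` / ``unclosed``).

    Returns the ensemble and the per-conformer ground-truth motif labels.
    Identical ``MixtureSpec`` (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(mix.seed)
    comp_idx = rng.choice(len(mix.components), size=mix.n_conformers, p=mix.weights)
    confs = []
    labels = []
    for k, ci in enumerate(comp_idx):
        motif = mix.components[ci][0]
        conf = None
        best_fallback = None
        best_dist = -1.0
        for _ in range(max_retries):
            phi0, psi0 = _base_dihedrals(motif, rng, seq)
            phi, psi = _jitter(motif, phi0, psi0, rng)
            cand = build_chain(seq, phi, psi)
            dist = cand.min_interatomic_distance()
            if dist >= 0.5 and motif.closure_residues is not None \
                    and not closure_ok(cand, motif, seq):
                # warm start from the refined base: small steps, no steric term
                cand = refine_closure(cand, motif, seq, max_iter=25,
                                      steric=False, steps=(6.0, 2.0, 1.0))
                dist = cand.min_interatomic_distance()
            if dist >= 0.5 and "unclosed" not in cand.flags:
                conf = cand
                break
            if dist > best_dist:
                best_fallback, best_dist = cand, dist
        if conf is None:
            conf = best_fallback
            if best_dist < 0.5:
                conf.flags = conf.flags + ("clashed",)
        conf.label = f"conf_{k}"
        confs.append(conf)
        labels.append(motif.label)
    ens = Ensemble(seq, confs)
    return ens, labels
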