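"""Generalized-Born (OBC-style) electrostatic solvation energy with a
surface-area nonpolar term, and ensemble/super-family solvation reports.

The electrostatic term uses pairwise-descreening effective Born radii
with the OBC-II tanh rescaling, Debye-Hueckel salt screening of the
solvent contribution, and the canonical Still interpolation
f_ij = sqrt(r_ij^2 + R_i R_j exp(-r_ij^2 / (4 R_i R_j))). The nonpolar
term is gamma * SASA with SASA from deterministic Shrake-Rupley sphere
sampling on a Fibonacci lattice.

The bundled per-atom parameter table (charges, intrinsic radii, OBC
scaling factors for backbone + C-beta atoms) is this package's own
parameterization: absolute energies are not comparable to any particular
force field — orderings, closed-form limits and the relative (delta)
conventions of the reports are the meaningful outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blockstats import BlockPartition, make_blocks
from .model_io import (
    ATOM_NAMES, Conformation, Ensemble, PeptideSequence, DEFAULT_PROTONATION,
)

COULOMB_HALF = 166.03  # kcal/mol * A / e^2, half the Coulomb constant


@dataclass(frozen=True)
class SolvParams:
    """Physical parameters of the GB/SA model."""

    eps_in: float = 1.0        # interior dielectric
    eps_out: float = 78.5      # solvent dielectric
    gamma: float = 0.005       # kcal/(mol A^2), surface tension
    salt_molar: float = 0.2    # M, effective salt concentration
    probe_radius: float = 1.4  # A, solvent probe
    n_points: int = 960        # Shrake-Rupley sphere points
    offset: float = 0.09       # A, Born-radius offset
    obc: tuple[float, float, float] = (1.0, 0.8, 4.85)  # OBC-II alpha/beta/gamma

    @property
    def kappa(self) -> float:
        """Debye screening constant in 1/A (~0.316 sqrt(M) at 298 K)."""
        return 0.316 * float(np.sqrt(self.salt_molar))


#: per-atom-name (partial charge e, intrinsic radius A, OBC scale);
#: backbone partial charges are AMBER-like with the alpha hydrogen folded
#: into CA, radii mbondi2-like, scales the standard element values
DEFAULT_PARAMS = {
    "N":  (-0.4157, 1.55, 0.79),
    "H":  (0.2719, 1.30, 0.85),
    "CA": (0.1160, 1.70, 0.72),
    "C":  (0.5973, 1.70, 0.72),
    "O":  (-0.5679, 1.50, 0.85),
    "CB": (0.0, 1.70, 0.72),
}


def load_param_table(path) -> dict:
    """Read a TSV parameter table (atom_name, charge, radius, scale)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"atom_name", "charge", "radius", "scale"}
    if not need.issubset(df.columns):
        raise ValueError(f"parameter table must have columns {sorted(need)}")
    return {
        str(r.atom_name): (float(r.charge), float(r.radius), float(r.scale))
        for r in df.itertuples()
    }


def write_param_table(params: dict, path) -> None:
    rows = [{"atom_name": k, "charge": q, "radius": r, "scale": s}
            for k, (q, r, s) in params.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class AtomSystem:
    """Flat per-atom arrays for solvation calculations."""

    coords: np.ndarray   # (M, 3) A
    charges: np.ndarray  # (M,) e
    radii: np.ndarray    # (M,) A intrinsic
    scales: np.ndarray   # (M,)

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


def atom_system(conf: Conformation, seq: PeptideSequence,
                params: Optional[dict] = None,
                convention: Optional[dict] = None) -> AtomSystem:
    """Build an AtomSystem from a backbone conformation.

    Residue formal charges under the protonation convention are placed on
    CB (CA for glycine); the N-terminal charge goes on N of residue 1 and
    the C-terminal charge (absent when amidated) on the terminal O. Where
    the amide H is not modeled its partial charge is folded into N so
    each residue stays near-neutral.
    """
    params = dict(DEFAULT_PARAMS if params is None else params)
    conv = dict(DEFAULT_PROTONATION)
    if convention:
        conv.update(convention)
    L = conf.n_residues
    coords, charges, radii, scales = [], [], [], []
    for i in range(L):
        present = {a: not np.any(np.isnan(conf.coords[i, k]))
                   for k, a in enumerate(ATOM_NAMES)}
        side_q = conv.get(seq.residues[i], 0)
        for k, a in enumerate(ATOM_NAMES):
            if not present[a]:
                continue
            if a not in params:
                raise KeyError(f"no parameters for atom {a}")
            q, r, s = params[a]
            if a == "N":
                if not present["H"]:
                    q += params["H"][0]  # fold unmodeled amide H into N
                if i == 0:
                    q += conv.get("nterm", 0)
            if a == "O" and i == L - 1 and not seq.c_amidated:
                q += conv.get("cterm", 0)
            if side_q and ((a == "CB" and present["CB"]) or
                           (a == "CA" and not present["CB"])):
                q += side_q
            coords.append(conf.coords[i, k])
            charges.append(q)
            radii.append(r)
            scales.append(s)
    return AtomSystem(np.asarray(coords), np.asarray(charges),
                      np.asarray(radii), np.asarray(scales))


# ---------------------------------------------------------------------------
# Born radii (pairwise descreening + OBC-II rescaling)
# ---------------------------------------------------------------------------

def born_radii(system: AtomSystem, p: SolvParams = SolvParams()) -> np.ndarray:
    """Effective Born radii via the HCT descreening integral with OBC-II
    tanh rescaling.

    For atom i with offset-reduced radius rho_i = radius_i - offset and
    neighbors of scaled reduced radius s_j, Psi_i = rho_i * sum_j H(r_ij,
    s_j), and 1/R_i = 1/rho_i - tanh(a Psi - b Psi^2 + c Psi^3)/radius_i
    with (a, b, c) = (1.0, 0.8, 4.85). An isolated atom's R equals its
    reduced radius; burial only increases R.
    """
    X = system.coords
    M = system.n_atoms
    r = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    off = ~np.eye(M, dtype=bool)
    if M > 1 and r[off].min() < 0.3:
        raise ValueError("overlapping atoms (closer than 0.3 A)")
    rho = system.radii - p.offset
    if np.any(rho <= 0):
        raise ValueError("intrinsic radius must exceed the offset")
    sr = system.scales * rho  # scaled reduced radius of the descreener
    I = np.zeros((M, M))
    for i in range(M):
        rij = r[i]
        s = sr.copy()
        mask = off[i] & (rij + s > rho[i])
        if not mask.any():
            continue
        rij = rij[mask]
        s = s[mask]
        U = rij + s
        Lw = np.maximum(rho[i], np.abs(rij - s))
        val = 0.5 * (
            1.0 / Lw - 1.0 / U
            + 0.25 * (1.0 / U ** 2 - 1.0 / Lw ** 2) * (rij - s ** 2 / rij)
            + 0.5 * np.log(Lw / U) / rij
        )
        inside = s - rij > rho[i]  # atom i fully inside neighbor's sphere
        val = val + np.where(inside, 2.0 * (1.0 / rho[i] - 1.0 / Lw) * 0.5, 0.0)
        I[i, mask] = val
    psi = rho * I.sum(axis=1)
    a, b, c = p.obc
    inv_r = 1.0 / rho - np.tanh(a * psi - b * psi ** 2 + c * psi ** 3) / system.radii
    return 1.0 / inv_r


# ---------------------------------------------------------------------------
# GB electrostatic energy
# ---------------------------------------------------------------------------

def gb_energy(system: AtomSystem, radii: np.ndarray,
              p: SolvParams = SolvParams()) -> float:
    """Generalized-Born electrostatic solvation energy (kcal/mol).

    E = -166.03 * sum_{i,j} q_i q_j (1/eps_in - exp(-kappa f_ij)/eps_out)
    / f_ij over all ordered pairs including i = j (f_ii = R_i), i.e. the
    i < j sum is counted twice, which reduces to the Born formula for a
    single ion and to screened Coulomb attraction at large separation.
    """
    q = np.asarray(system.charges, dtype=float)
    if np.any(~np.isfinite(q)):
        raise ValueError("missing (non-finite) charge")
    R = np.asarray(radii, dtype=float)
    X = system.coords
    r2 = ((X[:, None] - X[None, :]) ** 2).sum(axis=-1)
    RR = R[:, None] * R[None, :]
    f = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    screen = 1.0 / p.eps_in - np.exp(-p.kappa * f) / p.eps_out
    qq = q[:, None] * q[None, :]
    return float(-COULOMB_HALF * np.sum(qq * screen / f))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ], axis=1)


def _canonical_frame(X: np.ndarray) -> np.ndarray:
    """Rotate centered coordinates into their principal-axes frame.

    Gives sphere-sampled SASA exact invariance under rigid motions: the
    canonical orientation is a deterministic function of the shape alone
    (eigenvector signs fixed by their largest-magnitude component).
    """
    X = X - X.mean(axis=0)
    if len(X) < 2:
        return X
    cov = X.T @ X
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    V = V[:, order]
    for k in range(3):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return X @ V


def sasa(system: AtomSystem, p: SolvParams = SolvParams(),
         n_points: Optional[int] = None) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    Returns per-atom areas and the total. Deterministic for a fixed
    number of sphere points, and computed in the molecule's principal-axes
    frame so the result is invariant under rigid motions.
    """
    n_pts = p.n_points if n_points is None else n_points
    pts = _fibonacci_sphere(n_pts)
    X = _canonical_frame(system.coords)
    M = system.n_atoms
    rs = system.radii + p.probe_radius
    d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    areas = np.empty(M)
    for i in range(M):
        neigh = np.nonzero((d[i] < rs[i] + rs) & (np.arange(M) != i))[0]
        sphere = X[i] + rs[i] * pts
        if len(neigh):
            dist2 = ((sphere[:, None, :] - X[neigh][None, :, :]) ** 2).sum(-1)
            buried = (dist2 < (rs[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * rs[i] ** 2 * frac
    return areas, float(areas.sum())


# ---------------------------------------------------------------------------
# Totals and reports
# ---------------------------------------------------------------------------

@dataclass
class SolvationResult:
    """GB + surface-area solvation energy of one conformer (kcal/mol)."""

    e_gb: float
    e_surf: float

    @property
    def e_total(self) -> float:
        return self.e_gb + self.e_surf


def gbsa_total(conf: Conformation, seq: PeptideSequence,
               p: SolvParams = SolvParams(),
               params: Optional[dict] = None,
               convention: Optional[dict] = None) -> SolvationResult:
    """Total GB/SA solvation energy of one conformation."""
    system = atom_system(conf, seq, params=params, convention=convention)
    radii = born_radii(system, p)
    e_gb = gb_energy(system, radii, p)
    _, total_area = sasa(system, p)
    return SolvationResult(e_gb, p.gamma * total_area)


def ensemble_gbsa(ensemble: Ensemble, p: SolvParams = SolvParams(),
                  params: Optional[dict] = None,
                  convention: Optional[dict] = None) -> np.ndarray:
    """Per-conformer total GB/SA energies (kcal/mol)."""
    return np.array([
        gbsa_total(c, ensemble.sequence, p, params, convention).e_total
        for c in ensemble
    ])


def solvation_report(energies, labels: Sequence[str],
                     blocks: Optional[BlockPartition] = None,
                     last_k: int = 3) -> pd.DataFrame:
    """Per-super-family solvation statistics over the last blocks.

    Rows: one per label present plus an ``average`` row over all
    conformers. Columns: mean and sample std of per-block means, the
    conformer count, and ``delta_vs_helix_coil`` (0 for helix-coil
    itself; NaN when no helix-coil conformers exist).
    """
    energies = np.asarray(energies, dtype=float)
    labels = list(labels)
    if len(energies) != len(labels):
        raise ValueError("one energy per labeled conformer is required")
    if blocks is None:
        blocks = make_blocks(len(energies), last_k)
    tail = blocks.last(last_k)
    order = [lab for lab in dict.fromkeys(labels)]
    rows = []
    for lab in order + ["average"]:
        means = []
        for lo, hi in tail:
            sel = np.array([
                lab == "average" or labels[t] == lab for t in range(lo, hi)
            ])
            if sel.any():
                means.append(energies[lo:hi][sel].mean())
        if not means:
            continue  # label absent from the last blocks
        means = np.array(means)
        rows.append({
            "label": lab,
            "mean": float(means.mean()),
            "std": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
            "n": len(energies) if lab == "average"
                 else sum(1 for x in labels if x == lab),
        })
    df = pd.DataFrame(rows)
    ref = df.loc[df["label"] == "helix-coil", "mean"]
    ref_val = float(ref.iloc[0]) if len(ref) else np.nan
    df["delta_vs_helix_coil"] = np.where(
        df["label"] == "average", np.nan, df["mean"] - ref_val
    )
    return df


def relative_to_variant(averages: dict[str, float],
                        reference: str = "human") -> dict[str, float]:
    """Ensemble-average energies relative to a reference variant.

    The reference maps to exactly 0 by construction.
    """
    if reference not in averages:
        raise KeyError(f"reference variant {reference!r} not in table")
    ref = averages[reference]
    return {k: v - ref for k, v in averages.items()}
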