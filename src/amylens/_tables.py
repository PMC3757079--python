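"""Bundled backbone dihedral tables shared by the generator and the assigner.

All angles in degrees. Canonical helix/strand targets are the standard
Ramachandran values for an alpha-helix and an antiparallel beta-strand;
coil entries sample the PPII/extended/bridge basins while keeping a safe
margin (> 40 deg) from the helix and strand targets so dihedral-based
assignment stays unambiguous. Turn tables hold per-residue (phi, psi)
values for the hairpin turn/loop regions; they were obtained by running
the closure refinement on the ideal motifs so that the cross-strand
hydrogen bonds form from the tabulated values alone.
"""

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)

#: tolerance (deg, Euclidean in wrapped phi/psi space) for dihedral-mode
#: secondary-structure assignment
DIHEDRAL_TOLERANCE = 40.0

#: coil basin sample set (phi, psi)
COIL_PHI_PSI = (
    (-75.0, 150.0),
    (-70.0, 160.0),
    (-85.0, 120.0),
    (-150.0, 70.0),
    (-60.0, 130.0),
)

#: classic beta-turn dihedrals (types I, I', II, II'), used as additional
#: anchors for the dihedral-mode turn region
BETA_TURN_PHI_PSI = (
    (-60.0, -30.0),  # type I, i+1
    (-90.0, 0.0),    # type I, i+2
    (60.0, 30.0),    # type I', i+1
    (90.0, 0.0),     # type I', i+2
    (-60.0, 120.0),  # type II, i+1
    (80.0, 0.0),     # type II, i+2
    (60.0, -120.0),  # type II', i+1
    (-80.0, 0.0),    # type II', i+2
)

#: closure-refined per-residue (phi, psi) for the hairpin turn regions,
#: keyed by motif label; filled by design-time refinement of the ideal
#: motifs (see synthgen.refine_closure)
TURN_DIHEDRALS = {
    # residues 18..22 (beta-hairpin turn)
    "beta-hairpin": (
        (-89.0, 160.5),
        (100.5, 17.0),
        (80.5, 47.5),
        (110.0, 20.5),
        (-80.0, -2.0),
    ),
    # residues 28..32 (helix-hairpin loop plus the bridging residue)
    "helix-hairpin": (
        (38.65, 24.43),
        (99.64, -57.24),
        (-170.84, -55.77),
        (-64.97, -31.23),
        (-113.6, -3.06),
    ),
    # residues 27..33: the proline-shifted helix-hairpin register
    # (e.g. rat/pig P25), whose loop absorbs one residue of each strand
    "helix-hairpin-shifted": (
        (-5.95, -48.85),
        (-66.99, 27.17),
        (-29.46, -37.25),
        (-67.31, -45.98),
        (-145.79, -96.03),
        (-78.31, -64.75),
        (-0.66, -56.82),
    ),
}
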