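# Methods

## Scope and model

`amylens` characterizes conformer ensembles of a 37-residue amylin-like
peptide. The scientific object is not a single fold but a *mixture* of
backbone motifs; the package measures, for a given ensemble, the
secondary-structure content, the partition into structural families, the
merged super-family abundances, per-residue flexibility, and an implicit
solvation score per super-family. Because real replica-exchange
trajectories of this peptide are microsecond-scale and not deposited,
the package ships a synthetic generator that emulates the *structure* of
such ensembles (motif mixtures with controlled noise) without any claim
to their thermodynamics.

## Synthetic conformer generator

**Chain construction.** Backbones are built residue by residue from
internal coordinates (NeRF): ideal bond lengths N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å, C=O 1.231 Å; backbone angles N–CA–C 111.2°,
CA–C–N 116.6°, C–N–CA 121.9°; all-trans ω = 180°. The carbonyl O lies in
the CA–C–N(i+1) plane anti to N(i+1); for the C-terminal residue, whose
ψ is undefined, a virtual ψ of 150° places the terminal carbonyl. Amide
hydrogens sit 1.01 Å from N in the C(i−1)–N–CA plane, opposite the
bisector; residue 1 and prolines carry none. Cβ atoms are placed
tetrahedrally (none for glycine). Reconstructed dihedrals match the
inputs to ~1e-13 degrees (unit-tested at 1e-4).

**Motifs.** Helix segments use (φ,ψ) = (−57°,−47°) and strand segments
(−139°,135°) — standard Ramachandran values chosen so that the α-helical
i→i+4 hydrogen bonds and inter-strand registration emerge from geometry
alone. Coil residues draw per conformer from a five-entry φ/ψ set
covering the PPII/extended/bridge basins, each entry kept more than 40°
from the helix and strand anchors so dihedral-based assignment is
unambiguous. The three motifs use the residue ranges given above
(helix-coil: coil 1–7 / helix 8–17 / coil 18–37; helix-hairpin: strands
25–27 and 33–36 with loop 28–31; β-hairpin: strands 9–17 and 23–33 with
turn 18–22).

**Hairpin closure.** Ideal strand dihedrals alone do not register the
two strands, so the turn/loop residues' φ/ψ are refined by coordinate
descent (step sets from 20° down to 0.5°, ≤500 sweeps) on an objective
that is the sum of |d(O···H) − 1.95 Å| over the intended cross-strand
donor/acceptor directions plus a soft-core steric penalty (linear below
contact distance, weight 5) that prevents the strands from collapsing
onto each other. Intended pairs alternate along the antiparallel
register; of the two possible register offsets the generator picks the
one with the most realizable donor directions, because prolines cannot
donate (this shifts the register by one residue in the rat/pig
helix-hairpin, whose strand-1 contains P25). When the register is
shifted, the innermost strand residues effectively join the loop and the
refinable range extends one residue into each strand. The bundled turn
tables are the refined solutions for the canonical registers; at
sampling time the closure is re-refined once per motif/sequence
combination (cached, deterministic) and per-conformer only when the
jittered draw fails a quick H-bond check, warm-started with small steps.
A conformer whose two innermost cross-strand bonds stay above the
Kabsch–Sander cutoff is flagged `unclosed`.

**Sampling.** Per conformer: a mixture component is drawn at the preset
weights, every φ/ψ is jittered by Normal(0, σ) (σ per segment, default
3°; ω stays 180°), the chain is built, closure is checked/repaired, and
draws with any non-bonded atom pair closer than 0.5 Å are rejected and
redrawn (≤8 attempts). Identical seeds give bit-identical ensembles.
The variant presets use the super-family abundances of the four
variants as mixture weights: pig/rat 87/13 (helix-coil/helix-hairpin),
cat 28/25/47 and human 15/9/75 (helix-coil/helix-hairpin/β-hairpin,
normalized). Preset sequences are the literature human/rat/cat variants;
the pig entry applies the two pig-defining substitutions (S20R, N31K) on
the rat scaffold and is an approximation.

**What the generator does not emulate.** No side chains beyond Cβ, no
energetics (jitter is isotropic in dihedral space, not Boltzmann), no
kinetics or inter-block correlation, no partially-formed or chimeric
motifs, and no disulfide geometry (the 2–7 pair is topology metadata
only). Tests passing on these ensembles therefore validate the
*analysis operators* — assignment, clustering, classification, RMSF and
solvation scoring and their statistics — not any claim about real IAPP
thermodynamics.

## Secondary structure

The H-bond mode scores backbone N–H···O=C pairs with the Kabsch–Sander
electrostatic model, E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol, no bond evaluated beyond N···O ≥ 7 Å, bond declared below
−0.5 kcal/mol; donors without an amide H (residue 1, prolines) never
donate. Patterns follow DSSP: H from two consecutive i→i+4 turns, G from
i→i+3, E from bridge ladders (≥2 adjacent bridges), B for isolated
bridges, T for lone turn bonds, C otherwise; priority H > E > B > G > T.
STRIDE, the other widely used assigner in this field, mixes H-bond
energetics with knowledge-based torsional terms that are not fully
published; the Kabsch–Sander/DSSP formulation was chosen because it is
completely specified and testable. π-helix is not distinguished and PPII counts as
coil. Aggregate classes: helix = {H,G}, sheet = {E,B}, turn = {T},
coil = {C}; a merged 3-class report pools turn and coil. The dihedral
mode assigns H/E/T by proximity (Euclidean in wrapped φ/ψ, 40°
tolerance) to the generator's helix/strand/turn anchors and exists to
ground-truth synthetic ensembles.

## Clustering and super-families

Pairwise Cα-RMSD uses per-pair optimal Kabsch superposition (batched
3×3 SVDs; reflections corrected). The greedy neighbor-count clustering
removes, at each step, the structure with the most neighbors within the
3.0 Å cutoff together with those neighbors; counts are recomputed after
each removal (the "static counts" variant yields different partitions),
and ties break to the lowest structure index so the partition is
deterministic. The super-family rule is applied to centroids by default
(members inherit the centroid's label — the merge-of-families reading),
with a per-frame granularity available. Boundary conventions, both
unit-tested: an N-part helix/sheet tie is *not* helix-rich (→
β-hairpin); exactly four C-part sheet residues (the minimal 2:2 hairpin)
stay helix-coil — "more than four" is read strictly.

## RMSF

Conformers are superposed on the first conformer of their subset over
the alignment range (default residues 1–17, the rigid helix region — the
range is a parameter), and RMSF_i = sqrt(mean_t |r_i(t) − ⟨r_i⟩|²) over
Cα. Profiles are computed per super-family; labels with fewer than two
conformers are omitted with a warning. A mean-structure iterative
reference would change values only marginally for these ensembles and is
noted as an option, not implemented.

## GB/SA solvation

Effective Born radii come from the pairwise-descreening (HCT) integral
with OBC-II tanh rescaling: Ψ_i = ρ̃_i Σ_j H(r_ij, s_j ρ̃_j),
1/R_i = 1/ρ̃_i − tanh(αΨ − βΨ² + γΨ³)/ρ_i with (α,β,γ) = (1.0, 0.8,
4.85) and offset 0.09 Å. The electrostatic term is
E_GB = −166.03 Σ_{i,j} q_i q_j (1/ε_in − e^{−κ f_ij}/ε_out)/f_ij with
f_ij = sqrt(r_ij² + R_i R_j e^{−r_ij²/(4R_iR_j)}), the sum over all
ordered pairs including i = j (f_ii = R_i; the i<j sum is doubled).
Salt enters only through the Debye factor, κ = 0.316·√M Å⁻¹ (0.1413 Å⁻¹
at the default 0.2 M); ε_in = 1, ε_out = 78.5 and the temperature behind
κ are explicit parameters rather than constants. The
nonpolar term is γ·SASA with γ = 0.005 kcal·mol⁻¹·Å⁻², SASA by
Shrake–Rupley sampling on a deterministic Fibonacci lattice (960 points,
probe 1.4 Å), computed in the molecule's principal-axes frame so the
result is exactly invariant under rigid motions.

The per-atom parameter table (backbone + Cβ charges, mbondi2-like radii,
standard element scaling factors) is this package's own: residue formal
charges under the protonation convention sit on Cβ (CA for glycine), the
N-terminal charge on N1, and unmodeled amide-H charges are folded into
N. Absolute energies are therefore not comparable to any specific force
field; the meaningful outputs are the analytic limits (Born ion,
screened Coulomb, sphere areas — all unit-tested), orderings (e.g.
extended chains have larger surface term than helices), and the relative
Δ conventions of the reports (per-label Δ vs helix-coil within a
variant; ensemble-average Δ vs a reference variant, which maps the
reference to exactly 0).

The peptide charge itself is convention-dependent: no uniform
protonation rule reproduces all four variants' printed charges (rat =
human + H18R is more basic than human under any uniform rule), so the
convention is an explicit parameter with default {K:+1, R:+1, H:0,
D:−1, E:−1, N-term:+1, amidated C-term:0} and nothing is hard-coded.

## Block statistics and temperature ladder

Trajectories are split into equal consecutive blocks (default 6; earlier
blocks absorb the remainder); reported statistics are the mean and
sample standard deviation (divisor k−1) of per-block means over the last
k blocks (default 3). Per-block means over all blocks are exposed for
convergence inspection; no automated equilibration test is asserted.
"Exponentially spaced" replica temperatures are read as a geometric
progression T_i = T_min (T_max/T_min)^{i/(n−1)} with exact endpoints
(defaults 270–465 K, n = 16); ladder optimization is out of scope.

## Problem sizes and numerical choices

The shipped analyses use ensembles of 150–400 conformers for the
clustering pipelines and 2000 for the mixture-recovery and RMSF
statistics — large enough that binomial 3σ bands on the preset weights
are a few percent, small enough that a full run (generation through
solvation) completes in minutes on one core. Floating-point reports are
written at fixed precision so identical configuration and seed give
byte-identical outputs. Degenerate inputs are rejected rather than
silently handled: <3 or collinear atoms for superposition, overlapping
atoms (<0.3 Å) for solvation and H-bond scoring, fewer frames than
blocks, std over fewer than two blocks.

## Known limitations

- The H-bond assigner is DSSP-like, not STRIDE; assignments can differ
  from STRIDE near helix termini and short strands (the helix 8–17
  motif, for instance, is assigned helix on 9–16).
- The 3-residue helix-hairpin strands sit at the detection limit of
  stricter assigners (an independent DSSP cross-check sees the full
  β-hairpin ladders but only part of the short hairpin's).
- GB/SA absolute energies are package-specific (see above).
- The generator's conformers are locally ideal; bond lengths and angles
  carry no thermal noise, so RMSD distances within a motif family are
  driven entirely by dihedral jitter.
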