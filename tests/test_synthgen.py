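"""Chain builder, motif blueprints, hairpin closure and seeded sampling."""

import numpy as np
import pytest
from scipy import stats

from amylens.model_io import H_, O_, PeptideSequence
from amylens.secstruct import assign_ss
from amylens.superfamily import classify_superfamily
from amylens.synthgen import (
    MixtureSpec, Segment, MotifSpec, build_chain, closure_ok, hbond_pairs,
    make_motif, refine_closure, sample_ensemble, variant_mixture,
)
from amylens.cluster import rmsd_matrix


class TestBuildChain:
    def test_dihedrals_are_reproduced_exactly(self):
        seq = PeptideSequence("ADKFGHR")
        rng = np.random.default_rng(11)
        phi = rng.uniform(-180, 180, 7)
        psi = rng.uniform(-180, 180, 7)
        omega = np.where(rng.random(7) < 0.5, 180.0, 175.0)
        conf = build_chain(seq, phi, psi, omega)
        p, s, o = conf.backbone_dihedrals()
        np.testing.assert_allclose(p[1:], phi[1:], atol=1e-4)
        np.testing.assert_allclose(s[:-1], psi[:-1], atol=1e-4)
        np.testing.assert_allclose(o[1:], omega[1:], atol=1e-4)

    def test_dipeptide_omega_trans_exact(self):
        seq = PeptideSequence("AA")
        conf = build_chain(seq, [np.nan, -60.0], [120.0, np.nan])
        _, _, o = conf.backbone_dihedrals()
        assert abs(abs(o[1]) - 180.0) < 1e-9

    def test_ideal_helix_has_alpha_hbond_geometry(self):
        seq = PeptideSequence("A" * 37)
        conf = build_chain(seq, np.full(37, -57.0), np.full(37, -47.0))
        d = [np.linalg.norm(conf.coords[i, O_] - conf.coords[i + 4, H_])
             for i in range(1, 32)]
        assert min(d) > 1.8 and max(d) < 2.3

    def test_extended_strand_is_extended(self):
        seq = PeptideSequence("A" * 37)
        conf = build_chain(seq, np.full(37, -139.0), np.full(37, 135.0))
        assert np.linalg.norm(conf.ca[-1] - conf.ca[0]) > 100.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            build_chain(PeptideSequence("AAA"), [0.0, 0.0], [0.0, 0.0])


class TestMakeMotif:
    @pytest.mark.parametrize("label,kind,rng_", [
        ("helix-coil", "helix", (8, 17)),
        ("beta-hairpin", "turn", (18, 22)),
        ("beta-hairpin", "strand", (9, 17)),
        ("helix-hairpin", "strand", (25, 27)),
    ])
    def test_canonical_segment_ranges(self, label, kind, rng_):
        motif = make_motif(label)
        assert any(s.kind == kind and (s.start, s.stop) == rng_
                   for s in motif.segments)

    def test_helix_hairpin_loop_covers_28_31(self):
        motif = make_motif("helix-hairpin")
        turn = next(s for s in motif.segments if s.kind == "turn")
        assert turn.start == 28 and turn.stop >= 31

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            make_motif("pi-helix")

    def test_segments_must_tile_the_chain(self):
        with pytest.raises(ValueError):
            MotifSpec("x", (Segment(1, 5, "coil"), Segment(7, 37, "coil")))


class TestClosure:
    def test_refined_hairpin_registers_cross_strand_bonds(self, human_seq,
                                                          beta_hairpin_conf):
        motif = make_motif("beta-hairpin")
        assert closure_ok(beta_hairpin_conf, motif, human_seq)
        ss = assign_ss(beta_hairpin_conf, "hbond")
        assert sum(1 for c in ss[8:17] if c == "E") >= 6
        assert sum(1 for c in ss[22:33] if c == "E") >= 6

    def test_motif_without_closure_returned_unchanged(self, human_seq,
                                                      helix_coil_conf):
        motif = make_motif("helix-coil")
        out = refine_closure(helix_coil_conf, motif, human_seq)
        assert out is helix_coil_conf

    def test_refining_a_closed_hairpin_keeps_it_closed(self, human_seq,
                                                       beta_hairpin_conf):
        motif = make_motif("beta-hairpin")
        out = refine_closure(beta_hairpin_conf, motif, human_seq)
        assert closure_ok(out, motif, human_seq)
        assert "unclosed" not in out.flags

    def test_pair_register_avoids_proline_donors(self, rat_seq, human_seq):
        motif = make_motif("helix-hairpin")
        pairs_h = hbond_pairs(motif, human_seq)
        pairs_r = hbond_pairs(motif, rat_seq)
        assert (27, 33) in pairs_h
        # rat P25 kills a donor direction; the chosen register must not
        # lose realizable bonds relative to the human register
        score = sum(int(rat_seq.has_amide_h(i)) + int(rat_seq.has_amide_h(j))
                    for i, j in pairs_r)
        alt = sum(int(rat_seq.has_amide_h(i)) + int(rat_seq.has_amide_h(j))
                  for i, j in pairs_h)
        assert score >= alt


class TestSampling:
    def test_identical_seed_identical_ensemble(self, human_seq):
        mix = variant_mixture("human", 6, sigma=3.0, seed=42)
        e1, l1 = sample_ensemble(mix, human_seq)
        e2, l2 = sample_ensemble(mix, human_seq)
        assert l1 == l2
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_single_component_sigma_zero_is_degenerate(self, human_seq):
        mix = MixtureSpec(((make_motif("helix-coil", 0.0), 1.0),), 4, seed=9)
        ens, _ = sample_ensemble(mix, human_seq)
        # coil dihedrals are still drawn per conformer; restrict to the
        # deterministic helix residues via pairwise RMSD over 8..17
        m = rmsd_matrix(ens, residue_selection=range(8, 18))
        assert m.values.max() < 1e-6

    def test_component_counts_within_binomial_bound(self, human_seq):
        n = 600
        mix = MixtureSpec(
            ((make_motif("helix-coil", 3.0), 0.5),
             (make_motif("beta-hairpin", 3.0), 0.5)),
            n, seed=123,
        )
        _, labels = sample_ensemble(mix, human_seq)
        k = sum(1 for l in labels if l == "helix-coil")
        assert abs(k - n / 2) <= 3 * np.sqrt(n * 0.25)

    def test_component_frequencies_not_rejected_by_chi_square(self, human_seq):
        """Aggregated component counts over 20 seeds match the weights."""
        weights = (0.2, 0.3, 0.5)
        comps = tuple(
            (make_motif(lbl, 0.0), w)
            for lbl, w in zip(("helix-coil", "helix-hairpin", "beta-hairpin"), weights)
        )
        counts = np.zeros(3)
        n_per = 50
        for seed in range(20):
            mix = MixtureSpec(comps, n_per, seed=seed)
            _, labels = sample_ensemble(mix, human_seq)
            for k, lbl in enumerate(("helix-coil", "helix-hairpin", "beta-hairpin")):
                counts[k] += sum(1 for l in labels if l == lbl)
        total = counts.sum()
        expected = np.array(weights) * total
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=2) > 0.01

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(((make_motif("helix-coil"), 0.0),), 5, seed=0)

    def test_ground_truth_recovered_by_dihedral_classifier(self, human_seq):
        """At sigma <= 5 deg the dihedral-mode assigner recovers the
        generator's motif label for at least 95% of conformers."""
        mix = variant_mixture("human", 120, sigma=5.0, seed=77)
        ens, truth = sample_ensemble(mix, human_seq)
        pred = [classify_superfamily(assign_ss(c, "dihedral")) for c in ens]
        acc = np.mean([p == t for p, t in zip(pred, truth)])
        assert acc >= 0.95
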