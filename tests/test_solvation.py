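"""Born radii, GB energy limits, SASA closed forms and solvation reports."""

import numpy as np
import pytest

from amylens.blockstats import make_blocks
from amylens.solvation import (
    AtomSystem, DEFAULT_PARAMS, SolvParams, atom_system, born_radii,
    gb_energy, gbsa_total, relative_to_variant, sasa, solvation_report,
)
from amylens.synthgen import build_chain
from conftest import random_rotation

NO_SALT = SolvParams(salt_molar=0.0)


def single_atom(q=1.0, radius=2.09, scale=0.8):
    return AtomSystem(np.zeros((1, 3)), np.array([q]),
                      np.array([radius]), np.array([scale]))


class TestBornRadii:
    def test_isolated_atom_reduced_radius(self):
        R = born_radii(single_atom(), NO_SALT)
        assert R[0] == pytest.approx(2.0, abs=1e-12)  # 2.09 - 0.09 offset

    def test_burial_increases_radius(self):
        rng = np.random.default_rng(1)
        # central atom inside a dense shell
        shell = rng.normal(size=(30, 3))
        shell = 3.0 * shell / np.linalg.norm(shell, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        sys_ = AtomSystem(coords, np.zeros(31), np.full(31, 1.7), np.full(31, 0.8))
        R = born_radii(sys_, NO_SALT)
        assert R[0] > 1.7 - 0.09

    def test_two_atom_radius_monotone_in_separation(self):
        vals = []
        for r in np.linspace(2.0, 12.0, 12):
            sys_ = AtomSystem(np.array([[0, 0, 0], [r, 0, 0.]]),
                              np.zeros(2), np.full(2, 1.7), np.full(2, 0.8))
            vals.append(born_radii(sys_, NO_SALT)[0])
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.7 - 0.09, rel=1e-3)

    def test_overlapping_atoms_rejected(self):
        sys_ = AtomSystem(np.array([[0, 0, 0], [0.1, 0, 0.]]),
                          np.zeros(2), np.full(2, 1.7), np.full(2, 0.8))
        with pytest.raises(ValueError):
            born_radii(sys_, NO_SALT)


class TestGBEnergy:
    def test_born_closed_form_single_ion(self):
        e = gb_energy(single_atom(), np.array([2.0]), NO_SALT)
        expected = -166.03 * (1.0 - 1.0 / 78.5) / 2.0
        assert e == pytest.approx(expected, rel=1e-12)

    def test_single_charged_atom_always_negative(self):
        for q in (-2.0, -0.5, 0.3, 1.0):
            e = gb_energy(single_atom(q=q), np.array([2.0]), NO_SALT)
            assert e < 0

    def test_zero_charges_zero_energy(self, human_seq, helix_coil_conf):
        sys_ = atom_system(helix_coil_conf, human_seq)
        sys_.charges[:] = 0.0
        R = born_radii(sys_, NO_SALT)
        assert gb_energy(sys_, R, NO_SALT) == 0.0

    def test_coulomb_screening_limit_two_distant_charges(self):
        r = 60.0
        sys_ = AtomSystem(np.array([[0, 0, 0], [r, 0, 0.]]),
                          np.array([1.0, 1.0]), np.full(2, 2.09), np.full(2, 0.8))
        R = born_radii(sys_, NO_SALT)
        e = gb_energy(sys_, R, NO_SALT)
        e_self = sum(
            gb_energy(single_atom(), np.array([Ri]), NO_SALT) for Ri in R
        )
        interaction = e - e_self
        coulomb = -166.03 * 2.0 * (1.0 - 1.0 / 78.5) / r
        assert interaction == pytest.approx(coulomb, rel=0.01)

    def test_missing_charge_rejected(self):
        s = single_atom(q=np.nan)
        with pytest.raises(ValueError):
            gb_energy(s, np.array([2.0]), NO_SALT)


class TestSASA:
    def test_isolated_atom_full_sphere(self):
        areas, total = sasa(single_atom(radius=1.6), NO_SALT)
        assert total == pytest.approx(4 * np.pi * (1.6 + 1.4) ** 2, rel=0.01)

    def test_distant_atoms_additive(self):
        sys_ = AtomSystem(np.array([[0, 0, 0], [50, 0, 0.]]),
                          np.zeros(2), np.full(2, 1.6), np.full(2, 0.8))
        _, total = sasa(sys_, NO_SALT)
        assert total == pytest.approx(2 * 4 * np.pi * 3.0 ** 2, rel=0.01)

    def test_contact_occludes(self):
        sys_ = AtomSystem(np.array([[0, 0, 0], [1.0, 0, 0.]]),
                          np.zeros(2), np.full(2, 1.6), np.full(2, 0.8))
        areas, _ = sasa(sys_, NO_SALT)
        iso = 4 * np.pi * 3.0 ** 2
        assert areas[0] < iso and areas[1] < iso

    def test_deterministic(self, human_seq, helix_coil_conf):
        sys_ = atom_system(helix_coil_conf, human_seq)
        _, t1 = sasa(sys_)
        _, t2 = sasa(sys_)
        assert t1 == t2


class TestGBSATotal:
    def test_gamma_zero_reduces_to_gb(self, human_seq, helix_coil_conf):
        p0 = SolvParams(gamma=0.0)
        res = gbsa_total(helix_coil_conf, human_seq, p0)
        assert res.e_surf == 0.0
        assert res.e_total == res.e_gb

    def test_chargeless_conformer_positive_total(self, human_seq, helix_coil_conf):
        params = {k: (0.0, r, s) for k, (q, r, s) in DEFAULT_PARAMS.items()}
        conv = {"K": 0, "R": 0, "H": 0, "D": 0, "E": 0, "nterm": 0, "cterm": 0}
        res = gbsa_total(helix_coil_conf, human_seq, params=params, convention=conv)
        assert res.e_gb == 0.0
        assert res.e_total > 0.0

    def test_extended_chain_has_larger_surface_term(self, human_seq):
        helix = build_chain(human_seq, np.full(37, -57.0), np.full(37, -47.0))
        ext = build_chain(human_seq, np.full(37, -139.0), np.full(37, 135.0))
        rh = gbsa_total(helix, human_seq)
        re = gbsa_total(ext, human_seq)
        assert re.e_surf > rh.e_surf

    def test_rigid_motion_invariance(self, human_seq, beta_hairpin_conf):
        rng = np.random.default_rng(5)
        moved = beta_hairpin_conf.transformed(random_rotation(rng),
                                              rng.normal(scale=25.0, size=3))
        a = gbsa_total(beta_hairpin_conf, human_seq)
        b = gbsa_total(moved, human_seq)
        assert b.e_gb == pytest.approx(a.e_gb, rel=1e-6)
        assert b.e_surf == pytest.approx(a.e_surf, rel=1e-6)


class TestReports:
    def test_helix_coil_reference_row_is_zero(self):
        energies = np.arange(24, dtype=float)
        labels = ["helix-coil", "beta-hairpin"] * 12
        df = solvation_report(energies, labels, make_blocks(24, 6), last_k=3)
        row = df[df["label"] == "helix-coil"]
        assert float(row["delta_vs_helix_coil"].iloc[0]) == 0.0

    def test_label_absent_from_last_blocks_is_omitted(self):
        energies = np.arange(24, dtype=float)
        labels = ["helix-coil"] * 12 + ["beta-hairpin"] * 12
        df = solvation_report(energies, labels, make_blocks(24, 6), last_k=3)
        assert "helix-coil" not in set(df["label"])

    def test_constant_shift_leaves_deltas_unchanged(self):
        rng = np.random.default_rng(2)
        energies = rng.normal(size=36)
        labels = (["helix-coil"] * 3 + ["beta-hairpin"] * 3) * 6
        d1 = solvation_report(energies, labels, make_blocks(36, 6))
        d2 = solvation_report(energies + 100.0, labels, make_blocks(36, 6))
        np.testing.assert_allclose(d1["delta_vs_helix_coil"].dropna(),
                                   d2["delta_vs_helix_coil"].dropna(), atol=1e-9)

    def test_reference_variant_maps_to_zero(self):
        rel = relative_to_variant(
            {"human": -554.6, "rat": -651.7, "pig": -645.3}, "human")
        assert rel["human"] == 0.0
        assert rel["rat"] == pytest.approx(-97.1)
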