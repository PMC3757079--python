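"""Shared fixtures: preset sequences and small seeded motif ensembles."""

import numpy as np
import pytest

from amylens.synthgen import (
    MixtureSpec, make_motif, preset_sequence, sample_ensemble,
)


@pytest.fixture(scope="session")
def human_seq():
    return preset_sequence("human")


@pytest.fixture(scope="session")
def rat_seq():
    return preset_sequence("rat")


def motif_conformer(label, seq, seed=0, sigma=0.0):
    """One clash-checked conformer of a single motif."""
    mix = MixtureSpec(((make_motif(label, sigma), 1.0),), 1, seed)
    ens, _ = sample_ensemble(mix, seq)
    return ens[0]


def motif_ensemble(label, seq, n, seed=0, sigma=0.0):
    mix = MixtureSpec(((make_motif(label, sigma), 1.0),), n, seed)
    return sample_ensemble(mix, seq)


@pytest.fixture(scope="session")
def helix_coil_conf(human_seq):
    return motif_conformer("helix-coil", human_seq)


@pytest.fixture(scope="session")
def beta_hairpin_conf(human_seq):
    return motif_conformer("beta-hairpin", human_seq)


@pytest.fixture(scope="session")
def helix_hairpin_conf(human_seq):
    return motif_conformer("helix-hairpin", human_seq)


def random_rotation(rng):
    """Uniform-ish proper rotation matrix from a seeded generator."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
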