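"""Shared fixtures: one desk-scale trained model per session, plus the
standard planted-pocket fixture used by pipeline and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from strife import FragmentSpec, make_synthetic_pocket
from strife.datasets import synthetic_training_smiles
from strife.elaborator import enumerate_pairs, train

#: fixture fragment: moderately complex (SAScore ~3) so the fragment-relative
#: SAScore filter behaves as in realistic settings; exit on the carbonyl C.
FIXTURE_FRAGMENT = "[*]C(=O)NC(C)C"


@pytest.fixture(scope="session")
def training_pairs():
    smiles = synthetic_training_smiles(0, n=150)
    pairs = [p for s in smiles for p in enumerate_pairs(s)]
    assert len(pairs) >= 500
    return pairs


@pytest.fixture(scope="session")
def trained_model(training_pairs):
    return train(training_pairs)


@pytest.fixture(scope="session")
def amide_frag():
    return FragmentSpec.from_smiles(FIXTURE_FRAGMENT).embed(3)


@pytest.fixture(scope="session")
def planted_pocket(amide_frag):
    avoid = np.delete(amide_frag.coords, amide_frag.exit_atom, axis=0)
    grids, blobs = make_synthetic_pocket(
        seed=1, n_blobs=1, exit_pos=amide_frag.exit_pos, avoid_coords=avoid
    )
    return grids, blobs
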