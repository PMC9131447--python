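import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import QED

from strife import FragmentSpec
from strife.errors import EmptyInputError
from strife.metrics import (
    basic_metrics,
    delta_qed,
    delta_sle,
    extract_elaboration_smiles,
    standardize_les,
)


@pytest.fixture()
def benzene_frag():
    return FragmentSpec.from_smiles("[*]c1ccccc1")


def test_basic_metrics_hand_example(benzene_frag):
    generated = [
        "Cc1ccccc1",      # valid
        "Cc1ccccc1",      # duplicate
        "CCc1ccccc1",     # valid
        "c1ccccc1",       # no atom added -> invalid
        "CCCC",           # fragment absent -> invalid
        "not_smiles(((",  # unparseable -> invalid
    ]
    validity, uniqueness, novelty, pass_2d = basic_metrics(generated, benzene_frag)
    assert validity == pytest.approx(3 / 6)
    assert uniqueness == pytest.approx(2 / 3)
    assert novelty == pytest.approx(1.0)  # empty training set
    assert 0.0 <= pass_2d <= 1.0


def test_novelty_against_training_set(benzene_frag):
    training = {extract_elaboration_smiles(Chem.MolFromSmiles("Cc1ccccc1"), benzene_frag)}
    _, _, novelty, _ = basic_metrics(
        ["Cc1ccccc1", "CCc1ccccc1"], benzene_frag, training_elabs=training
    )
    assert novelty == pytest.approx(1 / 2)


def test_extract_elaboration_smiles(benzene_frag):
    elab = extract_elaboration_smiles("OCCc1ccccc1", benzene_frag)
    assert elab == Chem.MolToSmiles(Chem.MolFromSmiles("[*]CCO"))
    assert extract_elaboration_smiles("c1ccccc1", benzene_frag) is None


def test_basic_metrics_empty_raises(benzene_frag):
    with pytest.raises(EmptyInputError):
        basic_metrics([], benzene_frag)


def test_delta_qed_self_is_zero(benzene_frag):
    assert delta_qed([Chem.Mol(benzene_frag.mol)], benzene_frag) == pytest.approx(0.0)


def test_delta_qed_matches_brute_force(benzene_frag):
    mols = ["Cc1ccccc1", "OCc1ccccc1", "NCCc1ccccc1", "CCOc1ccccc1"]
    expected = np.mean(
        [QED.qed(Chem.MolFromSmiles(s)) - QED.qed(benzene_frag.mol) for s in mols]
    )
    assert delta_qed(mols, benzene_frag) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# delta-SLE
# ---------------------------------------------------------------------------


def test_standardization_mean_zero_sd_one():
    rng = np.random.default_rng(1)
    for _ in range(20):
        les = rng.normal(-0.5, 0.3, size=rng.integers(2, 40))
        if np.std(les, ddof=1) == 0:
            continue
        sle, _ = standardize_les(les, -0.4)
        assert abs(sle.mean()) < 1e-9
        assert abs(sle.std(ddof=1) - 1.0) < 1e-9


def test_delta_sle_worked_example_alpha_covers_all():
    # LEs {-2,-1,0}, GT -1, alpha=3: model mean 0 standardized, GT at mean -> 0
    assert delta_sle([([-2.0, -1.0, 0.0], -1.0)], alpha=3) == pytest.approx(0.0)


def test_delta_sle_worked_example_alpha_one():
    # mean -1, sample SD 1 -> standardized {-1, 0, 1}; top-1 = -1; GT -> 0
    # hand computation: delta = -1 - 0 = -1
    assert delta_sle([([-2.0, -1.0, 0.0], -1.0)], alpha=1) == pytest.approx(-1.0)


def test_delta_sle_alpha_exceeds_count_uses_all():
    assert delta_sle([([-2.0, -1.0, 0.0], -1.0)], alpha=50) == pytest.approx(0.0)


def test_delta_sle_directional_flag():
    # GT better (more negative) than every model LE
    example = [([-1.0, -0.5, 0.0], -3.0)]
    for alpha in (1, 2, 3):
        raw = delta_sle(example, alpha)
        oriented = delta_sle(example, alpha, better_positive=True)
        assert raw > 0            # model worse than GT under raw convention
        assert oriented == pytest.approx(-raw)
        assert oriented < 0       # "larger = better" orientation


def test_delta_sle_monotone_in_alpha():
    rng = np.random.default_rng(3)
    example = [(list(rng.normal(-0.5, 0.2, size=15)), -0.6)]
    oriented = [delta_sle(example, a, better_positive=True) for a in range(1, 16)]
    assert all(b <= a + 1e-12 for a, b in zip(oriented, oriented[1:]))


def test_delta_sle_zero_variance_skipped():
    # first example degenerate -> skipped with warning; second carries the value
    value = delta_sle(
        [([-1.0, -1.0, -1.0], -1.0), ([-2.0, -1.0, 0.0], -1.0)], alpha=1
    )
    assert value == pytest.approx(-1.0)
    with pytest.raises(EmptyInputError):
        delta_sle([([-1.0, -1.0], -1.0)], alpha=1)


def test_delta_sle_order_invariance():
    rng = np.random.default_rng(7)
    les = list(rng.normal(-0.5, 0.3, size=12))
    gt = -0.7
    a = delta_sle([(les, gt)], alpha=4)
    perm = list(rng.permutation(les))
    b = delta_sle([(perm, gt)], alpha=4)
    assert a == pytest.approx(b, abs=1e-12)


def test_delta_sle_validation():
    with pytest.raises(ValueError):
        delta_sle([([-1.0, 0.0], -0.5)], alpha=0)
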