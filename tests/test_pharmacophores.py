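import numpy as np
import pytest
from rdkit import Chem

from strife.errors import InvalidElaborationError, InvalidMoleculeError
from strife.hotspot_io import read_points_sdf
from strife.pharmacophores import (
    StructuralProfile,
    coarse_profile,
    fine_profile,
    make_lattice,
    perceive,
)


def _types(smiles):
    return sorted(f.ptype for f in perceive(smiles))


def test_perceive_pyridine():
    feats = perceive("c1ccncc1")
    assert _types("c1ccncc1") == ["acceptor", "aromatic"]
    arom = [f for f in feats if f.ptype == "aromatic"][0]
    assert len(arom.atom_indices) == 6


def test_perceive_phenol_oh_is_donor_and_acceptor():
    assert _types("Oc1ccccc1") == ["acceptor", "aromatic", "donor"]


def test_perceive_ethane_has_no_features():
    assert perceive("CC") == []


def test_perceive_amide_nitrogen_not_acceptor():
    # acetamide: NH2 is a donor but its delocalized lone pair is no acceptor
    feats = perceive("CC(N)=O")
    donors = [f for f in feats if f.ptype == "donor"]
    acceptors = [f for f in feats if f.ptype == "acceptor"]
    assert len(donors) == 1 and len(acceptors) == 1
    mol = Chem.MolFromSmiles("CC(N)=O")
    assert mol.GetAtomWithIdx(acceptors[0].atom_indices[0]).GetSymbol() == "O"


def test_perceive_fused_system_counted_once():
    feats = perceive("c1ccc2ccccc2c1")  # naphthalene
    arom = [f for f in feats if f.ptype == "aromatic"]
    assert len(arom) == 1
    assert len(arom[0].atom_indices) == 10


def test_perceive_unparseable_raises():
    with pytest.raises(InvalidMoleculeError):
        perceive("not-a-smiles")


def test_coarse_profile_standalone_elaboration():
    prof = coarse_profile("[*]CCO")
    assert prof.counts == (1, 1, 0)  # hydroxyl is acceptor + donor
    prof = coarse_profile("[*]Cc1ccccc1")
    assert prof.counts == (0, 0, 1)


def test_coarse_profile_restricted_to_elab_atoms():
    # phenol where only the OH (atom 0) is the elaboration
    mol = Chem.MolFromSmiles("Oc1ccccc1")
    prof = coarse_profile(mol, elab_atoms=[0])
    assert prof.counts == (1, 1, 0)  # ring belongs to the fragment


def test_fine_profile_path_distances():
    # elaboration N-C-C-O attached via the N (atom indices 1..4 in CNCCO)
    mol = Chem.MolFromSmiles("CNCCO")
    prof = fine_profile(mol, elab_atoms=[1, 2, 3, 4], attach_atom=1)
    # N at path 1 (donor+acceptor), O at path 4 (donor+acceptor)
    assert prof.counts == (2, 2, 0)
    assert sorted(prof.path_distances) == [
        ("acceptor", 1), ("acceptor", 4), ("donor", 1), ("donor", 4),
    ]


def test_fine_profile_matches_networkx_oracle(trained_model, amide_frag):
    import networkx as nx

    prof = StructuralProfile(n_acceptors=1, n_donors=1, n_aromatic=0)
    samples = trained_model.sample(amide_frag, prof, max_len=6, n=100, seed=42)
    checked = 0
    for s in samples:
        fine = fine_profile(s.mol, list(s.elab_atoms), s.attach_atom)
        g = nx.Graph()
        elab = set(s.elab_atoms)
        for b in s.mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in elab and j in elab:
                g.add_edge(i, j)
        g.add_nodes_from(elab)
        lengths = nx.single_source_shortest_path_length(g, s.attach_atom)
        from strife.pharmacophores import _elaboration_features
        expected = sorted(
            (f.ptype, min(lengths[i] for i in f.atom_indices) + 1)
            for f in _elaboration_features(s.mol, list(elab))
        )
        assert fine.path_distances == expected
        checked += 1
    assert checked == 100


def test_fine_profile_attach_must_be_elab_atom():
    mol = Chem.MolFromSmiles("CNCCO")
    with pytest.raises(InvalidElaborationError):
        fine_profile(mol, elab_atoms=[2, 3, 4], attach_atom=1)


def test_profile_validation():
    with pytest.raises(ValueError):
        StructuralProfile(n_acceptors=-1)
    with pytest.raises(ValueError):
        StructuralProfile(path_distances=[("donor", 0)])


def test_lattice_count_and_center(tmp_path):
    path = tmp_path / "lattice.sdf"
    make_lattice([1.0, -2.0, 3.0], path, extent=2, spacing=1)
    text = path.read_text()
    assert text.count("$$$$") == 125  # 5^3


def test_lattice_round_trip_of_user_selection(tmp_path):
    path = tmp_path / "lattice.sdf"
    make_lattice([0.0, 0.0, 0.0], path, extent=2, spacing=1)
    # user keeps two records and retypes them (element convention)
    blocks = path.read_text().split("$$$$\n")
    kept = blocks[0].replace(" C ", " N ") + "$$$$\n" + blocks[7].replace(" C ", " O ") + "$$$$\n"
    sel = tmp_path / "selected.sdf"
    sel.write_text(kept)
    points = read_points_sdf(sel)
    assert [p.ptype for p in points] == ["donor", "acceptor"]
    assert all(p.source == "manual" for p in points)


def test_lattice_carbon_records_ignored_on_read(tmp_path):
    path = tmp_path / "lattice.sdf"
    make_lattice([0.0, 0.0, 0.0], path, extent=2, spacing=1)
    assert read_points_sdf(path) == []
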