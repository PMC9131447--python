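import numpy as np
import pytest
from rdkit import Chem

from strife import FragmentSpec
from strife.hotspot_io import PharmacophoricPoint
from strife.hotspot_processing import VoxelPointSet
from strife.scoring import (
    FRAGMENT_RMSD_TOL,
    Pose,
    ScoredElaboration,
    ScoringWeights,
    SurrogateBackend,
    constrained_pose,
    ligand_efficiency,
    min_pharm_distance,
    optimize_pose_dihedrals,
    surrogate_score,
)


def test_ligand_efficiency_arithmetic():
    assert ligand_efficiency(-10.0, 20) == pytest.approx(-0.5)
    assert ligand_efficiency(4.0, 8) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        ligand_efficiency(-1.0, 0)


def test_scored_elaboration_computes_le():
    pose = Pose(coords=np.zeros((3, 3)), score=-6.0, fragment_rmsd=0.1)
    s = ScoredElaboration(smiles="CCC", best_pose=pose, heavy_atoms=3)
    assert s.ligand_efficiency == pytest.approx(-2.0)


def _simple_pose(smiles, coords, elab_atoms):
    mol = Chem.MolFromSmiles(smiles)
    return Pose(
        coords=np.asarray(coords, float),
        score=0.0,
        fragment_rmsd=0.0,
        mol=mol,
        elab_atoms=tuple(elab_atoms),
    )


def test_surrogate_pose_outside_pocket_scores_nonnegative():
    pocket = VoxelPointSet("apolar", [[0, 0, 0]], [2.0])
    pose = _simple_pose("CCC", [[50, 0, 0], [51, 0, 0], [52, 0, 0]], [])
    assert surrogate_score(pose, pocket) >= 0


def test_surrogate_exact_match_reward():
    w = ScoringWeights()
    pocket = VoxelPointSet("apolar", [[0, 0, 0], [1.4, 0, 0]], [2.0, 2.0])
    # ethanol: C-C-O with the O (atom 2) as the elaboration donor/acceptor
    target = PharmacophoricPoint("acceptor", [1.4, 0.0, 0.0])
    pose = _simple_pose("CCO", [[0, 0, 0], [0.7, 0, 0], [1.4, 0, 0]], [2])
    with_target = surrogate_score(pose, pocket, [target], w)
    without = surrogate_score(pose, pocket, [], w)
    assert with_target == pytest.approx(without - w.w_pharm)  # reward = w2 at d=0


def test_surrogate_monotone_in_match_distance():
    w = ScoringWeights()
    pocket = VoxelPointSet(
        "apolar", [[x / 2, 0, 0] for x in range(-2, 14)], np.ones(16) * 2
    )
    target = PharmacophoricPoint("acceptor", [1.4, 0.0, 0.0])
    scores = []
    for shift in np.linspace(0, 1.5, 7):
        pose = _simple_pose(
            "CCO", [[0, 0, 0], [0.7, 0, 0], [1.4 + shift, 0, 0]], [2]
        )
        scores.append(surrogate_score(pose, pocket, [target], w))
    assert all(b >= a for a, b in zip(scores, scores[1:]))
    assert scores[-1] > scores[0]


def test_surrogate_translation_equivariance():
    rng = np.random.default_rng(5)
    coords = rng.uniform(-2, 2, size=(3, 3))
    pocket_pts = rng.uniform(-3, 3, size=(30, 3))
    target_pos = rng.uniform(-2, 2, size=3)
    t = np.array([7.0, -3.0, 11.0])
    a = surrogate_score(
        _simple_pose("CCO", coords, [2]),
        VoxelPointSet("apolar", pocket_pts, np.ones(30)),
        [PharmacophoricPoint("acceptor", target_pos)],
    )
    b = surrogate_score(
        _simple_pose("CCO", coords + t, [2]),
        VoxelPointSet("apolar", pocket_pts + t, np.ones(30)),
        [PharmacophoricPoint("acceptor", target_pos + t)],
    )
    assert a == pytest.approx(b, abs=1e-9)


def test_min_pharm_distance_matches_manual():
    pose = _simple_pose("CCO", [[0, 0, 0], [0.7, 0, 0], [1.4, 0, 0]], [2])
    target = PharmacophoricPoint("acceptor", [2.4, 0.0, 0.0])
    assert min_pharm_distance(pose, target) == pytest.approx(1.0, abs=1e-6)
    donor_target = PharmacophoricPoint("donor", [2.4, 0.0, 0.0])
    # hydroxyl O is also a donor
    assert min_pharm_distance(pose, donor_target) == pytest.approx(1.0, abs=1e-6)
    # no aromatic features in the elaboration -> +inf for unmatched types
    carbon_only = _simple_pose("CCC", np.zeros((3, 3)), [2])
    assert min_pharm_distance(carbon_only, target) == float("inf")


def test_constrained_pose_pins_fragment(amide_frag):
    mol = Chem.MolFromSmiles("CC(C)NC(=O)CCO")
    poses = constrained_pose(mol, amide_frag, n_poses=8, seed=4)
    assert poses
    match = mol.GetSubstructMatch(amide_frag.mol)
    for pose in poses:
        rmsd = np.sqrt(
            np.mean(np.sum((pose.coords[list(match)] - amide_frag.coords) ** 2, axis=1))
        )
        assert rmsd <= FRAGMENT_RMSD_TOL + 1e-9
        assert pose.fragment_rmsd == pytest.approx(rmsd, abs=1e-6)


def test_constrained_pose_requires_fragment_substructure(amide_frag):
    with pytest.raises(ValueError):
        constrained_pose(Chem.MolFromSmiles("c1ccccc1"), amide_frag)


def test_dihedral_optimization_improves_match(amide_frag):
    mol = Chem.MolFromSmiles("CC(C)NC(=O)CCCN")
    poses = constrained_pose(mol, amide_frag, n_poses=6, seed=2)
    # place the target reachable by the terminal amine
    target = PharmacophoricPoint("donor", amide_frag.exit_pos + np.array([3.0, 1.0, 0.0]))
    for pose in poses[:3]:
        before = min_pharm_distance(pose, target)
        opt = optimize_pose_dihedrals(pose, [target])
        after = min_pharm_distance(opt, target)
        assert after <= before + 1e-9
        # fragment untouched
        match = mol.GetSubstructMatch(amide_frag.mol)
        assert np.allclose(opt.coords[list(match)], pose.coords[list(match)], atol=1e-6)


def test_backend_returns_best_scoring_pose(amide_frag):
    rng = np.random.default_rng(0)
    pts = amide_frag.exit_pos + rng.uniform(-4, 4, size=(400, 3))
    pocket = VoxelPointSet("apolar", pts, np.ones(400) * 2)
    backend = SurrogateBackend(pocket=pocket, n_poses=5)
    mol = Chem.MolFromSmiles("CC(C)NC(=O)CC")
    pose = backend.pose_and_score(mol, amide_frag, seed=1)
    assert pose.fragment_rmsd <= FRAGMENT_RMSD_TOL
    # deterministic
    again = backend.pose_and_score(mol, amide_frag, seed=1)
    assert np.allclose(pose.coords, again.coords)
    assert pose.score == pytest.approx(again.score)
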