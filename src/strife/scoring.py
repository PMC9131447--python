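"""Fragment-constrained 3D posing and pocket-complementarity scoring.

Poses are generated by distance-geometry embedding with the fragment atoms
pinned to their input coordinates (coordinate-map constraint plus a final
rigid alignment onto the fragment frame), mirroring constrained docking:
each molecule is posed several times and the top-scoring pose kept.

The default scorer is a geometric surrogate with a docking-score sign
convention (more negative = better): it rewards heavy atoms in contact with
the apolar hotspot envelope and elaboration pharmacophores placed near their
target points, and penalizes atoms that leave the envelope. An external
docking program can be swapped in behind the same interface; pipeline control
flow never depends on which backend produced the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .errors import PoseFailureError
from .fragment import FragmentSpec
from .hotspot_io import PharmacophoricPoint
from .hotspot_processing import VoxelPointSet
from .pharmacophores import perceive

logger = logging.getLogger(__name__)

#: maximum allowed RMSD of fragment atoms from their input coordinates
FRAGMENT_RMSD_TOL = 0.5


@dataclass
class Pose:
    """One 3D pose: heavy-atom coordinates in the protein frame plus score."""

    coords: np.ndarray           # (n_heavy, 3)
    score: float
    fragment_rmsd: float
    mol: Chem.Mol = None         # topology the coords refer to
    elab_atoms: tuple[int, ...] = ()

    def as_mol(self) -> Chem.Mol:
        """Copy of the molecule carrying this pose as its conformer."""
        mol = Chem.Mol(self.mol)
        mol.RemoveAllConformers()
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
        mol.AddConformer(conf)
        return mol


@dataclass
class ScoredElaboration:
    """A posed and scored molecule with its ligand efficiency."""

    smiles: str
    best_pose: Pose
    heavy_atoms: int
    ligand_efficiency: float = field(init=False)

    def __post_init__(self) -> None:
        self.ligand_efficiency = ligand_efficiency(self.best_pose.score, self.heavy_atoms)


def ligand_efficiency(score: float, heavy_atoms: int) -> float:
    """Docking score divided by heavy-atom count (size-normalized score)."""
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return score / heavy_atoms


@dataclass
class ScoringWeights:
    """Surrogate-score weights; distances in Å."""

    w_contact: float = 0.3
    w_pharm: float = 5.0
    w_clash: float = 1.0
    pharm_falloff: float = 1.5
    containment_tol: float = 0.5


class Scorer(Protocol):
    def __call__(self, pose: Pose) -> float: ...


def constrained_pose(
    mol: Chem.Mol,
    frag: FragmentSpec,
    n_poses: int = 10,
    seed: int = 0,
    scorer: Scorer | None = None,
    elab_atoms: Sequence[int] | None = None,
) -> list[Pose]:
    """Generate up to ``n_poses`` poses with the fragment pinned to its coords.

    Poses whose fragment RMSD exceeds 0.5 Å after rigid alignment are
    discarded. The returned list is sorted by score ascending (best first);
    ties break deterministically. Raises :class:`PoseFailureError` when no
    embedding satisfies the constraint.
    """
    if frag.coords is None:
        raise ValueError("fragment must carry 3D coordinates")
    match = mol.GetSubstructMatch(frag.mol)
    if not match:
        raise ValueError("molecule does not contain the fragment")
    if elab_atoms is None:
        elab_atoms = tuple(i for i in range(mol.GetNumAtoms()) if i not in set(match))

    molH = Chem.AddHs(Chem.Mol(mol))
    coord_map = {
        int(match[i]): Point3D(*map(float, frag.coords[i]))
        for i in range(frag.mol.GetNumAtoms())
    }
    # reference fragment with its conformer, for rigid alignment
    ref = Chem.Mol(frag.mol)
    ref_conf = Chem.Conformer(ref.GetNumAtoms())
    for i, xyz in enumerate(frag.coords):
        ref_conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    ref.RemoveAllConformers()
    ref.AddConformer(ref_conf)
    atom_map = [(int(match[i]), i) for i in range(frag.mol.GetNumAtoms())]

    conf_ids: list[int] = []
    for attempt in range(3):
        conf_ids = list(
            AllChem.EmbedMultipleConfs(
                molH,
                numConfs=n_poses,
                coordMap=coord_map,
                randomSeed=seed + 1000 * attempt + 1,
                useRandomCoords=attempt > 0,
                clearConfs=True,
            )
        )
        if conf_ids:
            break
    if not conf_ids:
        raise PoseFailureError("constrained embedding failed after retries")

    n_heavy = mol.GetNumAtoms()
    poses: list[Pose] = []
    for cid in conf_ids:
        AllChem.AlignMol(molH, ref, prbCid=cid, atomMap=atom_map)
        conf = molH.GetConformer(cid)
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n_heavy)])
        frag_rmsd = float(
            np.sqrt(np.mean(np.sum((coords[list(match)] - frag.coords) ** 2, axis=1)))
        )
        if frag_rmsd > FRAGMENT_RMSD_TOL:
            continue
        pose = Pose(
            coords=coords,
            score=0.0,
            fragment_rmsd=frag_rmsd,
            mol=mol,
            elab_atoms=tuple(elab_atoms),
        )
        if scorer is not None:
            pose.score = float(scorer(pose))
        poses.append(pose)
    if not poses:
        raise PoseFailureError("no pose satisfied the fragment RMSD constraint")
    poses.sort(key=lambda p: (p.score, p.fragment_rmsd, p.coords.sum()))
    return poses


def _elab_pharmacophore_positions(
    pose: Pose, ptype: str
) -> list[np.ndarray]:
    """3D positions of elaboration pharmacophores of one type in a pose."""
    mol = pose.as_mol()
    elab = set(pose.elab_atoms)
    positions = []
    for feat in perceive(mol):
        if feat.ptype != ptype:
            continue
        if feat.ptype == "aromatic":
            if not set(feat.atom_indices) <= elab:
                continue
        elif feat.atom_indices[0] not in elab:
            continue
        positions.append(np.asarray(feat.position))
    return positions


def _elab_feature_atoms(mol: Chem.Mol, elab: set[int]) -> list[tuple[str, tuple[int, ...]]]:
    """(ptype, atom indices) of pharmacophoric features in the elaboration."""
    out = []
    for feat in perceive(mol):
        if feat.ptype == "aromatic":
            if not set(feat.atom_indices) <= elab:
                continue
        elif feat.atom_indices[0] not in elab:
            continue
        out.append((feat.ptype, feat.atom_indices))
    return out


def _rotatable_dihedrals(mol: Chem.Mol, elab: set[int]) -> list[tuple[int, int, int, int]]:
    """Dihedral atom quadruples (i, j, k, l) for acyclic single bonds whose
    rotation moves only elaboration atoms (the l-side of the j-k bond)."""
    quads = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a not in elab and b not in elab:
            continue
        # the side containing fragment atoms must stay fixed; find it by BFS
        def side(start: int, other: int) -> set[int]:
            seen, stack = {start}, [start]
            while stack:
                cur = stack.pop()
                for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
                    n = nb.GetIdx()
                    if n == other and cur == start:
                        continue
                    if {cur, n} == {a, b}:
                        continue
                    if n not in seen:
                        seen.add(n)
                        stack.append(n)
            return seen
        side_a = side(a, b)
        if side_a <= elab:
            j, k, moving = b, a, side_a
        else:
            side_b = side(b, a)
            if not side_b <= elab:
                continue  # rotation would move fragment atoms
            j, k, moving = a, b, side_b
        if len(moving) < 2:
            continue  # rotating a terminal atom about its own bond is a no-op
        i_opts = [n.GetIdx() for n in mol.GetAtomWithIdx(j).GetNeighbors() if n.GetIdx() != k]
        l_opts = [n.GetIdx() for n in mol.GetAtomWithIdx(k).GetNeighbors() if n.GetIdx() != j]
        if not i_opts or not l_opts:
            continue
        quads.append((min(i_opts), j, k, min(l_opts)))
    return quads


def optimize_pose_dihedrals(
    pose: Pose,
    targets: Sequence[PharmacophoricPoint],
    step_deg: float = 30.0,
    passes: int = 2,
) -> Pose:
    """Greedy rigid-rotor refinement of the elaboration toward target points.

    Acyclic single bonds whose rotation moves only elaboration atoms are
    scanned in ``step_deg`` increments, minimizing the summed distance from
    each target to its nearest matching elaboration pharmacophore (the
    surrogate analogue of docking's pose optimization). The fragment atoms
    never move; deterministic.
    """
    from rdkit.Chem import rdMolTransforms

    if not targets:
        return pose
    mol = pose.as_mol()
    elab = set(pose.elab_atoms)
    features = _elab_feature_atoms(mol, elab)
    wanted = {t.ptype for t in targets}
    features = [f for f in features if f[0] in wanted]
    if not features:
        return pose
    quads = _rotatable_dihedrals(mol, elab)
    if not quads:
        return pose
    conf = mol.GetConformer()

    def objective() -> float:
        total = 0.0
        for t in targets:
            best = None
            for ptype, idxs in features:
                if ptype != t.ptype:
                    continue
                pos = np.mean([list(conf.GetAtomPosition(i)) for i in idxs], axis=0)
                d = float(np.linalg.norm(pos - t.position))
                best = d if best is None or d < best else best
            if best is not None:
                total += best
        return total

    angles = np.arange(0.0, 360.0, step_deg)
    for _ in range(passes):
        for i, j, k, l in quads:
            best_angle = rdMolTransforms.GetDihedralDeg(conf, i, j, k, l)
            best_obj = objective()
            for ang in angles:
                rdMolTransforms.SetDihedralDeg(conf, i, j, k, l, float(ang))
                obj = objective()
                if obj < best_obj - 1e-9:
                    best_obj, best_angle = obj, float(ang)
            rdMolTransforms.SetDihedralDeg(conf, i, j, k, l, best_angle)

    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    return Pose(
        coords=coords,
        score=pose.score,
        fragment_rmsd=pose.fragment_rmsd,
        mol=pose.mol,
        elab_atoms=pose.elab_atoms,
    )


def min_pharm_distance(pose: Pose, target: PharmacophoricPoint) -> float:
    """Distance from a target point to the nearest matching elaboration
    pharmacophore; +inf when the pose has no pharmacophore of that type."""
    positions = _elab_pharmacophore_positions(pose, target.ptype)
    if not positions:
        return float("inf")
    return float(min(np.linalg.norm(p - target.position) for p in positions))


def surrogate_score(
    pose: Pose,
    pocket: VoxelPointSet,
    targets: Sequence[PharmacophoricPoint] = (),
    weights: ScoringWeights | None = None,
) -> float:
    """Geometric pocket-complementarity score (more negative = better).

    ``score = -(w_contact * n_contacts + w_pharm * sum(match rewards))
    + w_clash * n_outside`` where a heavy atom is in contact when within the
    containment tolerance of an apolar voxel, a pharmacophore match reward is
    ``max(0, 1 - d / 1.5)`` for distance d to the target point, and atoms
    outside the apolar envelope count as clashes.
    """
    weights = weights or ScoringWeights()
    if len(pocket) == 0:
        return float(weights.w_clash * len(pose.coords))
    from scipy.spatial import cKDTree

    tree = cKDTree(pocket.points)
    d, _ = tree.query(pose.coords)
    contacts = int(np.sum(d <= weights.containment_tol))
    outside = int(np.sum(d > weights.containment_tol))
    reward = 0.0
    for target in targets:
        dist = min_pharm_distance(pose, target)
        if np.isfinite(dist):
            reward += max(0.0, 1.0 - dist / weights.pharm_falloff)
    return float(
        -(weights.w_contact * contacts + weights.w_pharm * reward)
        + weights.w_clash * outside
    )


@dataclass
class SurrogateBackend:
    """Default scoring backend bundling the pocket context."""

    pocket: VoxelPointSet
    targets: tuple[PharmacophoricPoint, ...] = ()
    weights: ScoringWeights = field(default_factory=ScoringWeights)
    n_poses: int = 10
    optimize: bool = True

    def pose_and_score(
        self, mol: Chem.Mol, frag: FragmentSpec, seed: int,
        elab_atoms: Sequence[int] | None = None,
    ) -> Pose:
        """Constrained posing with the surrogate scorer; returns the best pose.

        Each embedded pose is first refined toward the target points by rigid
        dihedral rotations (fragment pinned), then scored; the best-scoring
        pose wins, ties breaking deterministically.
        """
        poses = constrained_pose(
            mol, frag, n_poses=self.n_poses, seed=seed, elab_atoms=elab_atoms,
        )
        if self.optimize:
            poses = [optimize_pose_dihedrals(p, self.targets) for p in poses]
        for pose in poses:
            pose.score = surrogate_score(pose, self.pocket, self.targets, self.weights)
        poses.sort(key=lambda p: (p.score, p.fragment_rmsd, p.coords.sum()))
        return poses[0]


@dataclass
class ExternalCommandBackend:
    """Contract stub for an external constrained-docking program.

    An adapter must pose each molecule ``n_poses`` times with the fragment
    coordinates as the constraint, keep the top-ranked pose and return its
    score on a more-negative-is-better scale. ``flexible_residues`` is passed
    through for protocols that allow pocket side-chain flexibility.
    """

    command: str
    n_poses: int = 10
    flexible_residues: tuple[str, ...] = ()

    def pose_and_score(self, mol, frag, seed, elab_atoms=None):  # pragma: no cover
        raise NotImplementedError(
            "wire an external docking adapter here; the built-in surrogate "
            "backend is the default"
        )
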