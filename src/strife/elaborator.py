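"""Training-pair enumeration, model training/sampling, and the exit-to-point
atom-path-length regressor.

Training pairs are produced by cutting every acyclic single bond that is not
part of a functional group, the larger side becoming the fragment and the
smaller the elaboration (both orientations when the halves tie). The
functional-group exclusion set below protects amides, esters, sulfonamides,
nitro groups and similar units from being split through the middle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from sklearn.svm import SVR

from .errors import UntrainedModelError
from .fragment import FragmentSpec
from .genmodel import ElaborationModel, ModelConfig, SampledElaboration
from .pharmacophores import StructuralProfile

logger = logging.getLogger(__name__)

#: bonds touching an atom matched by any of these SMARTS are never cut
FUNCTIONAL_GROUP_SMARTS = (
    "[NX3][CX3]=[OX1]",          # amide
    "[CX3](=[OX1])[OX2][#6]",    # ester
    "[NX3][SX4](=[OX1])=[OX1]",  # sulfonamide
    "[NX3+](=O)[O-]",            # nitro (charged form)
    "N(=O)=O",                   # nitro (neutral form)
    "[CX3](=[OX1])[OX2H1]",      # carboxylic acid
    "C#N",                       # nitrile
    "[SX4](=[OX1])(=[OX1])",     # sulfone/sulfonyl
)
_FG_PATTERNS = [Chem.MolFromSmarts(s) for s in FUNCTIONAL_GROUP_SMARTS]


@dataclass
class TrainingPair:
    """A (fragment, elaboration) pair cut from a whole molecule."""

    mol: Chem.Mol
    fragment: FragmentSpec
    elab_atoms: tuple[int, ...]
    exit_atom: int     # fragment-side cut atom, in whole-molecule indexing
    attach_atom: int   # elaboration-side cut atom, in whole-molecule indexing
    elab_smiles: str   # elaboration with attachment dummy


def _functional_group_atoms(mol: Chem.Mol) -> set[int]:
    atoms: set[int] = set()
    for patt in _FG_PATTERNS:
        for match in mol.GetSubstructMatches(patt):
            atoms.update(match)
    return atoms


def _side_atoms(mol: Chem.Mol, start: int, blocked_bond: tuple[int, int]) -> set[int]:
    """Atoms reachable from ``start`` without crossing the blocked bond."""
    seen = {start}
    stack = [start]
    a, b = blocked_bond
    while stack:
        cur = stack.pop()
        for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
            j = nb.GetIdx()
            if {cur, j} == {a, b}:
                continue
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return seen


def _submol_with_dummy(mol: Chem.Mol, atoms: set[int], cut_atom: int) -> str:
    """SMILES of the induced subgraph with an attachment dummy on cut_atom."""
    rw = Chem.RWMol()
    amap = {}
    for i in sorted(atoms):
        src = mol.GetAtomWithIdx(i)
        a = Chem.Atom(src.GetAtomicNum())
        a.SetFormalCharge(src.GetFormalCharge())
        a.SetIsAromatic(src.GetIsAromatic())
        a.SetNumExplicitHs(src.GetNumExplicitHs())
        amap[i] = rw.AddAtom(a)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in amap and j in amap:
            rw.AddBond(amap[i], amap[j], bond.GetBondType())
    dummy = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(amap[cut_atom], dummy, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def enumerate_pairs(mol: Chem.Mol | str) -> list[TrainingPair]:
    """Enumerate fragment/elaboration pairs from all eligible bond cuts.

    Eligible bonds are acyclic single bonds with neither endpoint inside a
    functional group. The larger side becomes the fragment; equal halves
    yield both orientations.
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
        mol = parsed
    if mol.GetNumHeavyAtoms() < 2:
        return []
    fg_atoms = _functional_group_atoms(mol)
    pairs: list[TrainingPair] = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in fg_atoms or b in fg_atoms:
            continue
        side_a = _side_atoms(mol, a, (a, b))
        side_b = _side_atoms(mol, b, (a, b))
        orientations = []
        if len(side_a) > len(side_b):
            orientations = [(side_a, a, side_b, b)]
        elif len(side_b) > len(side_a):
            orientations = [(side_b, b, side_a, a)]
        else:
            orientations = [(side_a, a, side_b, b), (side_b, b, side_a, a)]
        for frag_atoms, exit_atom, elab_atoms, attach_atom in orientations:
            frag_smiles = _submol_with_dummy(mol, frag_atoms, exit_atom)
            elab_smiles = _submol_with_dummy(mol, elab_atoms, attach_atom)
            try:
                frag = FragmentSpec.from_smiles(frag_smiles)
            except Exception:
                continue
            pairs.append(
                TrainingPair(
                    mol=mol,
                    fragment=frag,
                    elab_atoms=tuple(sorted(elab_atoms)),
                    exit_atom=exit_atom,
                    attach_atom=attach_atom,
                    elab_smiles=elab_smiles,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# model training / sampling facade
# ---------------------------------------------------------------------------


def train(pairs: Sequence[TrainingPair], config: ModelConfig | None = None) -> ElaborationModel:
    """Fit the profile-conditioned generator on fragment/elaboration pairs."""
    config = config or ModelConfig()
    model = ElaborationModel(config)
    return model.fit(list(pairs))


def sample(
    model: ElaborationModel,
    frag: FragmentSpec,
    profile: StructuralProfile,
    max_len: int,
    n: int,
    seed: int,
    guided: bool = True,
) -> list[str]:
    """Sample elaborated molecules as SMILES (see model.sample for details)."""
    return [s.smiles for s in model.sample(frag, profile, max_len, n, seed, guided=guided)]


def sample_detailed(
    model: ElaborationModel,
    frag: FragmentSpec,
    profile: StructuralProfile,
    max_len: int,
    n: int,
    seed: int,
    guided: bool = True,
) -> list[SampledElaboration]:
    return model.sample(frag, profile, max_len, n, seed, guided=guided)


# ---------------------------------------------------------------------------
# exit-to-pharmacophore atom path length prediction
# ---------------------------------------------------------------------------


@dataclass
class LengthPrediction:
    """Predicted shortest-path atom count p and the sampling cap p + 4."""

    p: int
    max_len: int

    def __post_init__(self) -> None:
        if not (1 <= self.p <= self.max_len):
            raise ValueError("need 1 <= p <= max_len")


class PathLengthModel:
    """Regressor mapping Euclidean exit-to-point distance to atom path length.

    Features are the raw distance plus a one-hot distance bucket (1 Å bins),
    fitted with a linear support-vector regressor. Roughly 1.3 Å of spatial
    reach per chain atom is typical of relaxed elaboration geometries, so a
    monotone, near-linear mapping is the expected shape.
    """

    N_BUCKETS = 8

    def __init__(self) -> None:
        self._svr = SVR(kernel="linear", C=10.0, epsilon=0.1)
        self.fitted = False

    def _features(self, distances: np.ndarray) -> np.ndarray:
        d = np.asarray(distances, dtype=float).reshape(-1)
        buckets = np.clip(d.astype(int), 0, self.N_BUCKETS - 1)
        onehot = np.zeros((len(d), self.N_BUCKETS))
        onehot[np.arange(len(d)), buckets] = 1.0
        return np.column_stack([d, onehot])

    def fit(self, distances: Sequence[float], path_lengths: Sequence[int]) -> "PathLengthModel":
        X = self._features(np.asarray(distances))
        y = np.asarray(path_lengths, dtype=float)
        self._svr.fit(X, y)
        self.fitted = True
        return self

    def predict(self, distances: Sequence[float] | float) -> np.ndarray:
        if not self.fitted:
            raise UntrainedModelError("path-length model is not fitted")
        d = np.atleast_1d(np.asarray(distances, dtype=float))
        return self._svr.predict(self._features(d))


def synthetic_path_length_data(
    seed: int,
    n: int = 400,
    angstrom_per_atom: float = 1.3,
    noise_sd: float = 0.25,
    d_range: tuple[float, float] = (0.5, 8.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (distance, path length) pairs emulating posed chain geometry:
    each chain atom extends the reach by about 1.3 Å, with placement noise."""
    rng = np.random.default_rng(seed)
    d = rng.uniform(*d_range, size=n)
    p = np.maximum(1, np.round(d / angstrom_per_atom + rng.normal(0, noise_sd, n))).astype(int)
    return d, p


def default_path_length_model(seed: int = 0) -> PathLengthModel:
    """Path-length model fitted on synthetic chain geometry."""
    d, p = synthetic_path_length_data(seed)
    return PathLengthModel().fit(d, p)


def predict_path_length(
    exit_pos: Sequence[float],
    point,
    model: PathLengthModel,
    headroom: int = 4,
) -> LengthPrediction:
    """Predict the atom-path length from the exit vector to a pharmacophoric
    point; the sampling cap allows ``headroom`` extra atoms for rings and
    side chains."""
    if not model.fitted:
        raise UntrainedModelError("path-length model is not fitted")
    dist = float(np.linalg.norm(np.asarray(exit_pos, float) - point.position))
    p = max(1, int(round(float(model.predict(dist)[0]))))
    return LengthPrediction(p=p, max_len=p + headroom)
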