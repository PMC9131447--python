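"""Evaluation metrics for generated elaboration sets.

2D metrics: validity (parseable and at least one atom added), uniqueness
(distinct / total over valid), novelty (elaboration not in the training set),
2D-filter pass rate, and the mean QED difference to the fragment.

3D metric: standardized ligand efficiency (SLE). Ligand efficiencies within
one example are standardized to zero mean / unit variance over the model's
molecules, the ground truth transformed with the same parameters. The
top-alpha metric averages the alpha best standardized LEs (best = most
negative raw LE, the docking convention used throughout this package) and
subtracts the standardized ground truth:

    dSLE_alpha_j = SLE_alpha_j - SLE_GT_j,   dSLE_alpha = mean_j dSLE_alpha_j

Under the docking sign convention this raw difference is *negative* when the
model beats the ground truth. Reports that want "larger = better" (the usual
reading when scores are positive-better fitness values) can set
``better_positive=True``, which negates the result; one flag, applied
uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import QED

from .errors import EmptyInputError
from .fragment import FragmentSpec
from .pipeline import filter_2d

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    validity: float
    uniqueness: float
    novelty: float
    pass_2d: float
    delta_qed: float | None = None
    delta_sle: dict[int, float] = field(default_factory=dict)
    n_generated: int = 0

    def as_dict(self) -> dict:
        out = {
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "pass_2d": self.pass_2d,
            "n_generated": self.n_generated,
        }
        if self.delta_qed is not None:
            out["delta_qed"] = self.delta_qed
        for a, v in self.delta_sle.items():
            out[f"delta_sle_{a}"] = v
        return out


def extract_elaboration_smiles(mol: Chem.Mol | str, frag: FragmentSpec) -> str | None:
    """Canonical SMILES (with attachment dummy) of the elaboration part of a
    generated molecule, or None when the molecule does not extend the
    fragment by a single connected attachment."""
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            return None
    match = mol.GetSubstructMatch(frag.mol)
    if not match:
        return None
    frag_atoms = set(match)
    elab_atoms = [i for i in range(mol.GetNumAtoms()) if i not in frag_atoms]
    if not elab_atoms:
        return None
    attach = [
        i
        for i in elab_atoms
        if any(nb.GetIdx() in frag_atoms for nb in mol.GetAtomWithIdx(i).GetNeighbors())
    ]
    if len(attach) != 1:
        return None
    rw = Chem.RWMol()
    amap = {}
    for i in elab_atoms:
        src = mol.GetAtomWithIdx(i)
        a = Chem.Atom(src.GetAtomicNum())
        a.SetFormalCharge(src.GetFormalCharge())
        a.SetIsAromatic(src.GetIsAromatic())
        amap[i] = rw.AddAtom(a)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in amap and j in amap:
            rw.AddBond(amap[i], amap[j], bond.GetBondType())
    dummy = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(amap[attach[0]], dummy, Chem.BondType.SINGLE)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def basic_metrics(
    generated: Sequence[str],
    frag: FragmentSpec,
    training_elabs: set[str] | None = None,
) -> tuple[float, float, float, float]:
    """(validity, uniqueness, novelty, pass_2d) of a generated SMILES list.

    A molecule is valid when it parses and adds at least one atom to the
    fragment. Uniqueness, novelty and the 2D pass rate are computed over the
    valid molecules; novelty compares canonical elaborations against the
    training elaboration set.
    """
    if not generated:
        raise EmptyInputError("no generated molecules to evaluate")
    training_elabs = training_elabs or set()
    frag_canonical = Chem.MolToSmiles(frag.mol)
    valid_mols: list[tuple[str, Chem.Mol]] = []
    for smi in generated:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        if Chem.MolToSmiles(mol) == frag_canonical:
            continue  # no atom added
        if not mol.HasSubstructMatch(frag.mol):
            continue
        valid_mols.append((Chem.MolToSmiles(mol), mol))
    validity = len(valid_mols) / len(generated)
    if not valid_mols:
        return validity, 0.0, 0.0, 0.0
    distinct = {s for s, _ in valid_mols}
    uniqueness = len(distinct) / len(valid_mols)
    novel = 0
    passed = 0
    for smi, mol in valid_mols:
        elab = extract_elaboration_smiles(mol, frag)
        if elab is None or elab not in training_elabs:
            novel += 1
        if not filter_2d(mol, frag):
            passed += 1
    novelty = novel / len(valid_mols)
    pass_2d = passed / len(valid_mols)
    return validity, uniqueness, novelty, pass_2d


def delta_qed(mols: Sequence[Chem.Mol | str], frag: FragmentSpec) -> float:
    """Mean QED difference between elaborated molecules and their fragment."""
    if not mols:
        raise EmptyInputError("no molecules")
    q_frag = QED.qed(frag.mol)
    diffs = []
    for m in mols:
        if isinstance(m, str):
            m = Chem.MolFromSmiles(m)
            if m is None:
                continue
        diffs.append(QED.qed(m) - q_frag)
    return float(np.mean(diffs))


def standardize_les(les: Sequence[float], gt: float) -> tuple[np.ndarray, float]:
    """Standardize model LEs to zero mean / unit sample variance; transform
    the ground truth with the same parameters (it does not enter the fit)."""
    arr = np.asarray(les, dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least two ligand efficiencies")
    mu = arr.mean()
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (arr - mu) / sd, (gt - mu) / sd


def delta_sle(
    per_example: Sequence[tuple[Sequence[float], float]],
    alpha: int,
    better_positive: bool = False,
) -> float:
    """Mean over examples of (top-alpha mean standardized LE - standardized
    ground truth LE).

    Best molecules are the most negative raw LEs (docking convention). When
    ``alpha`` exceeds an example's molecule count, all its molecules are
    used. Zero-variance examples are skipped with a warning. With
    ``better_positive=True`` the sign is flipped so that positive values mean
    the model beat the ground truth.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    deltas = []
    for j, (les, gt) in enumerate(per_example):
        try:
            sle, sle_gt = standardize_les(les, gt)
        except ValueError:
            logger.warning("example %d skipped (fewer than 2 LEs or zero variance)", j)
            continue
        top = np.sort(sle)[: min(alpha, len(sle))]  # ascending: most negative first
        deltas.append(top.mean() - sle_gt)
    if not deltas:
        raise EmptyInputError("no usable examples for delta-SLE")
    out = float(np.mean(deltas))
    return -out if better_positive else out
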