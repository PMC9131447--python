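"""Fragment representation: molecular graph, optional 3D coords, exit vector.

The exit vector is the fragment heavy atom from which an elaboration grows.
In SMILES form the attachment is marked with a dummy atom (``[*]``), the
common convention for attachment points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import InvalidMoleculeError


@dataclass
class FragmentSpec:
    """A fragment to elaborate: graph, optional per-atom coords, exit atom."""

    mol: Chem.Mol
    exit_atom: int
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.exit_atom < self.mol.GetNumAtoms()):
            raise ValueError("exit_atom index out of range")
        atom = self.mol.GetAtomWithIdx(self.exit_atom)
        if atom.GetTotalNumHs() + atom.GetNumRadicalElectrons() < 1 and atom.GetTotalValence() >= Chem.GetPeriodicTable().GetDefaultValence(atom.GetAtomicNum()):
            raise ValueError("exit atom has no free valence for elaboration")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.mol.GetNumAtoms(), 3):
                raise ValueError("coords must be (n_atoms, 3)")

    @classmethod
    def from_smiles(cls, smiles: str, coords: np.ndarray | None = None) -> "FragmentSpec":
        """Build from a SMILES with the attachment marked by a dummy atom.

        ``coords`` (if given) refer to the heavy atoms after dummy removal,
        in RDKit atom order.
        """
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise InvalidMoleculeError(f"unparseable SMILES: {smiles!r}")
        dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise InvalidMoleculeError(
                "fragment SMILES must contain exactly one attachment dummy atom"
            )
        dummy = dummies[0]
        neighbors = [a.GetIdx() for a in mol.GetAtomWithIdx(dummy).GetNeighbors()]
        if len(neighbors) != 1:
            raise InvalidMoleculeError("attachment dummy must have exactly one neighbor")
        exit_atom = neighbors[0]
        rw = Chem.RWMol(mol)
        rw.RemoveAtom(dummy)
        clean = rw.GetMol()
        Chem.SanitizeMol(clean)
        # removing an atom shifts indices above it down by one
        if exit_atom > dummy:
            exit_atom -= 1
        return cls(mol=clean, exit_atom=exit_atom, coords=coords)

    @classmethod
    def from_sdf(cls, path: str, exit_atom: int) -> "FragmentSpec":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        mol = next((m for m in supplier if m is not None), None)
        if mol is None:
            raise InvalidMoleculeError(f"no readable molecule in {path}")
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        return cls(mol=mol, exit_atom=exit_atom, coords=coords)

    @property
    def smiles(self) -> str:
        """Canonical SMILES with the attachment marked by a dummy atom."""
        rw = Chem.RWMol(self.mol)
        dummy = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(self.exit_atom, dummy, Chem.BondType.SINGLE)
        out = rw.GetMol()
        Chem.SanitizeMol(out, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_ADJUSTHS)
        return Chem.MolToSmiles(out)

    @property
    def exit_pos(self) -> np.ndarray:
        if self.coords is None:
            raise ValueError("fragment has no 3D coordinates")
        return self.coords[self.exit_atom]

    @property
    def heavy_atom_coords(self) -> np.ndarray:
        if self.coords is None:
            raise ValueError("fragment has no 3D coordinates")
        return self.coords

    def embed(self, seed: int = 7) -> "FragmentSpec":
        """Return a copy with ETKDG-generated 3D coordinates (for fixtures)."""
        mol = Chem.AddHs(Chem.Mol(self.mol))
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise InvalidMoleculeError("3D embedding failed")
        mol = Chem.RemoveHs(mol)
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        return FragmentSpec(mol=self.mol, exit_atom=self.exit_atom, coords=coords)

    def translated(self, offset: np.ndarray) -> "FragmentSpec":
        if self.coords is None:
            raise ValueError("fragment has no 3D coordinates")
        return FragmentSpec(
            mol=self.mol, exit_atom=self.exit_atom, coords=self.coords + np.asarray(offset)
        )
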