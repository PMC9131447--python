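"""Ligand pharmacophore perception and structural-information profiles.

The generative model is conditioned on a structural profile: coarse counts of
hydrogen-bond acceptors, hydrogen-bond donors and aromatic ring systems in
the elaboration, optionally refined with the shortest bond-path atom count
from the elaboration attachment atom to each pharmacophore.

Perception rules (SMARTS, applied consistently by generation conditioning,
quasi-active matching and evaluation metrics):

===========  ==================================================  =============
class        SMARTS                                              rationale
===========  ==================================================  =============
donor        ``[#7;!H0;+0]``, ``[#8;!H0;+0]``                    H on N or O
acceptor     ``[OX2;+0]``, ``[OX1;+0]``                          ether/alcohol,
                                                                 carbonyl O
acceptor     ``[nX2;+0]``                                        pyridine-type
                                                                 aromatic N
acceptor     ``[NX1;+0]``, ``[NX2;+0]``                          nitrile, imine
acceptor     ``[NX3;+0;!$([NX3][CX3]=[OX1]);                     amine, but not
             !$([NX3][SX4](=O)=O)]``                             amide or
                                                                 sulfonamide N
aromatic     fused aromatic ring system (counted once)           ring stacking
===========  ==================================================  =============

Pyrrole-type aromatic nitrogens are excluded from acceptors (they match
neither ``[nX2]`` nor an aliphatic-N pattern); amide and sulfonamide nitrogens
are excluded because their lone pair is delocalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .errors import InvalidElaborationError, InvalidMoleculeError

DONOR_SMARTS = ("[#7;!H0;+0]", "[#8;!H0;+0]")
ACCEPTOR_SMARTS = (
    "[OX2;+0]",
    "[OX1;+0]",
    "[nX2;+0]",
    "[NX1;+0]",
    "[NX2;+0]",
    "[NX3;+0;!$([NX3][CX3]=[OX1]);!$([NX3][SX4](=O)=O)]",
)

_DONOR_PATTERNS = [Chem.MolFromSmarts(s) for s in DONOR_SMARTS]
_ACCEPTOR_PATTERNS = [Chem.MolFromSmarts(s) for s in ACCEPTOR_SMARTS]


@dataclass
class LigandPharmacophore:
    """A typed pharmacophoric feature on a ligand.

    ``atom_indices`` holds the key atom (donor/acceptor) or the aromatic ring
    system members; ``position`` is set when 3D coordinates are available
    (ring centroid for aromatic features).
    """

    ptype: str  # donor | acceptor | aromatic
    atom_indices: tuple[int, ...]
    position: np.ndarray | None = None


@dataclass
class StructuralProfile:
    """Conditioning vector for the generative model.

    Coarse form: pharmacophore counts over the elaboration. Fine form adds,
    per pharmacophore, the shortest bond-path atom count from the elaboration
    attachment atom (inclusive of both endpoints).
    """

    n_acceptors: int = 0
    n_donors: int = 0
    n_aromatic: int = 0
    path_distances: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if min(self.n_acceptors, self.n_donors, self.n_aromatic) < 0:
            raise ValueError("profile counts must be non-negative")
        if self.path_distances is not None:
            if any(d < 1 for _, d in self.path_distances):
                raise ValueError("path distances must be >= 1")

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_acceptors, self.n_donors, self.n_aromatic)

    @property
    def is_fine(self) -> bool:
        return self.path_distances is not None


def _aromatic_systems(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Fused aromatic ring systems, each returned once as a sorted atom tuple."""
    ri = mol.GetRingInfo()
    aromatic_rings = [
        tuple(ring)
        for ring in ri.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    ]
    systems: list[set[int]] = []
    for ring in aromatic_rings:
        ring_set = set(ring)
        merged = [s for s in systems if s & ring_set]
        for s in merged:
            ring_set |= s
            systems.remove(s)
        systems.append(ring_set)
    return [tuple(sorted(s)) for s in sorted(systems, key=min)]


def _match_atoms(mol: Chem.Mol, patterns: Iterable[Chem.Mol]) -> set[int]:
    hits: set[int] = set()
    for patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            hits.add(match[0])
    return hits


def perceive(mol: Chem.Mol | str) -> list[LigandPharmacophore]:
    """Perceive donor, acceptor and aromatic pharmacophores of a molecule.

    Positions are attached when the molecule carries a 3D conformer
    (aromatic features use the ring-system centroid).
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise InvalidMoleculeError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    conf = mol.GetConformer() if mol.GetNumConformers() else None

    def pos_of(indices: tuple[int, ...]) -> np.ndarray | None:
        if conf is None:
            return None
        pts = np.array([list(conf.GetAtomPosition(i)) for i in indices])
        return pts.mean(axis=0)

    feats: list[LigandPharmacophore] = []
    for idx in sorted(_match_atoms(mol, _DONOR_PATTERNS)):
        feats.append(LigandPharmacophore("donor", (idx,), pos_of((idx,))))
    for idx in sorted(_match_atoms(mol, _ACCEPTOR_PATTERNS)):
        feats.append(LigandPharmacophore("acceptor", (idx,), pos_of((idx,))))
    for system in _aromatic_systems(mol):
        feats.append(LigandPharmacophore("aromatic", system, pos_of(system)))
    return feats


def _elaboration_features(
    mol: Chem.Mol, elab_atoms: Sequence[int] | None
) -> list[LigandPharmacophore]:
    """Pharmacophores restricted to the elaboration subgraph.

    Donor/acceptor features count when their key atom is an elaboration atom;
    aromatic systems when the whole system lies in the elaboration (acyclic
    cuts never split a ring between fragment and elaboration).
    """
    feats = perceive(mol)
    if elab_atoms is None:
        return feats
    elab = set(elab_atoms)
    kept = []
    for f in feats:
        if f.ptype == "aromatic":
            if set(f.atom_indices) <= elab:
                kept.append(f)
        elif f.atom_indices[0] in elab:
            kept.append(f)
    return kept


def coarse_profile(
    mol: Chem.Mol | str, elab_atoms: Sequence[int] | None = None
) -> StructuralProfile:
    """Coarse profile: (acceptors, donors, aromatic systems) of an elaboration.

    ``mol`` may be a full molecule with ``elab_atoms`` naming the elaboration
    subgraph, or a standalone elaboration (SMILES may carry an attachment
    dummy, which is ignored by perception).
    """
    if isinstance(mol, str):
        mol = _parse_elaboration(mol)
    feats = _elaboration_features(mol, elab_atoms)
    return StructuralProfile(
        n_acceptors=sum(f.ptype == "acceptor" for f in feats),
        n_donors=sum(f.ptype == "donor" for f in feats),
        n_aromatic=sum(f.ptype == "aromatic" for f in feats),
    )


def _parse_elaboration(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles!r}")
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if dummies:
        rw = Chem.RWMol(mol)
        for idx in sorted(dummies, reverse=True):
            rw.RemoveAtom(idx)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    return mol


def fine_profile(
    mol: Chem.Mol | str,
    elab_atoms: Sequence[int],
    attach_atom: int,
) -> StructuralProfile:
    """Fine profile: coarse counts plus per-pharmacophore path distances.

    ``attach_atom`` is the first elaboration atom (the one bonded to the
    fragment exit vector). The path distance to a pharmacophore is the number
    of atoms on the shortest bond path from the attachment atom to the
    pharmacophore atom, both endpoints included; aromatic features use their
    nearest ring atom.
    """
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise InvalidMoleculeError("unparseable SMILES")
    elab = set(elab_atoms)
    if attach_atom not in elab:
        raise InvalidElaborationError("attachment atom must be an elaboration atom")
    # BFS over the elaboration subgraph only
    dist: dict[int, int] = {attach_atom: 0}
    queue = [attach_atom]
    while queue:
        cur = queue.pop(0)
        for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
            j = nb.GetIdx()
            if j in elab and j not in dist:
                dist[j] = dist[cur] + 1
                queue.append(j)
    if set(dist) != elab:
        raise InvalidElaborationError("elaboration subgraph is disconnected")

    profile = coarse_profile(mol, elab_atoms)
    feats = _elaboration_features(mol, elab_atoms)
    paths: list[tuple[str, int]] = []
    for f in feats:
        d = min(dist[i] for i in f.atom_indices) + 1  # atom count, inclusive
        paths.append((f.ptype, d))
    profile.path_distances = sorted(paths)
    return profile


def make_lattice(
    exit_pos: Sequence[float],
    path: str | Path,
    extent: float = 5.0,
    spacing: float = 1.0,
) -> Path:
    """Write a cubic lattice of selectable points around the exit vector.

    Each lattice point is a single-carbon SDF record; to declare a
    pharmacophoric point the user keeps the record and changes its element to
    O (acceptor) or N (donor) — or sets a PTYPE field — then reads the file
    back with :func:`strife.hotspot_io.read_points_sdf`. Carbon records are
    ignored on read.
    """
    if extent <= spacing:
        raise ValueError("extent must exceed spacing")
    exit_pos = np.asarray(exit_pos, dtype=float)
    half = int(extent // spacing)
    offsets = spacing * np.arange(-half, half + 1)
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for dx in offsets:
            for dy in offsets:
                for dz in offsets:
                    mol = Chem.RWMol()
                    idx = mol.AddAtom(Chem.Atom("C"))
                    conf = Chem.Conformer(1)
                    conf.SetAtomPosition(
                        idx, Point3D(*(exit_pos + np.array([dx, dy, dz])))
                    )
                    mol.AddConformer(conf)
                    writer.write(mol.GetMol())
    finally:
        writer.close()
    return path
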