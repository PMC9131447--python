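"""Incremental, valence-safe construction of fragment elaborations.

The generative model grows an elaboration one node at a time from the
fragment exit vector, breadth-first: the current focus atom repeatedly either
receives a new child node or is closed, after which the next frontier atom
becomes the focus. Six-membered aromatic rings are grown as a forced run of
six ring-atom choices (carbon opener, then five C/N picks) and closed
automatically, which keeps every intermediate chemically meaningful.

Chemical guard rails enforced here (and mirrored when linearizing training
molecules, so the model only ever sees representable sequences):

* element vocabulary C, N, O, F, S plus carbonyl O and aromatic ring atoms;
* heteroatoms bond only to carbon (no O-O, N-N, N-O, ... single bonds);
* carbonyl oxygens attach by a double bond to an aliphatic carbon;
* aromatic rings are six-membered, open on a carbon, contain at most two
  nitrogens and no adjacent nitrogens;
* valence bookkeeping caps children per atom; the exit vector accepts exactly
  one child (an elaboration has a single attachment bond).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from rdkit import Chem

#: chain-context actions (each adds one heavy atom, or opens a ring)
CHAIN_LABELS = ("C", "N", "O", "F", "S", "O=", "c1")
#: ring-context actions
RING_LABELS = ("c", "n")
ALL_LABELS = CHAIN_LABELS + RING_LABELS
STOP = "STOP"

VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2}
HETERO = {"N", "O", "F", "S"}

# kekulized bond orders around the ring: (r0-r1), (r1-r2), ..., (r4-r5), (r5-r0)
_RING_BOND_ORDERS = (
    Chem.BondType.DOUBLE,
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.SINGLE,
)


@dataclass
class _RingState:
    atoms: list[int] = field(default_factory=list)
    n_count: int = 0


class ElaborationBuilder:
    """Grows an elaboration on a copy of the fragment molecule."""

    def __init__(self, frag_mol: Chem.Mol, exit_atom: int, max_len: int):
        if max_len < 1:
            raise ValueError("max_len must be >= 1")
        self.rw = Chem.RWMol(frag_mol)
        self.exit_atom = exit_atom
        self.max_len = max_len
        self.budget = max_len
        self.elab_atoms: list[int] = []
        self.attach_atom: int | None = None
        self.queue: deque[int] = deque()
        self.focus: int | None = exit_atom
        self.depth: dict[int, int] = {exit_atom: 0}
        self.ring: _RingState | None = None
        self.finished = False
        self.t = 0
        # remaining bonding capacity per atom we manage
        exit_a = self.rw.GetAtomWithIdx(exit_atom)
        self._cap: dict[int, int] = {exit_atom: min(1, exit_a.GetTotalNumHs())}
        self._arom: set[int] = set()  # grammar-grown aromatic ring atoms

    # -- state queries ------------------------------------------------------

    def capacity(self, idx: int) -> int:
        return self._cap.get(idx, 0)

    def focus_element(self) -> str:
        assert self.focus is not None
        return self.rw.GetAtomWithIdx(self.focus).GetSymbol()

    def focus_is_aromatic(self) -> bool:
        assert self.focus is not None
        return (
            self.rw.GetAtomWithIdx(self.focus).GetIsAromatic()
            or self.focus in self._arom
        )

    def in_ring_mode(self) -> bool:
        return self.ring is not None

    def chain_action_allowed(self, label: str) -> bool:
        """Structural feasibility of a chain action at the current focus."""
        if self.finished or self.focus is None or self.in_ring_mode():
            return False
        if self.budget < 1 or self.capacity(self.focus) < 1:
            return False
        elem = self.focus_element()
        if label == "O=":
            return (
                elem == "C"
                and not self.focus_is_aromatic()
                and self.capacity(self.focus) >= 2
            )
        if label == "c1":
            return self.budget >= 6
        if label in HETERO:
            # heteroatoms bond only to carbon
            return elem == "C"
        return label == "C"

    def any_chain_action_allowed(self) -> bool:
        return any(self.chain_action_allowed(lb) for lb in CHAIN_LABELS)

    def ring_action_allowed(self, label: str) -> bool:
        if self.ring is None:
            return False
        if label == "c":
            return True
        if label != "n":
            return False
        if self.ring.n_count >= 2:
            return False
        prev = self.rw.GetAtomWithIdx(self.ring.atoms[-1]).GetSymbol()
        if prev == "N":
            return False
        # last position is adjacent to the (carbon) opener, always fine
        return True

    # -- state transitions --------------------------------------------------

    def _new_atom(self, element: str) -> int:
        idx = self.rw.AddAtom(Chem.Atom(element))
        self.elab_atoms.append(idx)
        if self.attach_atom is None:
            self.attach_atom = idx
        self.budget -= 1
        self.t += 1
        return idx

    def add_chain_atom(self, label: str) -> int:
        if not self.chain_action_allowed(label):
            raise ValueError(f"chain action {label!r} not allowed here")
        focus = self.focus
        assert focus is not None
        if label == "c1":
            idx = self._new_atom("C")
            self.rw.AddBond(focus, idx, Chem.BondType.SINGLE)
            self._cap[focus] -= 1
            self._cap[idx] = 0  # opener is saturated once the ring closes
            self._arom.add(idx)
            self.depth[idx] = self.depth[focus] + 1
            self.ring = _RingState(atoms=[idx])
            return idx
        if label == "O=":
            idx = self._new_atom("O")
            self.rw.AddBond(focus, idx, Chem.BondType.DOUBLE)
            self._cap[focus] -= 2
            self._cap[idx] = 0
            self.depth[idx] = self.depth[focus] + 1
            return idx
        idx = self._new_atom(label)
        self.rw.AddBond(focus, idx, Chem.BondType.SINGLE)
        self._cap[focus] -= 1
        self._cap[idx] = VALENCE[label] - 1
        self.depth[idx] = self.depth[focus] + 1
        if self._cap[idx] > 0:
            self.queue.append(idx)
        return idx

    def add_ring_atom(self, label: str) -> int:
        if not self.ring_action_allowed(label):
            raise ValueError(f"ring action {label!r} not allowed here")
        assert self.ring is not None
        element = "C" if label == "c" else "N"
        idx = self._new_atom(element)
        prev = self.ring.atoms[-1]
        order = _RING_BOND_ORDERS[len(self.ring.atoms) - 1]
        self.rw.AddBond(prev, idx, order)
        pos = len(self.ring.atoms)
        opener = self.ring.atoms[0]
        self.depth[idx] = self.depth[opener] + min(pos, 6 - pos)
        self._arom.add(idx)
        self.ring.atoms.append(idx)
        if label == "n":
            self.ring.n_count += 1
            self._cap[idx] = 0
        else:
            self._cap[idx] = 1
        if len(self.ring.atoms) == 6:
            self._close_ring()
        return idx

    def _close_ring(self) -> None:
        assert self.ring is not None and len(self.ring.atoms) == 6
        self.rw.AddBond(self.ring.atoms[5], self.ring.atoms[0], _RING_BOND_ORDERS[5])
        for idx in self.ring.atoms[1:]:
            if self._cap.get(idx, 0) > 0:
                self.queue.append(idx)
        self.ring = None

    def stop_focus(self) -> None:
        """Close the current focus and advance to the next frontier atom."""
        if self.in_ring_mode():
            raise ValueError("cannot stop mid-ring")
        if self.queue:
            self.focus = self.queue.popleft()
        else:
            self.focus = None
            self.finished = True

    def auto_advance(self) -> None:
        """Skip focuses that have no possible action; finish when exhausted."""
        if self.in_ring_mode():
            return
        if self.budget < 1:
            self.focus = None
            self.queue.clear()
            self.finished = True
            return
        while not self.finished and not self.any_chain_action_allowed():
            self.stop_focus()

    # -- outputs ------------------------------------------------------------

    def partial_mol(self) -> Chem.Mol:
        """Sanitized copy of the current (possibly mid-ring) structure."""
        mol = Chem.Mol(self.rw)
        Chem.SanitizeMol(mol)
        return mol

    def raw_graph(self) -> Chem.Mol:
        """Unsanitized view for encoder feature extraction."""
        return self.rw

    def result(self) -> tuple[str, Chem.Mol, list[int]] | None:
        """Final molecule as (canonical SMILES, mol, elaboration atom indices).

        Returns None if the build is unusable (ring left open, no atom added,
        or sanitization failure).
        """
        if self.in_ring_mode() or not self.elab_atoms:
            return None
        mol = Chem.Mol(self.rw)
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return None
        return Chem.MolToSmiles(mol), mol, list(self.elab_atoms)


# ---------------------------------------------------------------------------
# Linearization of existing elaborations into builder action sequences
# ---------------------------------------------------------------------------


def linearize_elaboration(
    mol: Chem.Mol, elab_atoms: list[int], exit_atom: int
) -> list[tuple[str, str]] | None:
    """Express an existing elaboration as a builder action sequence.

    Returns a list of (kind, label) with kind in {"add", "ring", "stop"}, or
    None when the elaboration is not representable by the growth grammar
    (non-aromatic or fused rings, non-carbonyl multiple bonds, exotic
    elements, heteroatom-heteroatom bonds, charges).
    """
    elab = set(elab_atoms)
    ri = mol.GetRingInfo()
    rings = [tuple(r) for r in ri.AtomRings() if set(r) & elab]
    ring_of: dict[int, tuple[int, ...]] = {}
    for r in rings:
        if not set(r) <= elab:
            return None  # cut through a ring: not producible by acyclic cuts anyway
        if len(r) != 6 or not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r):
            return None
        n_atoms = [i for i in r if mol.GetAtomWithIdx(i).GetSymbol() == "N"]
        if len(n_atoms) > 2:
            return None
        for i in r:
            if i in ring_of:
                return None  # fused systems not representable
            sym = mol.GetAtomWithIdx(i).GetSymbol()
            if sym not in ("C", "N"):
                return None
            ring_of[i] = r
    for a, b in ((i, j) for i in elab for j in elab if i < j):
        bond = mol.GetBondBetweenAtoms(a, b)
        if bond is None:
            continue
        sa, sb = (mol.GetAtomWithIdx(x).GetSymbol() for x in (a, b))
        if bond.GetBondType() == Chem.BondType.AROMATIC or (a in ring_of and b in ring_of):
            if sa == "N" and sb == "N":
                return None  # adjacent aromatic nitrogens
            continue
        if bond.GetBondType() == Chem.BondType.DOUBLE:
            if {sa, sb} != {"C", "O"}:
                return None
            o = a if sa == "O" else b
            if mol.GetAtomWithIdx(o).GetDegree() != 1:
                return None
            continue
        if bond.GetBondType() != Chem.BondType.SINGLE:
            return None
        if sa in HETERO and sb in HETERO:
            return None
    for i in elab:
        atom = mol.GetAtomWithIdx(i)
        if atom.GetSymbol() not in VALENCE or atom.GetFormalCharge() != 0:
            return None
        if atom.GetSymbol() in HETERO and i in ring_of and atom.GetSymbol() != "N":
            return None

    # attachment: exactly one bond between fragment side and elaboration
    attach_candidates = [
        nb.GetIdx()
        for nb in mol.GetAtomWithIdx(exit_atom).GetNeighbors()
        if nb.GetIdx() in elab
    ]
    if len(attach_candidates) != 1:
        return None

    # drive a builder in lockstep with a BFS over the real elaboration, so the
    # recorded decision sequence matches generation-time semantics exactly
    frag_mol, frag_exit = _fragment_side(mol, elab, exit_atom)
    if frag_mol is None:
        return None
    builder = ElaborationBuilder(frag_mol, frag_exit, max_len=len(elab))
    to_orig: dict[int, int] = {frag_exit: exit_atom}
    visited: set[int] = set()
    actions: list[tuple[str, str]] = []

    def unvisited_children(orig_focus: int) -> list[int]:
        return sorted(
            nb.GetIdx()
            for nb in mol.GetAtomWithIdx(orig_focus).GetNeighbors()
            if nb.GetIdx() in elab and nb.GetIdx() not in visited
        )

    while True:
        builder.auto_advance()
        if builder.finished:
            break
        focus_b = builder.focus
        assert focus_b is not None
        orig_focus = to_orig.get(focus_b)
        if orig_focus is None:
            return None  # builder frontier diverged from the real structure
        children = unvisited_children(orig_focus)
        if not children:
            actions.append(("stop", ""))
            builder.stop_focus()
            continue
        child = children[0]
        catom = mol.GetAtomWithIdx(child)
        bond = mol.GetBondBetweenAtoms(orig_focus, child)
        if child in ring_of:
            if catom.GetSymbol() != "C":
                return None  # ring opener must be carbon
            if not builder.chain_action_allowed("c1"):
                return None
            ring = ring_of[child]
            nbs = sorted(
                x for x in ring if mol.GetBondBetweenAtoms(child, x) is not None
            )
            order = _walk_ring(mol, ring, child, nbs[0])
            idx_b = builder.add_chain_atom("c1")
            actions.append(("add", "c1"))
            to_orig[idx_b] = child
            visited.add(child)
            for orig_idx in order[1:]:
                sym = mol.GetAtomWithIdx(orig_idx).GetSymbol()
                label = "c" if sym == "C" else "n"
                if not builder.ring_action_allowed(label):
                    return None
                idx_b = builder.add_ring_atom(label)
                actions.append(("ring", label))
                to_orig[idx_b] = orig_idx
                visited.add(orig_idx)
        elif bond.GetBondType() == Chem.BondType.DOUBLE:
            if not builder.chain_action_allowed("O="):
                return None
            builder.add_chain_atom("O=")
            actions.append(("add", "O="))
            visited.add(child)
        else:
            label = catom.GetSymbol()
            if not builder.chain_action_allowed(label):
                return None
            idx_b = builder.add_chain_atom(label)
            actions.append(("add", label))
            to_orig[idx_b] = child
            visited.add(child)

    if visited != elab:
        return None
    out = builder.result()
    if out is None or out[0] != Chem.MolToSmiles(mol):
        return None
    return actions


def _walk_ring(
    mol: Chem.Mol, ring: tuple[int, ...], start: int, second: int
) -> list[int]:
    order = [start, second]
    while len(order) < len(ring):
        cur = order[-1]
        nxt = [
            x
            for x in ring
            if x not in order and mol.GetBondBetweenAtoms(cur, x) is not None
        ]
        order.append(nxt[0])
    return order


def _fragment_side(
    mol: Chem.Mol, elab: set[int], exit_atom: int
) -> tuple[Chem.Mol | None, int]:
    """Extract the fragment-side submolecule and the exit atom's new index."""
    keep = [i for i in range(mol.GetNumAtoms()) if i not in elab]
    amap: dict[int, int] = {}
    rw = Chem.RWMol()
    for i in keep:
        amap[i] = rw.AddAtom(Chem.Atom(mol.GetAtomWithIdx(i).GetAtomicNum()))
        rw.GetAtomWithIdx(amap[i]).SetIsAromatic(mol.GetAtomWithIdx(i).GetIsAromatic())
        rw.GetAtomWithIdx(amap[i]).SetFormalCharge(mol.GetAtomWithIdx(i).GetFormalCharge())
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in amap and b in amap:
            rw.AddBond(amap[a], amap[b], bond.GetBondType())
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None, -1
    return out, amap[exit_atom]
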