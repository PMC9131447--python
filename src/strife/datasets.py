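"""Synthetic desk-scale training data.

Generates drug-like small molecules with a seeded random policy over the same
growth grammar the generative model uses (chains of C/N/O/S/F, carbonyls,
six-membered aromatic rings with up to two non-adjacent nitrogens). Cutting
these molecules with :func:`strife.elaborator.enumerate_pairs` yields a
training set whose elaborations are fully representable by the grammar, so a
few hundred molecules support end-to-end training without any download.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from ._build import CHAIN_LABELS, RING_LABELS, ElaborationBuilder
from .fragment import FragmentSpec

_SEED_FRAGMENTS = ("[*]C", "[*]CC", "[*]c1ccccc1", "[*]C(C)C", "[*]CCN", "[*]CO")

_CHAIN_WEIGHTS = {
    "C": 0.42,
    "N": 0.10,
    "O": 0.13,
    "F": 0.03,
    "S": 0.03,
    "O=": 0.11,
    "c1": 0.18,
}
_RING_WEIGHTS = {"c": 0.8, "n": 0.2}


def _weighted_pick(options: list[str], weights: dict[str, float], rng: np.random.Generator) -> str:
    w = np.array([weights[o] for o in options])
    w = w / w.sum()
    return options[int(rng.choice(len(options), p=w))]


def _grow_random(seed_smiles: str, n_atoms: int, rng: np.random.Generator) -> str | None:
    frag = FragmentSpec.from_smiles(seed_smiles)
    builder = ElaborationBuilder(frag.mol, frag.exit_atom, max_len=n_atoms)
    for _ in range(100):
        if builder.in_ring_mode():
            options = [lb for lb in RING_LABELS if builder.ring_action_allowed(lb)]
            builder.add_ring_atom(_weighted_pick(options, _RING_WEIGHTS, rng))
            continue
        builder.auto_advance()
        if builder.finished:
            break
        options = [lb for lb in CHAIN_LABELS if builder.chain_action_allowed(lb)]
        if not options:
            builder.stop_focus()
            continue
        # stop a focus with increasing probability as the molecule grows
        p_stop = 0.12 + 0.5 * (1 - builder.budget / builder.max_len) * 0.3
        if builder.t > 0 and rng.random() < p_stop:
            builder.stop_focus()
            continue
        builder.add_chain_atom(_weighted_pick(options, _CHAIN_WEIGHTS, rng))
    result = builder.result()
    if result is None:
        return None
    return result[0]


def synthetic_training_smiles(seed: int, n: int = 150) -> list[str]:
    """Deterministically generate ``n`` distinct drug-like training molecules."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        seed_smiles = _SEED_FRAGMENTS[int(rng.integers(len(_SEED_FRAGMENTS)))]
        n_atoms = int(rng.integers(5, 14))
        smi = _grow_random(seed_smiles, n_atoms, rng)
        if smi is None:
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumHeavyAtoms() < 5:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(canonical)
    return out
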