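"""Profile-conditioned autoregressive graph generator (NumPy).

Molecules grow node by node from the fragment exit vector (see
:mod:`strife._build`). At each step the model samples K expansion-node
latents from an h-dimensional standard normal; a label classifier assigns
each latent an atom type given the conditioning profile D, the graph summary
H^t and context; a decision head scores attaching each labelled expansion
node against stopping, from features (s_v, s_u, d_{u,v}, H^t, D, t) where
s = [latent, label]. After an addition, node encodings are refreshed by a
fixed randomized message-passing encoder over the updated graph.

Only the two policy heads are trained (softmax cross-entropy, minibatch SGD
with momentum, hand-coded gradients); the encoder weights are drawn once at
model creation and frozen, which is what makes desk-scale CPU training
practical. The expansion latents are the stochastic source of sample
diversity: the label classifier learns the atom-type distribution conditioned
on (D, H, progress), marginalized over the latent.

At sampling time, structurally infeasible actions (valence, ring state,
budget) are masked, as is standard for constrained graph generation; by
default profile-infeasible actions are masked as well, so that requested
pharmacophore counts are neither overshot nor abandoned while budget remains.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from ._build import (
    ALL_LABELS,
    CHAIN_LABELS,
    RING_LABELS,
    ElaborationBuilder,
    linearize_elaboration,
)
from .errors import TooFewPairsError, UntrainedModelError
from .pharmacophores import StructuralProfile, coarse_profile, fine_profile

logger = logging.getLogger(__name__)

ELEMENTS = ("C", "N", "O", "F", "S", "Cl", "Br", "X")
_N_LABELS = len(ALL_LABELS)  # 9
_N_CHAIN = len(CHAIN_LABELS)
_D_DIM = 12


def _elem_index(symbol: str) -> int:
    try:
        return ELEMENTS.index(symbol)
    except ValueError:
        return len(ELEMENTS) - 1


@dataclass
class ModelConfig:
    h: int = 32
    K: int = 12
    epochs: int = 25
    lr: float = 0.1
    momentum: float = 0.9
    batch_size: int = 256
    seed: int = 0
    msg_rounds: int = 2


def d_features(
    target: StructuralProfile,
    cur_counts: tuple[int, int, int],
    budget_left: int,
    max_len: int,
    t: int,
) -> np.ndarray:
    """Conditioning feature vector: requested counts, remaining deficits,
    fine-grained path requests, and progress scalars."""
    ta, td, tr = target.counts
    ca, cd, cr = cur_counts
    fine = target.path_distances is not None
    pa = pd_ = pr = 0.0
    if fine:
        for ptype, dist in target.path_distances:  # type: ignore[union-attr]
            if ptype == "acceptor" and (pa == 0 or dist < pa):
                pa = dist
            elif ptype == "donor" and (pd_ == 0 or dist < pd_):
                pd_ = dist
            elif ptype == "aromatic" and (pr == 0 or dist < pr):
                pr = dist
    return np.array(
        [
            ta,
            td,
            tr,
            ta - ca,
            td - cd,
            tr - cr,
            float(fine),
            pa / 5.0,
            pd_ / 5.0,
            pr / 5.0,
            budget_left / max(max_len, 1),
            min(t, 20) / 10.0,
        ],
        dtype=float,
    )


class _Encoder:
    """Fixed randomized message-passing encoder producing node latents."""

    def __init__(self, h: int, rng: np.random.Generator):
        self.h = h
        self.E = rng.normal(0, 1.0, (len(ELEMENTS), h))
        self.E_arom = rng.normal(0, 1.0, h)
        self.E_elab = rng.normal(0, 1.0, h)
        self.W1 = rng.normal(0, 1.0 / np.sqrt(h), (h, h))
        self.W2 = rng.normal(0, 1.0 / np.sqrt(h), (h, h))
        self.rounds = 2

    def encode(
        self, mol: Chem.Mol, elab_atoms: set[int], extra_arom: set[int]
    ) -> tuple[np.ndarray, np.ndarray]:
        n = mol.GetNumAtoms()
        X = np.empty((n, self.h))
        for i in range(n):
            atom = mol.GetAtomWithIdx(i)
            X[i] = self.E[_elem_index(atom.GetSymbol())]
            if atom.GetIsAromatic() or i in extra_arom:
                X[i] = X[i] + self.E_arom
            if i in elab_atoms:
                X[i] = X[i] + self.E_elab
        nbrs: list[list[int]] = [[] for _ in range(n)]
        for bond in mol.GetBonds():
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            nbrs[a].append(b)
            nbrs[b].append(a)
        Z = np.tanh(X)
        for _ in range(self.rounds):
            M = np.zeros_like(Z)
            for i, ns in enumerate(nbrs):
                if ns:
                    M[i] = Z[ns].mean(axis=0)
            Z = np.tanh(Z @ self.W1 + M @ self.W2)
        return Z, Z.mean(axis=0)

    def state(self) -> dict[str, np.ndarray]:
        return {
            "E": self.E,
            "E_arom": self.E_arom,
            "E_elab": self.E_elab,
            "W1": self.W1,
            "W2": self.W2,
        }

    @classmethod
    def from_state(cls, h: int, state: dict[str, np.ndarray]) -> "_Encoder":
        enc = cls.__new__(cls)
        enc.h = h
        enc.E = state["E"]
        enc.E_arom = state["E_arom"]
        enc.E_elab = state["E_elab"]
        enc.W1 = state["W1"]
        enc.W2 = state["W2"]
        enc.rounds = 2
        return enc


@dataclass
class _StepRecord:
    """One teacher-forced decision with precomputed static features."""

    kind: str  # add | ring | stop
    label_idx: int  # index into ALL_LABELS (-1 for stop)
    z_focus: np.ndarray
    H: np.ndarray
    focus_elem: int
    depth: int
    t: int
    d_coarse: np.ndarray
    d_fine: np.ndarray


def _softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    m = logits.max(axis=axis, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=axis, keepdims=True)


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Categorical sample per row of a (B, C) probability matrix."""
    probs = np.atleast_2d(probs)
    cum = probs.cumsum(axis=1)
    cum[:, -1] = 1.0
    u = rng.random((probs.shape[0], 1))
    return (cum > u).argmax(axis=1)


class ElaborationModel:
    """Trained generator: fixed encoder plus two learned policy heads."""

    FORMAT_VERSION = 1

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = _Encoder(config.h, rng)
        h = config.h
        self._d_lab = h + _D_DIM + h + 2  # [z_i, D, H, ring_flag, bias]
        self._d_bond = h + len(ELEMENTS) + h + _N_LABELS + 1 + _D_DIM + h + 2
        # [z_v, elem_onehot, z_u, label_onehot, depth, D, H, t, bias]
        self.W_lab = 0.01 * rng.normal(size=(self._d_lab, _N_LABELS))
        self.w_bond = 0.01 * rng.normal(size=self._d_bond)
        self.losses_: list[float] = []
        self.trained = False

    # -- feature assembly ----------------------------------------------------

    def _label_features(
        self, z: np.ndarray, d_feat: np.ndarray, H: np.ndarray, ring_flag: float
    ) -> np.ndarray:
        """z may be (h,) or (B, h); d_feat/H broadcast accordingly."""
        z = np.atleast_2d(z)
        B = z.shape[0]
        d2 = np.broadcast_to(d_feat, (B, _D_DIM))
        H2 = np.broadcast_to(H, (B, self.config.h))
        rf = np.full((B, 1), ring_flag)
        ones = np.ones((B, 1))
        return np.concatenate([z, d2, H2, rf, ones], axis=1)

    def _bond_features(
        self,
        z_v: np.ndarray,
        elem_idx: int,
        z_u: np.ndarray,
        label_idx: np.ndarray,
        depth: int,
        d_feat: np.ndarray,
        H: np.ndarray,
        t: int,
    ) -> np.ndarray:
        """Candidate features, (K+1, d_bond); last row is the stop option."""
        K = z_u.shape[0]
        rows = np.zeros((K + 1, self._d_bond))
        h = self.config.h
        elem_oh = np.zeros(len(ELEMENTS))
        elem_oh[elem_idx] = 1.0
        base = np.concatenate([z_v, elem_oh])
        off = h + len(ELEMENTS)
        rows[:, :off] = base
        for k in range(K):
            lab_oh = np.zeros(_N_LABELS)
            lab_oh[label_idx[k]] = 1.0
            rows[k, off : off + h] = z_u[k]
            rows[k, off + h : off + h + _N_LABELS] = lab_oh
        p = off + h + _N_LABELS
        rows[:, p] = depth / 5.0
        rows[:, p + 1 : p + 1 + _D_DIM] = d_feat
        rows[:, p + 1 + _D_DIM : p + 1 + _D_DIM + h] = H
        rows[:, -2] = min(t, 20) / 10.0
        rows[:, -1] = 1.0
        return rows

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Serialize as an ``.npz`` weights file with a JSON config sidecar."""
        path = Path(path)
        arrays = {f"enc_{k}": v for k, v in self.encoder.state().items()}
        arrays["W_lab"] = self.W_lab
        arrays["w_bond"] = self.w_bond
        arrays["losses"] = np.array(self.losses_)
        np.savez(path, **arrays)
        npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        sidecar = {
            "format_version": self.FORMAT_VERSION,
            "trained": self.trained,
            "config": asdict(self.config),
        }
        npz_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return npz_path

    @classmethod
    def load(cls, path: str | Path) -> "ElaborationModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        config = ModelConfig(**sidecar["config"])
        model = cls(config)
        data = np.load(path)
        model.encoder = _Encoder.from_state(
            config.h, {k[4:]: data[k] for k in data.files if k.startswith("enc_")}
        )
        model.W_lab = data["W_lab"]
        model.w_bond = data["w_bond"]
        model.losses_ = list(data["losses"])
        model.trained = bool(sidecar["trained"])
        return model

    # -- training ------------------------------------------------------------

    def _collect_steps(self, pairs) -> list[_StepRecord]:
        records: list[_StepRecord] = []
        skipped = 0
        for pair in pairs:
            actions = linearize_elaboration(pair.mol, list(pair.elab_atoms), pair.exit_atom)
            if actions is None:
                skipped += 1
                continue
            target_c = coarse_profile(pair.mol, pair.elab_atoms)
            target_f = fine_profile(pair.mol, list(pair.elab_atoms), pair.attach_atom)
            frag = pair.fragment
            builder = ElaborationBuilder(frag.mol, frag.exit_atom, max_len=len(pair.elab_atoms))
            for kind, label in actions:
                builder.auto_advance()
                if builder.finished:
                    break
                focus = builder.focus
                assert focus is not None
                Z, H = self.encoder.encode(
                    builder.raw_graph(), set(builder.elab_atoms), builder._arom
                )
                cur = coarse_profile(builder.partial_mol(), builder.elab_atoms).counts
                rec_common = dict(
                    z_focus=Z[focus].copy(),
                    H=H.copy(),
                    focus_elem=_elem_index(builder.focus_element()),
                    depth=builder.depth.get(focus, 0),
                    t=builder.t,
                    d_coarse=d_features(target_c, cur, builder.budget, builder.max_len, builder.t),
                    d_fine=d_features(target_f, cur, builder.budget, builder.max_len, builder.t),
                )
                if kind == "stop":
                    records.append(_StepRecord(kind="stop", label_idx=-1, **rec_common))
                    builder.stop_focus()
                elif kind == "ring":
                    records.append(
                        _StepRecord(kind="ring", label_idx=ALL_LABELS.index(label), **rec_common)
                    )
                    builder.add_ring_atom(label)
                else:
                    records.append(
                        _StepRecord(kind="add", label_idx=ALL_LABELS.index(label), **rec_common)
                    )
                    builder.add_chain_atom(label)
        if skipped:
            logger.info("skipped %d pairs not representable by the growth grammar", skipped)
        return records

    def fit(self, pairs, min_pairs: int = 100) -> "ElaborationModel":
        if len(pairs) < min_pairs:
            raise TooFewPairsError(
                f"need at least {min_pairs} training pairs, got {len(pairs)}"
            )
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        steps = self._collect_steps(pairs)
        if not steps:
            raise TooFewPairsError("no training pair is representable by the grammar")
        h, K = cfg.h, cfg.K
        vel_lab = np.zeros_like(self.W_lab)
        vel_bond = np.zeros_like(self.w_bond)
        chain_mask = np.array([lb in CHAIN_LABELS for lb in ALL_LABELS])
        ring_mask = np.array([lb in RING_LABELS for lb in ALL_LABELS])
        self.losses_ = []
        n = len(steps)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            total_loss, total_n = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                batch = [steps[i] for i in order[start : start + cfg.batch_size]]
                loss, g_lab, g_bond = self._batch_grads(batch, rng, chain_mask, ring_mask)
                vel_lab = cfg.momentum * vel_lab - cfg.lr * g_lab
                vel_bond = cfg.momentum * vel_bond - cfg.lr * g_bond
                self.W_lab += vel_lab
                self.w_bond += vel_bond
                total_loss += loss * len(batch)
                total_n += len(batch)
            self.losses_.append(total_loss / total_n)
        self.trained = True
        return self

    def _batch_grads(self, batch, rng, chain_mask, ring_mask):
        cfg = self.config
        h, K = cfg.h, cfg.K
        g_lab = np.zeros_like(self.W_lab)
        g_bond = np.zeros_like(self.w_bond)
        loss = 0.0
        n_terms = 0
        # use both coarse and fine conditioning variants of every step
        for rec in batch:
            for d_feat in (rec.d_coarse, rec.d_fine):
                # ---- label head (add/ring steps)
                if rec.kind in ("add", "ring"):
                    z = rng.standard_normal(h)
                    x = self._label_features(z, d_feat, rec.H, float(rec.kind == "ring"))[0]
                    logits = x @ self.W_lab
                    mask = ring_mask if rec.kind == "ring" else chain_mask
                    logits = np.where(mask, logits, -1e9)
                    p = _softmax(logits)
                    loss -= np.log(max(p[rec.label_idx], 1e-12))
                    dlog = p.copy()
                    dlog[rec.label_idx] -= 1.0
                    dlog[~mask] = 0.0
                    g_lab += np.outer(x, dlog)
                    n_terms += 1
                # ---- decision head (chain add vs stop)
                if rec.kind in ("add", "stop"):
                    z_u = rng.standard_normal((K, h))
                    x_lab = self._label_features(z_u, d_feat, rec.H, 0.0)
                    lab_logits = x_lab @ self.W_lab
                    lab_logits = np.where(chain_mask, lab_logits, -1e9)
                    lab_p = _softmax(lab_logits, axis=1)
                    labels = _sample_rows(lab_p, rng)
                    phi = self._bond_features(
                        rec.z_focus, rec.focus_elem, z_u, labels,
                        rec.depth, d_feat, rec.H, rec.t,
                    )
                    logits = phi @ self.w_bond
                    p = _softmax(logits)
                    if rec.kind == "stop":
                        group = np.array([K])
                    else:
                        group = np.where(labels == rec.label_idx)[0]
                        if group.size == 0:
                            continue  # no candidate carries the true label
                    pg = p[group].sum()
                    loss -= np.log(max(pg, 1e-12))
                    dlog = p.copy()
                    dlog[group] -= p[group] / max(pg, 1e-12)
                    g_bond += phi.T @ dlog
                    n_terms += 1
        if n_terms:
            g_lab /= n_terms
            g_bond /= n_terms
            loss /= n_terms
        return loss, g_lab, g_bond

    # -- sampling --------------------------------------------------------------

    def sample(
        self,
        frag,
        profile: StructuralProfile,
        max_len: int,
        n: int,
        seed: int,
        guided: bool = True,
    ) -> list["SampledElaboration"]:
        """Draw up to ``n`` elaborations of ``frag`` conditioned on ``profile``.

        Every output contains the fragment as a substructure (the elaboration
        is grown on the fragment graph, so this is a construction guarantee)
        and has at most ``max_len`` elaboration heavy atoms. Invalid builds
        are dropped with a log message, so fewer than ``n`` may return.
        """
        if not self.trained:
            raise UntrainedModelError("model must be trained before sampling")
        rng = np.random.default_rng(seed)
        out: list[SampledElaboration] = []
        dropped = 0
        for _ in range(n):
            res = self._sample_one(frag, profile, max_len, rng, guided)
            if res is None:
                dropped += 1
            else:
                out.append(res)
        if dropped:
            logger.info("dropped %d invalid samples of %d", dropped, n)
        return out

    def _sample_one(self, frag, profile, max_len, rng, guided):
        cfg = self.config
        builder = ElaborationBuilder(frag.mol, frag.exit_atom, max_len=max_len)
        ring_def_a = 0
        for _ in range(200):  # hard iteration guard
            if builder.in_ring_mode():
                allowed = [
                    lb
                    for lb in RING_LABELS
                    if builder.ring_action_allowed(lb)
                    and (not guided or lb == "c" or ring_def_a - builder.ring.n_count > 0)
                ]
                if not allowed:
                    allowed = ["c"]
                z = rng.standard_normal(cfg.h)
                Z, H = self.encoder.encode(
                    builder.raw_graph(), set(builder.elab_atoms), builder._arom
                )
                cur = coarse_profile(builder.partial_mol(), builder.elab_atoms).counts
                d_feat = d_features(profile, cur, builder.budget, max_len, builder.t)
                x = self._label_features(z, d_feat, H, 1.0)[0]
                logits = x @ self.W_lab
                mask = np.array([lb in allowed for lb in ALL_LABELS])
                logits = np.where(mask, logits, -1e9)
                label = ALL_LABELS[int(_sample_rows(_softmax(logits), rng)[0])]
                builder.add_ring_atom(label)
                continue
            builder.auto_advance()
            if builder.finished:
                break
            focus = builder.focus
            assert focus is not None
            Z, H = self.encoder.encode(
                builder.raw_graph(), set(builder.elab_atoms), builder._arom
            )
            cur = coarse_profile(builder.partial_mol(), builder.elab_atoms).counts
            d_feat = d_features(profile, cur, builder.budget, max_len, builder.t)
            def_a, def_d, def_r = (np.array(profile.counts) - np.array(cur)).tolist()
            allowed = [
                lb
                for lb in CHAIN_LABELS
                if builder.chain_action_allowed(lb)
                and (not guided or self._guidance_ok(lb, def_a, def_d, def_r, builder.budget))
            ]
            if not allowed:
                builder.stop_focus()
                continue
            # expansion nodes: sample latents, assign labels
            z_u = rng.standard_normal((cfg.K, cfg.h))
            x_lab = self._label_features(z_u, d_feat, H, 0.0)
            lab_logits = x_lab @ self.W_lab
            lab_mask = np.array([lb in allowed for lb in ALL_LABELS])
            lab_logits = np.where(lab_mask, lab_logits, -1e9)
            lab_p = _softmax(lab_logits, axis=1)
            labels = _sample_rows(lab_p, rng)
            phi = self._bond_features(
                Z[focus], _elem_index(builder.focus_element()), z_u, labels,
                builder.depth.get(focus, 0), d_feat, H, builder.t,
            )
            logits = phi @ self.w_bond
            stop_banned = builder.t == 0 or (
                guided
                and not builder.queue
                and (max(def_a, 0) + max(def_d, 0) + max(def_r, 0)) > 0
            )
            if stop_banned:
                logits[-1] = -1e9
            choice = int(_sample_rows(_softmax(logits), rng)[0])
            if choice == cfg.K:
                builder.stop_focus()
                continue
            label = ALL_LABELS[labels[choice]]
            if label == "c1":
                ring_def_a = max(def_a, 0)
            builder.add_chain_atom(label)
        result = builder.result()
        if result is None:
            return None
        smiles, mol, elab_atoms = result
        if not mol.HasSubstructMatch(frag.mol):
            logger.warning("sample lost the fragment substructure; dropping")
            return None
        return SampledElaboration(
            smiles=smiles,
            mol=mol,
            elab_atoms=tuple(elab_atoms),
            attach_atom=elab_atoms[0],
        )

    @staticmethod
    def _guidance_ok(label: str, def_a: int, def_d: int, def_r: int, budget: int) -> bool:
        """Profile-feasibility mask: do not overshoot requested pharmacophore
        counts, and reserve remaining budget for unmet ones."""
        needed = 6 * max(def_r, 0) + max(max(def_a, 0), max(def_d, 0))
        if label == "c1":
            return def_r > 0
        if label in ("N", "O", "O="):
            return def_a > 0 or def_d > 0
        # plain scaffold atoms: fine unless the remaining budget is spoken for
        return not (0 < needed >= budget)


@dataclass
class SampledElaboration:
    """A generated molecule with its elaboration bookkeeping."""

    smiles: str
    mol: Chem.Mol
    elab_atoms: tuple[int, ...]
    attach_atom: int

    @property
    def n_elab_atoms(self) -> int:
        return len(self.elab_atoms)
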