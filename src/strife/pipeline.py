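"""Exploration/refinement orchestration and 2D filtering.

For each pharmacophoric point the pipeline:

1. predicts the exit-to-point atom path length p and samples elaborations
   conditioned on coarse profiles (one matching pharmacophore, aromatic count
   swept over {0, 1}) across requested lengths up to p + 4;
2. filters candidates in 2D (only passing molecules are posed, which keeps
   posing cost bounded), poses them with the fragment constrained, and keeps
   up to five "quasi-actives": molecules whose matching pharmacophore lands
   within 1.5 Å of the point, closest first;
3. derives fine-grained profiles (counts + path distances) from the
   quasi-actives, samples further elaborations conditioned on them, filters,
   poses, deduplicates and ranks unique molecules by ligand efficiency.

The quantitative-druglikeness (QED) flag is advisory and post hoc: molecules
scoring below the fragment's own QED (or an explicit override) are flagged,
never removed.
"""

from __future__ import annotations

import csv
import json
import logging
import os
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import QED, FilterCatalog

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, resolved via RDConfig)

from .elaborator import (
    PathLengthModel,
    default_path_length_model,
    predict_path_length,
)
from .errors import FragmentUnsuitableError, PoseFailureError
from .fragment import FragmentSpec
from .genmodel import ElaborationModel, SampledElaboration
from .hotspot_io import HotspotGrid, PharmacophoricPoint
from .hotspot_processing import (
    HotspotConfig,
    VoxelPointSet,
    extract_pharmacophoric_points,
    threshold_channel,
)
from .pharmacophores import StructuralProfile, fine_profile
from .scoring import (
    Pose,
    ScoringWeights,
    SurrogateBackend,
    ligand_efficiency,
    min_pharm_distance,
)

logger = logging.getLogger(__name__)

_pains_params = FilterCatalog.FilterCatalogParams()
_pains_params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
_PAINS_CATALOG = FilterCatalog.FilterCatalog(_pains_params)

QUASI_ACTIVE_CUTOFF = 1.5  # Å
QUASI_ACTIVE_TOP = 5


@dataclass
class QuasiActive:
    """An exploration hit: pharmacophore within 1.5 Å of the target point."""

    smiles: str
    matched_point: PharmacophoricPoint
    match_distance: float
    fine: StructuralProfile
    n_atoms: int

    def __post_init__(self) -> None:
        if not self.match_distance < QUASI_ACTIVE_CUTOFF:
            raise ValueError("quasi-actives must match within 1.5 Å")


@dataclass
class RankedElaboration:
    """A refined, posed molecule ranked by ligand efficiency (rank 1 = best)."""

    smiles: str
    ligand_efficiency: float
    rank: int
    filter_flags: frozenset[str]
    source_profile: StructuralProfile
    point_index: int = 0
    score: float = 0.0
    pose: Pose | None = None


# ---------------------------------------------------------------------------
# 2D filters
# ---------------------------------------------------------------------------


def _elab_ring_double_bond(mol: Chem.Mol, elab_atoms: Sequence[int] | None) -> bool:
    """True if a nonaromatic ring touching the elaboration has a double bond."""
    elab = set(elab_atoms) if elab_atoms is not None else None
    ri = mol.GetRingInfo()
    for ring in ri.BondRings():
        bonds = [mol.GetBondWithIdx(b) for b in ring]
        if any(b.GetIsAromatic() for b in bonds):
            continue
        if not any(b.GetBondType() == Chem.BondType.DOUBLE for b in bonds):
            continue
        atoms = {a for b in bonds for a in (b.GetBeginAtomIdx(), b.GetEndAtomIdx())}
        if elab is None or atoms & elab:
            return True
    return False


def filter_2d(
    mol: Chem.Mol | str,
    frag: FragmentSpec,
    elab_atoms: Sequence[int] | None = None,
) -> set[str]:
    """Violated 2D-filter flags for a generated molecule (empty set = pass).

    Flags: ``sascore`` when the molecule is harder to synthesize than its
    fragment, ``ring_double_bond`` when the elaboration carries a nonaromatic
    ring with a double bond, ``pains`` on any pan-assay-interference match.
    """
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            return {"invalid"}
    flags: set[str] = set()
    if sascorer.calculateScore(mol) > sascorer.calculateScore(frag.mol):
        flags.add("sascore")
    if _elab_ring_double_bond(mol, elab_atoms):
        flags.add("ring_double_bond")
    if _PAINS_CATALOG.HasMatch(mol):
        flags.add("pains")
    return flags


def filter_qed(
    mol: Chem.Mol | str,
    frag: FragmentSpec,
    threshold_override: float | None = None,
) -> bool:
    """Advisory druglikeness flag: True when QED(mol) is strictly below the
    fragment's QED (equality passes) or the explicit override threshold."""
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            return True
    threshold = threshold_override if threshold_override is not None else QED.qed(frag.mol)
    return QED.qed(mol) < threshold


# ---------------------------------------------------------------------------
# quasi-active selection
# ---------------------------------------------------------------------------


def select_quasi_actives(
    candidates: Sequence[tuple[str, float]],
    cutoff: float = QUASI_ACTIVE_CUTOFF,
    top: int = QUASI_ACTIVE_TOP,
) -> list[tuple[str, float]]:
    """Molecules with match distance < cutoff, the ``top`` smallest distances.

    Fewer are returned when fewer qualify. Ties break by candidate order.
    """
    qualifying = [(s, d) for s, d in candidates if d < cutoff]
    qualifying.sort(key=lambda sd: sd[1])
    return qualifying[:top]


# ---------------------------------------------------------------------------
# exploration / refinement
# ---------------------------------------------------------------------------


def _coarse_profiles_for(points: Sequence[PharmacophoricPoint]) -> list[StructuralProfile]:
    """Coarse conditioning sweep for a point set: the matching pharmacophore
    count(s), with the aromatic count swept over {0, 1}."""
    n_acc = sum(p.ptype == "acceptor" for p in points)
    n_don = sum(p.ptype == "donor" for p in points)
    return [
        StructuralProfile(n_acceptors=n_acc, n_donors=n_don, n_aromatic=a)
        for a in (0, 1)
    ]


def explore(
    frag: FragmentSpec,
    point: PharmacophoricPoint | Sequence[PharmacophoricPoint],
    model: ElaborationModel,
    backend: SurrogateBackend,
    path_model: PathLengthModel | None = None,
    n: int = 250,
    seed: int = 1,
) -> list[QuasiActive]:
    """Exploration phase for one pharmacophoric point (or a set, in the
    explicitly requested multi-point mode): coarse-profile sampling, 2D
    filtering, constrained posing, quasi-active selection."""
    points = [point] if isinstance(point, PharmacophoricPoint) else list(point)
    path_model = path_model or default_path_length_model(seed)
    pred = max(
        (predict_path_length(frag.exit_pos, p, path_model) for p in points),
        key=lambda lp: lp.max_len,
    )
    profiles = _coarse_profiles_for(points)
    conditions = [
        (length, prof)
        for length in range(1, pred.max_len + 1)
        for prof in profiles
        if not (prof.n_aromatic > 0 and length < 6)
    ]
    per_cond = max(1, int(np.ceil(n / len(conditions))))
    candidates: dict[str, SampledElaboration] = {}
    budget = n
    for k, (length, prof) in enumerate(conditions):
        take = min(per_cond, budget)
        if take <= 0:
            break
        budget -= take
        for s in model.sample(frag, prof, max_len=length, n=take, seed=seed * 10007 + k):
            candidates.setdefault(s.smiles, s)

    scored: list[tuple[str, float, SampledElaboration, Pose]] = []
    for i, (smiles, cand) in enumerate(sorted(candidates.items())):
        if filter_2d(cand.mol, frag, cand.elab_atoms):
            continue
        try:
            pose = backend.pose_and_score(
                cand.mol, frag, seed=seed + 31 * i, elab_atoms=cand.elab_atoms
            )
        except PoseFailureError:
            continue
        dist = max(min_pharm_distance(pose, p) for p in points)
        if np.isfinite(dist):
            scored.append((smiles, dist, cand, pose))

    selected = select_quasi_actives([(s, d) for s, d, _, _ in scored])
    by_smiles = {s: (c, d) for s, d, c, _ in scored}
    quasi: list[QuasiActive] = []
    for smiles, dist in selected:
        cand, _ = by_smiles[smiles]
        fine = fine_profile(cand.mol, list(cand.elab_atoms), cand.attach_atom)
        quasi.append(
            QuasiActive(
                smiles=smiles,
                matched_point=points[0],
                match_distance=dist,
                fine=fine,
                n_atoms=cand.n_elab_atoms,
            )
        )
    return quasi


def refine(
    frag: FragmentSpec,
    quasi: Sequence[QuasiActive],
    model: ElaborationModel,
    backend: SurrogateBackend,
    n_total: int = 100,
    mode: str = "sampled",
    seed: int = 1,
    point_index: int = 0,
    qed_override: float | None = None,
) -> list[RankedElaboration]:
    """Refinement phase: sample with fine-grained profiles derived from the
    quasi-actives, 2D-filter, pose, deduplicate and rank by ligand efficiency."""
    if not quasi:
        raise ValueError("refinement requires at least one quasi-active")
    if mode not in ("per_profile", "sampled"):
        raise ValueError("mode must be 'per_profile' or 'sampled'")
    rng = np.random.default_rng(seed)
    if mode == "per_profile":
        counts = [n_total // len(quasi) + (1 if i < n_total % len(quasi) else 0)
                  for i in range(len(quasi))]
    else:
        draws = rng.integers(0, len(quasi), size=n_total)
        counts = [int(np.sum(draws == i)) for i in range(len(quasi))]

    sampled: dict[str, tuple[SampledElaboration, StructuralProfile]] = {}
    for i, (q, cnt) in enumerate(zip(quasi, counts)):
        if cnt == 0:
            continue
        for s in model.sample(
            frag, q.fine, max_len=q.n_atoms, n=cnt, seed=seed * 7919 + i
        ):
            sampled.setdefault(s.smiles, (s, q.fine))

    results: list[RankedElaboration] = []
    for i, (smiles, (cand, prof)) in enumerate(sorted(sampled.items())):
        flags = filter_2d(cand.mol, frag, cand.elab_atoms)
        if flags:
            continue  # only molecules passing the 2D filters are posed
        try:
            pose = backend.pose_and_score(
                cand.mol, frag, seed=seed + 53 * i, elab_atoms=cand.elab_atoms
            )
        except PoseFailureError:
            continue
        le = ligand_efficiency(pose.score, cand.mol.GetNumHeavyAtoms())
        qed_flags = {"qed"} if filter_qed(cand.mol, frag, qed_override) else set()
        results.append(
            RankedElaboration(
                smiles=smiles,
                ligand_efficiency=le,
                rank=0,
                filter_flags=frozenset(qed_flags),
                source_profile=prof,
                point_index=point_index,
                score=pose.score,
                pose=pose,
            )
        )
    results.sort(key=lambda r: (r.ligand_efficiency, r.smiles))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    points: list[PharmacophoricPoint]
    quasi_actives: dict[int, list[QuasiActive]]
    ranked: dict[int, list[RankedElaboration]]
    log: dict

    @property
    def all_ranked(self) -> list[RankedElaboration]:
        return [r for rs in self.ranked.values() for r in rs]


def _fallback_pocket(frag: FragmentSpec, points: Sequence[PharmacophoricPoint]) -> VoxelPointSet:
    """Apolar envelope stand-in when no grids are supplied (manual points):
    a 1 Å lattice within 5 Å of any fragment atom or target point."""
    anchors = np.vstack([frag.heavy_atom_coords] + [p.position[None] for p in points])
    lo = anchors.min(axis=0) - 5.0
    hi = anchors.max(axis=0) + 5.0
    axes = [np.arange(lo[i], hi[i] + 1.0, 1.0) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d = np.min(
        np.linalg.norm(pts[:, None, :] - anchors[None, :, :], axis=2), axis=1
    )
    keep = pts[d <= 5.0]
    return VoxelPointSet("apolar", keep, np.ones(len(keep)))


def run_strife(
    frag: FragmentSpec,
    model: ElaborationModel,
    grids: dict[str, HotspotGrid] | None = None,
    points: Sequence[PharmacophoricPoint] | None = None,
    path_model: PathLengthModel | None = None,
    n_explore: int = 250,
    n_refine: int = 100,
    refine_mode: str = "sampled",
    seed: int = 1,
    out_dir: str | Path | None = None,
    hotspot_config: HotspotConfig | None = None,
    weights: ScoringWeights | None = None,
    override_containment: bool = False,
    multi: bool = False,
    qed_override: float | None = None,
) -> RunResult:
    """End-to-end run: points (from grids or manual), explore, refine, rank.

    By default each pharmacophoric point is addressed by its own elaboration
    round; ``multi=True`` (only sensible for manually curated points)
    conditions on all points simultaneously. Fully reproducible per seed.
    """
    hotspot_config = hotspot_config or HotspotConfig()
    if points is not None:
        point_list = list(points)
        pocket = (
            threshold_channel(grids["apolar"], hotspot_config)
            if grids
            else _fallback_pocket(frag, point_list)
        )
    else:
        if grids is None:
            raise ValueError("either grids or manual points are required")
        point_list = extract_pharmacophoric_points(
            grids, frag, hotspot_config, override_containment=override_containment
        )
        pocket = threshold_channel(grids["apolar"], hotspot_config)

    weights = weights or ScoringWeights(
        containment_tol=(grids["apolar"].spacing if grids else 1.0)
    )
    path_model = path_model or default_path_length_model(seed)
    log: dict = {"seed": seed, "n_points": len(point_list), "points": [
        {"ptype": p.ptype, "position": [round(float(x), 4) for x in p.position]}
        for p in point_list
    ]}

    if not point_list:
        logger.warning("no pharmacophoric points found; nothing to elaborate")
        result = RunResult(points=[], quasi_actives={}, ranked={}, log=log)
        if out_dir is not None:
            _write_outputs(result, Path(out_dir))
        return result

    rounds: list[tuple[int, list[PharmacophoricPoint]]]
    if multi:
        rounds = [(0, point_list)]
    else:
        rounds = [(i, [p]) for i, p in enumerate(point_list)]

    quasi_map: dict[int, list[QuasiActive]] = {}
    ranked_map: dict[int, list[RankedElaboration]] = {}
    for idx, pts in rounds:
        backend = SurrogateBackend(pocket=pocket, targets=tuple(pts), weights=weights)
        quasi = explore(
            frag, pts if multi else pts[0], model, backend,
            path_model=path_model, n=n_explore, seed=seed + 1009 * idx,
        )
        quasi_map[idx] = quasi
        if not quasi:
            logger.warning("point %d: no quasi-actives found; skipping", idx)
            ranked_map[idx] = []
            continue
        ranked_map[idx] = refine(
            frag, quasi, model, backend,
            n_total=n_refine, mode=refine_mode, seed=seed + 2003 * idx,
            point_index=idx, qed_override=qed_override,
        )
    log["n_quasi"] = {str(k): len(v) for k, v in quasi_map.items()}
    log["n_ranked"] = {str(k): len(v) for k, v in ranked_map.items()}

    result = RunResult(points=point_list, quasi_actives=quasi_map, ranked=ranked_map, log=log)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "ranked.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["point", "rank", "smiles", "ligand_efficiency", "score", "flags"])
        for idx in sorted(result.ranked):
            for r in result.ranked[idx]:
                writer.writerow(
                    [idx, r.rank, r.smiles, f"{r.ligand_efficiency:.6f}",
                     f"{r.score:.6f}", ";".join(sorted(r.filter_flags))]
                )
    sdf_path = out_dir / "ranked.sdf"
    sdf = Chem.SDWriter(str(sdf_path))
    try:
        for idx in sorted(result.ranked):
            for r in result.ranked[idx]:
                if r.pose is None:
                    continue
                mol = r.pose.as_mol()
                mol.SetProp("_Name", r.smiles)
                mol.SetProp("RANK", str(r.rank))
                mol.SetProp("POINT", str(idx))
                mol.SetProp("LIGAND_EFFICIENCY", f"{r.ligand_efficiency:.6f}")
                sdf.write(mol)
    finally:
        sdf.close()
    (out_dir / "run_log.json").write_text(json.dumps(result.log, indent=2, sort_keys=True))
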