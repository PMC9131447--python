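"""Convert raw hotspot grids into pharmacophoric points.

Pipeline per polar channel (donor, acceptor):

1. threshold the grid (>1 apolar, >10 polar by default; 17 is the stricter
   published cut for predicting fragment binding),
2. keep voxels 1.5-5 Å from the fragment exit vector and closer to the exit
   vector than to any other fragment heavy atom,
3. single-linkage cluster at 1 Å,
4. consolidate: drop the smaller of centroid pairs <1.5 Å apart, then drop
   clusters smaller than 8 voxels unless no cluster reaches 8,
5. keep only centroids contained in the apolar envelope; a fragment with any
   heavy atom outside the envelope is flagged unsuitable for elaboration
   (overridable).

Cluster membership is defined by connected components of the <=link-distance
graph, which makes the partition independent of seed-point selection order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import FragmentUnsuitableError
from .fragment import FragmentSpec
from .hotspot_io import Channel, HotspotGrid, PharmacophoricPoint


@dataclass
class HotspotConfig:
    """Thresholds and distances for hotspot-grid processing (Å)."""

    apolar_cut: float = 1.0
    polar_cut: float = 10.0
    dmin: float = 1.5
    dmax: float = 5.0
    link: float = 1.0
    merge: float = 1.5
    min_size: int = 8
    containment_tol: float | None = None  # default: one voxel spacing


@dataclass
class VoxelPointSet:
    """Above-threshold voxel centres of one channel, with their scores."""

    channel: Channel
    points: np.ndarray  # (N, 3)
    values: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.points) != len(self.values):
            raise ValueError("points and values must have matching lengths")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Cluster:
    """A connected set of voxel centres; centroid is the member mean."""

    member_points: np.ndarray
    centroid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.member_points = np.asarray(self.member_points, dtype=float).reshape(-1, 3)
        if len(self.member_points) == 0:
            raise ValueError("cluster must have at least one member")
        self.centroid = self.member_points.mean(axis=0)

    @property
    def size(self) -> int:
        return len(self.member_points)


def threshold_channel(grid: HotspotGrid, config: HotspotConfig | None = None) -> VoxelPointSet:
    """Keep voxel centres whose score exceeds the channel threshold."""
    config = config or HotspotConfig()
    cut = config.apolar_cut if grid.channel == "apolar" else config.polar_cut
    flat = grid.flat_values()
    mask = flat > cut
    return VoxelPointSet(grid.channel, grid.voxel_centers()[mask], flat[mask])


def filter_by_exit_distance(
    pts: VoxelPointSet, frag: FragmentSpec, config: HotspotConfig | None = None
) -> VoxelPointSet:
    """Keep voxels in the [dmin, dmax] shell around the fragment exit vector
    that are closer to the exit vector than to any other fragment heavy atom."""
    config = config or HotspotConfig()
    if len(pts) == 0:
        return pts
    exit_pos = frag.exit_pos
    d_exit = np.linalg.norm(pts.points - exit_pos, axis=1)
    keep = (d_exit >= config.dmin) & (d_exit <= config.dmax)
    other = np.delete(frag.heavy_atom_coords, frag.exit_atom, axis=0)
    if len(other):
        d_other = np.linalg.norm(
            pts.points[:, None, :] - other[None, :, :], axis=2
        ).min(axis=1)
        keep &= d_exit <= d_other
    return VoxelPointSet(pts.channel, pts.points[keep], pts.values[keep])


def greedy_cluster(pts: VoxelPointSet | np.ndarray, link: float = 1.0) -> list[Cluster]:
    """Cluster points into single-linkage connected components at ``link`` Å.

    Growing a cluster greedily by repeatedly absorbing all unclustered points
    within the link distance yields exactly the connected components of the
    <=link adjacency graph, so the result does not depend on seed-point order.
    """
    if link <= 0:
        raise ValueError("link distance must be positive")
    points = pts.points if isinstance(pts, VoxelPointSet) else np.asarray(pts, float)
    n = len(points)
    if n == 0:
        return []
    tree = cKDTree(points)
    pairs = tree.query_pairs(link, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = csr_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = [Cluster(points[labels == c]) for c in range(n_comp)]
    # deterministic ordering: by first member index
    first = [int(np.argmax(labels == c)) for c in range(n_comp)]
    return [clusters[i] for i in np.argsort(first)]


def consolidate_clusters(
    clusters: Sequence[Cluster], merge: float = 1.5, min_size: int = 8
) -> list[Cluster]:
    """Apply the redundancy and size rules to a cluster list.

    Repeatedly, while any two surviving centroids are closer than ``merge``:
    take the closest such pair (ties broken toward the earlier pair in index
    order) and delete the smaller cluster (equal sizes: delete the
    later-indexed one). Centroids are never recomputed: deletion removes whole
    clusters. Finally drop clusters with fewer than ``min_size`` members,
    unless no survivor reaches ``min_size``, in which case all survivors are
    retained.
    """
    alive = list(range(len(clusters)))
    while True:
        best: tuple[float, int, int] | None = None
        for ii, i in enumerate(alive):
            for j in alive[ii + 1 :]:
                d = float(np.linalg.norm(clusters[i].centroid - clusters[j].centroid))
                if d < merge and (best is None or d < best[0] - 1e-12):
                    best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        if clusters[i].size > clusters[j].size:
            alive.remove(j)
        elif clusters[j].size > clusters[i].size:
            alive.remove(i)
        else:
            alive.remove(j)  # tie: delete the later-indexed cluster
    survivors = [clusters[i] for i in alive]
    big = [c for c in survivors if c.size >= min_size]
    return big if big else survivors


def apolar_containment(
    points: Sequence[PharmacophoricPoint],
    apolar: VoxelPointSet,
    frag: FragmentSpec,
    tol: float,
    override: bool = False,
) -> list[PharmacophoricPoint]:
    """Filter points to those contained in the apolar hotspot envelope.

    A position is contained iff it lies within ``tol`` (by default one voxel
    spacing) of any retained apolar voxel centre. If any fragment heavy atom
    is uncontained the fragment is deemed unsuitable for elaboration and
    :class:`FragmentUnsuitableError` is raised, unless ``override`` is set.
    """
    if len(apolar) == 0:
        if not override:
            raise FragmentUnsuitableError("apolar hotspot envelope is empty")
        return []
    tree = cKDTree(apolar.points)

    def contained(pos: np.ndarray) -> bool:
        d, _ = tree.query(pos)
        return bool(d <= tol)

    if not override:
        for i, pos in enumerate(frag.heavy_atom_coords):
            if not contained(pos):
                raise FragmentUnsuitableError(
                    f"fragment heavy atom {i} lies outside the apolar hotspot envelope"
                )
    return [p for p in points if contained(p.position)]


def extract_pharmacophoric_points(
    grids: dict[str, HotspotGrid],
    frag: FragmentSpec,
    config: HotspotConfig | None = None,
    override_containment: bool = False,
) -> list[PharmacophoricPoint]:
    """Full grid-to-points pipeline over the donor and acceptor channels."""
    config = config or HotspotConfig()
    for ch in ("apolar", "donor", "acceptor"):
        if ch not in grids:
            raise ValueError(f"missing {ch} grid")
    apolar_pts = threshold_channel(grids["apolar"], config)
    tol = config.containment_tol if config.containment_tol is not None else grids["apolar"].spacing

    points: list[PharmacophoricPoint] = []
    for ch in ("donor", "acceptor"):
        pts = threshold_channel(grids[ch], config)
        pts = filter_by_exit_distance(pts, frag, config)
        clusters = greedy_cluster(pts, config.link)
        clusters = consolidate_clusters(clusters, config.merge, config.min_size)
        for cl in sorted(clusters, key=lambda c: (-c.size, tuple(c.centroid))):
            points.append(
                PharmacophoricPoint(
                    ptype=ch, position=cl.centroid, cluster_size=cl.size, source="fhm"
                )
            )
    return apolar_containment(points, apolar_pts, frag, tol, override=override_containment)
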