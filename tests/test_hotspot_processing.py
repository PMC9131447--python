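import numpy as np
import pytest

from strife import FragmentSpec
from strife.errors import FragmentUnsuitableError
from strife.hotspot_io import HotspotGrid, PharmacophoricPoint, make_synthetic_pocket
from strife.hotspot_processing import (
    Cluster,
    HotspotConfig,
    VoxelPointSet,
    apolar_containment,
    consolidate_clusters,
    extract_pharmacophoric_points,
    filter_by_exit_distance,
    greedy_cluster,
    threshold_channel,
)


def _frag_at(exit_pos, other=()):
    """Two-atom fragment (ethane-like) with controlled coordinates."""
    coords = np.vstack([np.asarray(exit_pos, float)[None], np.asarray(other, float).reshape(-1, 3)])
    frag = FragmentSpec.from_smiles("[*]" + "C" * len(coords))
    # from_smiles gives a chain; exit atom is the first
    return FragmentSpec(mol=frag.mol, exit_atom=frag.exit_atom, coords=_chain_coords(frag, exit_pos, other))


def _chain_coords(frag, exit_pos, other):
    n = frag.mol.GetNumAtoms()
    coords = np.zeros((n, 3))
    coords[frag.exit_atom] = exit_pos
    rest = [i for i in range(n) if i != frag.exit_atom]
    for i, pos in zip(rest, np.asarray(other, float).reshape(-1, 3)):
        coords[i] = pos
    return coords


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def test_threshold_all_below_gives_empty():
    grid = HotspotGrid("donor", np.zeros(3), 0.5, np.full((4, 4, 4), 10.0))
    assert len(threshold_channel(grid)) == 0  # strict >


def test_threshold_single_voxel_apolar():
    values = np.zeros((4, 4, 4))
    values[1, 2, 3] = 1.5
    grid = HotspotGrid("apolar", np.zeros(3), 0.5, values)
    pts = threshold_channel(grid)
    assert len(pts) == 1
    assert np.allclose(pts.points[0], [0.5, 1.0, 1.5])
    assert pts.values[0] == 1.5


def test_threshold_count_matches_brute_force():
    grids, _ = make_synthetic_pocket(seed=4, n_blobs=2, exit_pos=[0, 0, 0])
    for ch, cut in (("apolar", 1.0), ("donor", 10.0), ("acceptor", 10.0)):
        pts = threshold_channel(grids[ch])
        assert len(pts) == int(np.sum(grids[ch].values > cut))


# ---------------------------------------------------------------------------
# exit-distance filtering
# ---------------------------------------------------------------------------


def test_exit_distance_shell_bounds():
    frag = FragmentSpec.from_smiles("[*]C")
    frag = FragmentSpec(mol=frag.mol, exit_atom=frag.exit_atom, coords=np.zeros((1, 3)))
    pts = VoxelPointSet("donor", [[1.0, 0, 0], [1.5, 0, 0], [5.0, 0, 0], [5.3, 0, 0]], [1, 2, 3, 4])
    kept = filter_by_exit_distance(pts, frag)
    # 1.0 below dmin (removed); 1.5 and 5.0 inclusive bounds; 5.3 above
    assert np.allclose(kept.points, [[1.5, 0, 0], [5.0, 0, 0]])
    assert np.allclose(kept.values, [2, 3])


def test_exit_distance_removes_points_closer_to_other_atom():
    frag = _frag_at([0, 0, 0], other=[[4.0, 0, 0]])
    pts = VoxelPointSet(
        "donor",
        [[2.5, 0, 0],   # closer to the other atom at x=4 (1.5 < 2.5) -> removed
         [-2.5, 0, 0],  # closer to exit -> kept
         [2.0, 0, 0]],  # equidistant -> kept (<= rule)
        [1, 2, 3],
    )
    kept = filter_by_exit_distance(pts, frag)
    assert np.allclose(kept.points, [[-2.5, 0, 0], [2.0, 0, 0]])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def test_two_points_beyond_link_form_two_clusters():
    clusters = greedy_cluster(np.array([[0, 0, 0], [1.1, 0, 0]]), link=1.0)
    assert [c.size for c in clusters] == [1, 1]


def test_chain_links_into_one_cluster():
    points = np.array([[0.9 * i, 0.0, 0.0] for i in range(50)])
    clusters = greedy_cluster(points, link=1.0)
    assert len(clusters) == 1
    assert clusters[0].size == 50
    span = np.linalg.norm(points[-1] - points[0])
    assert span > 44  # single linkage chains far beyond the link distance


def test_cluster_partition_matches_bfs_oracle():
    rng = np.random.default_rng(13)
    points = rng.uniform(0, 6, size=(120, 3))
    clusters = greedy_cluster(points, link=1.0)
    labels = _bfs_components(points, 1.0)
    ours = {frozenset(map(tuple, c.member_points)) for c in clusters}
    theirs = {
        frozenset(tuple(points[i]) for i in range(len(points)) if labels[i] == c)
        for c in set(labels)
    }
    assert ours == theirs


def _bfs_components(points, link):
    n = len(points)
    labels = [-1] * n
    cur = 0
    for s in range(n):
        if labels[s] != -1:
            continue
        stack = [s]
        labels[s] = cur
        while stack:
            i = stack.pop()
            for j in range(n):
                if labels[j] == -1 and np.linalg.norm(points[i] - points[j]) <= link:
                    labels[j] = cur
                    stack.append(j)
        cur += 1
    return labels


def test_cluster_order_invariance():
    rng = np.random.default_rng(17)
    points = rng.uniform(0, 4, size=(60, 3))
    perm = rng.permutation(60)
    a = {frozenset(map(tuple, c.member_points)) for c in greedy_cluster(points)}
    b = {frozenset(map(tuple, c.member_points)) for c in greedy_cluster(points[perm])}
    assert a == b


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------


def _cluster_at(center, size):
    return Cluster(np.tile(np.asarray(center, float), (size, 1)))


def test_consolidation_deletes_smaller_of_close_pair():
    big = _cluster_at([0, 0, 0], 10)
    small = _cluster_at([1.4, 0, 0], 3)
    out = consolidate_clusters([big, small])
    assert len(out) == 1 and out[0] is big


def test_consolidation_keeps_separated_pair():
    a = _cluster_at([0, 0, 0], 10)
    b = _cluster_at([1.6, 0, 0], 3)
    out = consolidate_clusters([a, b], min_size=2)
    assert [id(c) for c in out] == [id(a), id(b)]


def test_consolidation_tie_deletes_later_cluster():
    a = _cluster_at([0, 0, 0], 9)
    b = _cluster_at([1.0, 0, 0], 9)
    out = consolidate_clusters([a, b], min_size=1)
    assert len(out) == 1 and out[0] is a


def test_consolidation_all_small_retention():
    a = _cluster_at([0, 0, 0], 4)
    b = _cluster_at([5, 0, 0], 3)
    out = consolidate_clusters([a, b], min_size=8)
    assert [id(c) for c in out] == [id(a), id(b)]  # all-small retention


def test_consolidation_size_filter_applies_after_merge():
    a = _cluster_at([0, 0, 0], 9)
    b = _cluster_at([1.0, 0, 0], 5)
    c = _cluster_at([9, 9, 9], 2)
    out = consolidate_clusters([a, b, c], min_size=8)
    assert len(out) == 1 and out[0] is a


def test_consolidation_centroids_never_recomputed():
    # a(size 5) and b(size 4) are close: b deleted. c sits 1.4 Å from the
    # ORIGINAL a centroid; with no recomputation a-c still conflicts, c deleted.
    a = _cluster_at([0, 0, 0], 5)
    b = _cluster_at([0.5, 0, 0], 4)
    c = _cluster_at([1.4, 0, 0], 3)
    out = consolidate_clusters([a, b, c], min_size=1)
    assert len(out) == 1 and out[0] is a


# ---------------------------------------------------------------------------
# containment + full extraction
# ---------------------------------------------------------------------------


def test_containment_raises_when_fragment_outside():
    frag = FragmentSpec.from_smiles("[*]C")
    frag = FragmentSpec(mol=frag.mol, exit_atom=0, coords=np.array([[50.0, 0, 0]]))
    apolar = VoxelPointSet("apolar", [[0, 0, 0]], [2.0])
    pt = PharmacophoricPoint("donor", [0.2, 0, 0])
    with pytest.raises(FragmentUnsuitableError):
        apolar_containment([pt], apolar, frag, tol=0.5)
    # override proceeds and keeps the contained point
    kept = apolar_containment([pt], apolar, frag, tol=0.5, override=True)
    assert len(kept) == 1 and kept[0] is pt


def test_containment_filters_outside_points():
    frag = FragmentSpec.from_smiles("[*]C")
    frag = FragmentSpec(mol=frag.mol, exit_atom=0, coords=np.array([[0.0, 0, 0]]))
    apolar = VoxelPointSet("apolar", [[0, 0, 0]], [2.0])
    inside = PharmacophoricPoint("donor", [0.4, 0, 0])
    outside = PharmacophoricPoint("donor", [3.0, 0, 0])
    kept = apolar_containment([inside, outside], apolar, frag, tol=0.5)
    assert len(kept) == 1 and kept[0] is inside


def test_extract_missing_channel_raises(amide_frag, planted_pocket):
    grids, _ = planted_pocket
    partial = {k: v for k, v in grids.items() if k != "donor"}
    with pytest.raises(ValueError):
        extract_pharmacophoric_points(partial, amide_frag)


def test_extracted_points_lie_in_shell_and_envelope(amide_frag):
    avoid = np.delete(amide_frag.coords, amide_frag.exit_atom, axis=0)
    grids, _ = make_synthetic_pocket(
        seed=23, n_blobs=3, exit_pos=amide_frag.exit_pos, avoid_coords=avoid
    )
    points = extract_pharmacophoric_points(grids, amide_frag)
    assert points
    apolar = threshold_channel(grids["apolar"])
    for p in points:
        d = np.linalg.norm(p.position - amide_frag.exit_pos)
        assert 1.5 <= d <= 5.0
        dmin = np.min(np.linalg.norm(apolar.points - p.position, axis=1))
        assert dmin <= grids["apolar"].spacing
        assert p.source == "fhm" and p.cluster_size >= 8
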