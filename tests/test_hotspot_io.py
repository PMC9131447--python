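import numpy as np
import pytest

from strife.errors import EmptyInputError, GridFormatError
from strife.hotspot_io import (
    HotspotGrid,
    PharmacophoricPoint,
    make_synthetic_pocket,
    read_grid,
    read_points_sdf,
    write_grid,
    write_points_sdf,
)


def _random_grid(seed=0, dims=(7, 6, 5)):
    rng = np.random.default_rng(seed)
    return HotspotGrid(
        channel="donor",
        origin=np.array([1.25, -3.5, 10.0]),
        spacing=0.5,
        values=rng.uniform(0, 20, size=dims),
        frame_id="t1",
    )


def test_ascii_round_trip(tmp_path):
    grid = _random_grid()
    path = write_grid(grid, tmp_path / "g.grd")
    back = read_grid(path, "donor")
    assert np.allclose(back.values, grid.values, atol=1e-6)
    assert np.allclose(back.origin, grid.origin, atol=1e-6)
    assert back.spacing == pytest.approx(grid.spacing, abs=1e-6)
    assert back.frame_id == "t1"
    assert back.channel == "donor"


def test_ccp4_round_trip(tmp_path):
    grid = _random_grid(seed=3)
    path = write_grid(grid, tmp_path / "g.ccp4")
    back = read_grid(path, "donor")
    assert np.allclose(back.values, grid.values, atol=1e-5)
    assert np.allclose(back.origin, grid.origin, atol=1e-6)
    assert back.spacing == pytest.approx(grid.spacing, abs=1e-6)


def test_format_sniffing_ignores_extension(tmp_path):
    grid = _random_grid()
    path = write_grid(grid, tmp_path / "misnamed.ccp4", fmt="ascii")
    back = read_grid(path, "donor")
    assert np.allclose(back.values, grid.values, atol=1e-6)


def test_bad_ascii_header_raises(tmp_path):
    path = tmp_path / "bad.grd"
    path.write_text("# strife grid v1\nchannel donor\nspacing 0.5\n1 2 3\n")
    with pytest.raises(GridFormatError):
        read_grid(path, "donor")


def test_value_count_mismatch_raises(tmp_path):
    path = tmp_path / "bad.grd"
    path.write_text(
        "# strife grid v1\norigin 0 0 0\nspacing 0.5\ndims 2 2 2\n1 2 3\n"
    )
    with pytest.raises(GridFormatError):
        read_grid(path, "donor")


def test_garbage_binary_raises(tmp_path):
    path = tmp_path / "junk.map"
    path.write_bytes(b"\x00\x01nonsense" * 10)
    with pytest.raises(GridFormatError):
        read_grid(path, "apolar")


def test_negative_values_rejected_on_construction():
    with pytest.raises(ValueError):
        HotspotGrid("donor", np.zeros(3), 0.5, -np.ones((2, 2, 2)))


def test_voxel_centers_order_matches_flat_values():
    grid = _random_grid(dims=(3, 4, 2))
    centers = grid.voxel_centers()
    flat = grid.flat_values()
    # spot-check a specific voxel
    idx = (2, 1, 1)
    pos = grid.origin + np.array(idx) * grid.spacing
    k = int(np.argmin(np.linalg.norm(centers - pos, axis=1)))
    assert np.allclose(centers[k], pos)
    assert flat[k] == grid.values[idx]


def test_points_sdf_round_trip(tmp_path):
    pts = [
        PharmacophoricPoint("donor", [1.0, 2.0, 3.0], cluster_size=12, source="fhm"),
        PharmacophoricPoint("acceptor", [-4.25, 0.5, 9.0]),
    ]
    path = write_points_sdf(pts, tmp_path / "p.sdf")
    back = read_points_sdf(path)
    assert len(back) == 2
    for orig, rt in zip(pts, back):
        assert rt.ptype == orig.ptype
        assert np.allclose(rt.position, orig.position, atol=1e-4)
        assert rt.cluster_size == orig.cluster_size
        assert rt.source == orig.source


def test_points_sdf_empty_raises(tmp_path):
    with pytest.raises(EmptyInputError):
        write_points_sdf([], tmp_path / "p.sdf")


def test_synthetic_pocket_no_blobs_polar_below_threshold():
    grids, blobs = make_synthetic_pocket(seed=5, n_blobs=0, exit_pos=[0, 0, 0])
    assert blobs == []
    assert grids["donor"].values.max() < 10
    assert grids["acceptor"].values.max() < 10
    assert grids["apolar"].values.max() > 1


def test_synthetic_pocket_deterministic():
    a, blobs_a = make_synthetic_pocket(seed=9, n_blobs=2, exit_pos=[1, 2, 3])
    b, blobs_b = make_synthetic_pocket(seed=9, n_blobs=2, exit_pos=[1, 2, 3])
    for ch in ("apolar", "donor", "acceptor"):
        assert np.array_equal(a[ch].values, b[ch].values)
    for x, y in zip(blobs_a, blobs_b):
        assert np.array_equal(x.center, y.center) and x.channel == y.channel


def test_synthetic_pocket_blob_geometry():
    grids, blobs = make_synthetic_pocket(seed=11, n_blobs=3, exit_pos=[5, -5, 0])
    exit_pos = np.array([5.0, -5.0, 0.0])
    for b in blobs:
        d = np.linalg.norm(b.center - exit_pos)
        assert 1.5 <= d <= 5.0
    for i in range(len(blobs)):
        for j in range(i + 1, len(blobs)):
            assert np.linalg.norm(blobs[i].center - blobs[j].center) >= 3.0
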