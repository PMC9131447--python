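"""Read/write fragment-hotspot grids and pharmacophoric-point files.

Two grid dialects are supported:

* CCP4/MRC volumetric maps (via :mod:`gemmi`), the field standard. Only
  orthogonal cells with cubic voxels are accepted; the map origin is taken
  from the MRC2014 ORIGIN header words.
* A plain-text ``.grd`` dialect for fixtures and interchange::

      # strife grid v1
      channel donor
      frame_id 1abc_A
      origin 10.0 4.5 -2.0
      spacing 0.5
      dims 32 32 32
      <nx*ny*nz whitespace-separated values, x index varying fastest>

Pharmacophoric points travel as SDF: one single-atom record per point,
acceptor encoded as an O atom and donor as an N atom for viewer legibility,
with an authoritative ``PTYPE`` data field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .errors import EmptyInputError, GridFormatError, UnsupportedGeometryError

logger = logging.getLogger(__name__)

Channel = Literal["apolar", "donor", "acceptor"]
CHANNELS: tuple[Channel, ...] = ("apolar", "donor", "acceptor")

#: SDF element convention for manual/FHM pharmacophoric points.
PTYPE_TO_ELEMENT = {"acceptor": "O", "donor": "N"}
ELEMENT_TO_PTYPE = {v: k for k, v in PTYPE_TO_ELEMENT.items()}


@dataclass
class HotspotGrid:
    """One channel of a volumetric propensity map.

    Voxel centres sit at ``origin + index * spacing`` (0-based indices,
    Angstroms, protein frame). ``values[ix, iy, iz]`` holds non-negative
    propensity scores.
    """

    channel: Channel
    origin: np.ndarray
    spacing: float
    values: np.ndarray
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3D array")
        if np.any(self.values < 0):
            raise ValueError("grid values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_center(self, index: Sequence[int]) -> np.ndarray:
        """Cartesian centre of the voxel at a 0-based (ix, iy, iz) index."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of all voxel centres, x index varying fastest."""
        nx, ny, nz = self.values.shape
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack(
            [ix.ravel(order="F"), iy.ravel(order="F"), iz.ravel(order="F")], axis=1
        )
        return self.origin + idx * self.spacing

    def flat_values(self) -> np.ndarray:
        """Values flattened in the same order as :meth:`voxel_centers`."""
        return self.values.ravel(order="F")


@dataclass
class PharmacophoricPoint:
    """A typed 3D target location for elaborations (protein frame, Å)."""

    ptype: Literal["donor", "acceptor"]
    position: np.ndarray
    cluster_size: int = 0
    source: Literal["fhm", "manual"] = "manual"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.ptype not in ("donor", "acceptor"):
            raise ValueError(f"unknown pharmacophore type {self.ptype!r}")
        if self.source == "fhm" and self.cluster_size < 1:
            raise ValueError("FHM-derived points must have cluster_size >= 1")
        if self.source == "manual":
            self.cluster_size = 0


# ---------------------------------------------------------------------------
# Grid I/O
# ---------------------------------------------------------------------------

_ASCII_MAGIC = "# strife grid v1"


def _clamp_negative(values: np.ndarray, path: str) -> np.ndarray:
    if np.any(values < 0):
        n = int(np.sum(values < 0))
        logger.warning("%s: clamped %d negative grid values to 0", path, n)
        values = np.clip(values, 0.0, None)
    return values


def read_grid(path: str | Path, channel: Channel) -> HotspotGrid:
    """Read a hotspot grid from a CCP4/MRC map or the ASCII ``.grd`` dialect.

    The format is chosen by sniffing the file content, not the extension.
    Negative stored values are clamped to zero with a logged warning.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(len(_ASCII_MAGIC))
    if head == _ASCII_MAGIC.encode():
        return _read_ascii_grid(path, channel)
    return _read_ccp4_grid(path, channel)


def _read_ascii_grid(path: Path, channel: Channel) -> HotspotGrid:
    header: dict[str, str] = {}
    values_tokens: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    in_header = True
    for line in lines[1:]:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if in_header:
            key, _, rest = line.partition(" ")
            if key in ("channel", "frame_id", "origin", "spacing", "dims"):
                header[key] = rest.strip()
                continue
            in_header = False
        values_tokens.extend(line.split())
    for required in ("origin", "spacing", "dims"):
        if required not in header:
            raise GridFormatError(f"{path}: missing header field '{required}'")
    try:
        origin = np.array([float(x) for x in header["origin"].split()])
        spacing = float(header["spacing"])
        dims = tuple(int(x) for x in header["dims"].split())
    except ValueError as exc:
        raise GridFormatError(f"{path}: unparseable header value ({exc})") from exc
    if origin.shape != (3,) or len(dims) != 3:
        raise GridFormatError(f"{path}: origin/dims must have 3 components")
    n = dims[0] * dims[1] * dims[2]
    if len(values_tokens) != n:
        raise GridFormatError(
            f"{path}: expected {n} values for dims {dims}, found {len(values_tokens)}"
        )
    flat = np.array([float(t) for t in values_tokens])
    values = flat.reshape(dims, order="F")  # x-fastest
    values = _clamp_negative(values, str(path))
    return HotspotGrid(
        channel=channel,
        origin=origin,
        spacing=spacing,
        values=values,
        frame_id=header.get("frame_id", ""),
    )


def _read_ccp4_grid(path: Path, channel: Channel) -> HotspotGrid:
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on bad files
        raise GridFormatError(f"{path}: not a readable CCP4/MRC map ({exc})") from exc
    grid = ccp4.grid
    cell = grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3 and abs(cell.gamma - 90) < 1e-3):
        raise UnsupportedGeometryError(f"{path}: non-orthogonal cell")
    steps = (cell.a / grid.nu, cell.b / grid.nv, cell.c / grid.nw)
    if max(steps) - min(steps) > 1e-4:
        raise UnsupportedGeometryError(
            f"{path}: non-cubic voxels {steps}; only cubic voxels are supported"
        )
    spacing = float(steps[0])
    origin = np.array(
        [ccp4.header_float(50), ccp4.header_float(51), ccp4.header_float(52)]
    )
    values = np.array(grid, copy=True).astype(float)
    values = _clamp_negative(values, str(path))
    return HotspotGrid(
        channel=channel, origin=origin, spacing=spacing, values=values, frame_id=""
    )


def write_grid(grid: HotspotGrid, path: str | Path, fmt: str | None = None) -> Path:
    """Write a grid as ``.grd`` ASCII or CCP4 map (chosen by ``fmt`` or suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "ccp4" if path.suffix.lower() in (".ccp4", ".mrc", ".map") else "ascii"
    if fmt == "ascii":
        _write_ascii_grid(grid, path)
    elif fmt == "ccp4":
        _write_ccp4_grid(grid, path)
    else:
        raise ValueError(f"unknown grid format {fmt!r}")
    return path


def _write_ascii_grid(grid: HotspotGrid, path: Path) -> None:
    nx, ny, nz = grid.values.shape
    with open(path, "w") as fh:
        fh.write(f"{_ASCII_MAGIC}\n")
        fh.write(f"channel {grid.channel}\n")
        if grid.frame_id:
            fh.write(f"frame_id {grid.frame_id}\n")
        fh.write(f"origin {grid.origin[0]:.9g} {grid.origin[1]:.9g} {grid.origin[2]:.9g}\n")
        fh.write(f"spacing {grid.spacing:.9g}\n")
        fh.write(f"dims {nx} {ny} {nz}\n")
        flat = grid.values.ravel(order="F")
        for start in range(0, flat.size, 8):
            fh.write(" ".join(f"{v:.9g}" for v in flat[start : start + 8]) + "\n")


def _write_ccp4_grid(grid: HotspotGrid, path: Path) -> None:
    nx, ny, nz = grid.values.shape
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    ccp4.grid.unit_cell = gemmi.UnitCell(
        nx * grid.spacing, ny * grid.spacing, nz * grid.spacing, 90, 90, 90
    )
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header(2, True)
    for word, val in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Pharmacophoric point SDF I/O
# ---------------------------------------------------------------------------


def write_points_sdf(points: Sequence[PharmacophoricPoint], path: str | Path) -> Path:
    """Write pharmacophoric points as single-atom SDF records.

    Acceptors become O atoms, donors N atoms; the PTYPE data field is the
    authoritative type annotation.
    """
    if not points:
        raise EmptyInputError("cannot write an empty pharmacophoric point list")
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for pt in points:
            mol = Chem.RWMol()
            idx = mol.AddAtom(Chem.Atom(PTYPE_TO_ELEMENT[pt.ptype]))
            conf = Chem.Conformer(1)
            conf.SetAtomPosition(idx, Point3D(*map(float, pt.position)))
            mol.AddConformer(conf)
            out = mol.GetMol()
            out.SetProp("PTYPE", pt.ptype)
            out.SetProp("CLUSTER_SIZE", str(pt.cluster_size))
            out.SetProp("SOURCE", pt.source)
            # mol-block coordinates carry only 4 decimals; this field is the
            # authoritative full-precision position
            out.SetProp("POSITION", " ".join(f"{x:.9g}" for x in pt.position))
            writer.write(out)
    finally:
        writer.close()
    return path


def read_points_sdf(path: str | Path) -> list[PharmacophoricPoint]:
    """Read pharmacophoric points written by :func:`write_points_sdf` or a
    user-edited lattice file (element convention fallback when PTYPE absent)."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    points: list[PharmacophoricPoint] = []
    for mol in supplier:
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        conf = mol.GetConformer()
        for atom in mol.GetAtoms():
            pos = conf.GetAtomPosition(atom.GetIdx())
            if mol.GetNumAtoms() == 1 and mol.HasProp("PTYPE"):
                ptype = mol.GetProp("PTYPE")
            else:
                ptype = ELEMENT_TO_PTYPE.get(atom.GetSymbol())
            if ptype is None:
                continue  # lattice placeholder atoms, etc.
            source = mol.GetProp("SOURCE") if mol.HasProp("SOURCE") else "manual"
            size = int(mol.GetProp("CLUSTER_SIZE")) if mol.HasProp("CLUSTER_SIZE") else 0
            if mol.GetNumAtoms() == 1 and mol.HasProp("POSITION"):
                position = np.array([float(x) for x in mol.GetProp("POSITION").split()])
            else:
                position = np.array([pos.x, pos.y, pos.z])
            points.append(
                PharmacophoricPoint(
                    ptype=ptype,  # type: ignore[arg-type]
                    position=position,
                    cluster_size=size if source == "fhm" else 0,
                    source=source,  # type: ignore[arg-type]
                )
            )
    return points


# ---------------------------------------------------------------------------
# Synthetic pocket fixtures
# ---------------------------------------------------------------------------


@dataclass
class PlantedBlob:
    """Ground truth for one planted polar hotspot blob."""

    center: np.ndarray
    channel: Channel


def make_synthetic_pocket(
    seed: int,
    n_blobs: int,
    exit_pos: Sequence[float],
    spacing: float = 0.5,
    box_half_extent: float = 8.0,
    apolar_peak: float = 5.0,
    apolar_sigma: float = 3.4,
    blob_peak: float = 25.0,
    blob_sigma: float = 0.8,
    blob_radius_range: tuple[float, float] = (1.5, 5.0),
    min_blob_separation: float = 3.0,
    frame_id: str = "synthetic",
    avoid_coords: np.ndarray | None = None,
    avoid_margin: float = 0.5,
) -> tuple[dict[str, HotspotGrid], list[PlantedBlob]]:
    """Generate a pocket-shaped synthetic hotspot map with planted polar blobs.

    The apolar channel is a broad Gaussian envelope (peak 5, sigma 3.4 Å)
    centred on ``exit_pos``, so the above-threshold (>1) region spans a pocket
    roughly 12 Å across. Each planted blob is a sharp Gaussian (peak 25,
    sigma 0.8 Å) on the donor or acceptor channel, centred 1.5-5 Å from the
    exit position; blob centres are kept >= ``min_blob_separation`` apart so
    that downstream clustering resolves them individually. Deterministic per
    seed.

    ``avoid_coords`` (e.g. the non-exit fragment atom positions) rejects blob
    centres that sit closer to any of those positions than to the exit (plus
    ``avoid_margin``), so planted blobs survive the exit-proximity filter of
    the processing stage.

    Returns a dict with keys ``apolar``/``donor``/``acceptor`` and the list of
    planted blob ground truths.
    """
    if n_blobs < 0:
        raise ValueError("n_blobs must be >= 0")
    rng = np.random.default_rng(seed)
    exit_pos = np.asarray(exit_pos, dtype=float)
    origin = exit_pos - box_half_extent
    n = int(round(2 * box_half_extent / spacing))
    ax = origin[0] + spacing * np.arange(n)
    ay = origin[1] + spacing * np.arange(n)
    az = origin[2] + spacing * np.arange(n)
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    coords = np.stack([gx, gy, gz], axis=-1)

    d2_exit = np.sum((coords - exit_pos) ** 2, axis=-1)
    apolar_vals = apolar_peak * np.exp(-d2_exit / (2 * apolar_sigma**2))

    # sample well-separated blob centres in the 1.5-5 Å shell around the exit
    avoid = None if avoid_coords is None else np.asarray(avoid_coords, dtype=float)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_blobs:
        attempts += 1
        if attempts > 100000:
            raise ValueError("could not place blobs; relax the avoid constraints")
        vec = rng.normal(size=3)
        vec /= np.linalg.norm(vec)
        radius = rng.uniform(*blob_radius_range)
        cand = exit_pos + radius * vec
        if any(np.linalg.norm(cand - c) < min_blob_separation for c in centers):
            continue
        if avoid is not None and len(avoid) > 0:
            if np.min(np.linalg.norm(avoid - cand, axis=1)) < radius + avoid_margin:
                continue
        centers.append(cand)
    channels_for_blobs = [
        ("donor", "acceptor")[int(rng.integers(2))] for _ in range(n_blobs)
    ]

    polar_vals = {"donor": np.zeros_like(apolar_vals), "acceptor": np.zeros_like(apolar_vals)}
    blobs: list[PlantedBlob] = []
    for center, ch in zip(centers, channels_for_blobs):
        d2 = np.sum((coords - center) ** 2, axis=-1)
        polar_vals[ch] += blob_peak * np.exp(-d2 / (2 * blob_sigma**2))
        blobs.append(PlantedBlob(center=center, channel=ch))

    grids = {
        "apolar": HotspotGrid("apolar", origin, spacing, apolar_vals, frame_id),
        "donor": HotspotGrid("donor", origin, spacing, polar_vals["donor"], frame_id),
        "acceptor": HotspotGrid("acceptor", origin, spacing, polar_vals["acceptor"], frame_id),
    }
    return grids, blobs
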