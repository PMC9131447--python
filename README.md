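# strife

Structure-informed fragment elaboration: turn fragment hotspot maps into
pharmacophoric target points, generate fragment elaborations with a
profile-conditioned graph generative model, pose and score them against the
pocket, and rank the results by ligand efficiency.

The package is self-contained: it ships a NumPy generative model (no deep
learning framework required), a surrogate posing/scoring backend, synthetic
data generators for end-to-end testing, and a command-line interface.

## Quickstart (Python API)

```python
import numpy as np
from strife import FragmentSpec, make_synthetic_pocket
from strife.datasets import synthetic_training_smiles
from strife.elaborator import enumerate_pairs, train
from strife.pipeline import run_strife

# 1. Train the elaboration model on (fragment, elaboration) pairs
pairs = [p for s in synthetic_training_smiles(0, n=150) for p in enumerate_pairs(s)]
model = train(pairs)

# 2. A fragment with a marked exit vector, embedded in 3D
frag = FragmentSpec.from_smiles("[*]C(=O)NC(C)C").embed(seed=3)

# 3. Hotspot grids (here: a synthetic pocket with a planted polar blob)
avoid = np.delete(frag.coords, frag.exit_atom, axis=0)
grids, blobs = make_synthetic_pocket(
    seed=1, n_blobs=1, exit_pos=frag.exit_pos, avoid_coords=avoid
)

# 4. Full pipeline: points -> explore -> refine -> rank
result = run_strife(frag, model, grids=grids, seed=1, out_dir="out")
for r in result.all_ranked[:5]:
    print(r.rank, r.smiles, f"{r.ligand_efficiency:.3f}")
```

`run_strife` writes `ranked.csv`, `ranked.sdf`, `points.sdf` and
`run_log.json` to `out_dir`. Runs are byte-for-byte reproducible for a given
seed.

## Command-line interface

```bash
# Train a model (on your SMILES file, or the built-in synthetic corpus)
strife train --smiles mols.smi --out model.npz
strife train --n-synthetic 150 --seed 0 --out model.npz

# Extract pharmacophoric points from hotspot grids
strife hotspots --grids grids/ --fragment frag.sdf --exit-atom 0 --out points.sdf

# Generate a manual-specification lattice for user-selected points
strife lattice --fragment "[*]CC" --extent 5 --spacing 1 --out lattice.sdf

# Full run (grids and/or manually curated points)
strife run --grids grids/ --fragment frag.sdf --exit-atom 0 \
    --model model.npz --n-explore 250 --n-refine 100 --seed 1 --out out/

# Evaluate a set of generated molecules
strife eval --generated gen.smi --fragment "[*]c1ccccc1" --out report.json
```

Grid directories must contain `apolar.*`, `donor.*` and `acceptor.*` files in
CCP4 or ASCII `.grd` format (format is sniffed from content, not extension).

## Package layout

| Module | Contents |
| --- | --- |
| `strife.hotspot_io` | Grid/points readers and writers (CCP4 via gemmi, ASCII `.grd`, points SDF), `make_synthetic_pocket` |
| `strife.hotspot_processing` | Thresholding, exit-shell and proximity filters, single-linkage clustering, centroid consolidation, apolar-containment check |
| `strife.pharmacophores` | Donor/acceptor/aromatic perception, coarse and fine structural profiles, manual lattice specification |
| `strife.fragment` | `FragmentSpec`: exit-vector handling, embedding, SDF/SMILES I/O |
| `strife.elaborator` | (fragment, elaboration) pair enumeration, distance → path-length model |
| `strife.genmodel` | Profile-conditioned NumPy generative model (train/sample/save/load) |
| `strife.scoring` | Constrained posing, dihedral pose refinement, surrogate pocket scoring, ligand efficiency |
| `strife.pipeline` | 2D filters (PAINS, SAScore, QED, ring double bonds), quasi-active selection, explore/refine, `run_strife` |
| `strife.metrics` | Validity/uniqueness/novelty/2D-pass rates, ΔQED, standardized ligand-efficiency delta (ΔSLE) |
| `strife.cli` | `strife` command-line entry point |

## Testing

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance tests; the
remaining files cover each module with independently computed oracles.

See `docs/methods.md` for a full description of every pipeline stage.
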