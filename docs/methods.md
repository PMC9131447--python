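# Methods

This document describes every stage of the pipeline in the order it runs:
hotspot grids → pharmacophoric points → profile-conditioned generation
(explore → refine) → constrained posing and surrogate scoring →
ligand-efficiency ranking → evaluation metrics.

## 1. Hotspot grid I/O (`strife.hotspot_io`)

Hotspot maps are per-channel scalar grids (`apolar`, `donor`, `acceptor`) on
a regular cubic lattice, typically at 0.5 Å spacing. Two on-disk dialects are
supported and sniffed from file content (never from the extension):

- **CCP4/MRC** maps, read and written through `gemmi`. The grid origin is
  stored in header floats 50–52.
- **ASCII `.grd`**: a small text header (channel, origin, spacing, shape)
  followed by whitespace-separated values in C order. Floats are written with
  `%.9g` so that float32-representable grids round-trip to within 1e-6.

Grid values must be non-negative; negative values raise `GridFormatError`,
as do malformed headers or wrong value counts.

Pharmacophoric points are exchanged as SDF files of single-atom records
(N for donor, O for acceptor, C for apolar) with `TYPE`, `CLUSTER_SIZE` and
`SOURCE` properties. Because mol-block coordinates carry only four decimals,
each record also stores an authoritative `POSITION` property at `%.9g`,
which the reader prefers; this gives 1e-6 round-trip fidelity.

`make_synthetic_pocket` builds a test pocket: a broad apolar Gaussian
envelope (peak 5, σ 3.4 Å) plus `n_blobs` sharp polar blobs (peak 25,
σ 0.8 Å) planted 1.5–5 Å from a supplied exit position with ≥3 Å mutual
separation. Optional `avoid_coords`/`avoid_margin` reject blob centers that
fall too close to other (non-exit) fragment atoms, so that planted blobs
survive the proximity filter of stage 2. It returns the grids and the ground
truth blob list.

## 2. Hotspot processing (`strife.hotspot_processing`)

Given the three grids and an embedded fragment (`FragmentSpec`), points are
extracted per channel:

1. **Thresholding.** Voxels with value > 1 (apolar) or > 10 (donor/acceptor)
   are kept; all others are discarded.
2. **Exit shell.** Polar voxels must lie within [1.5, 5] Å (inclusive) of the
   fragment's exit-vector position.
3. **Proximity filter.** A voxel closer to any *other* fragment heavy atom
   than to the exit position is removed (ties kept).
4. **Clustering.** Surviving voxels are grouped by single-linkage clustering
   at 1 Å — equivalently, connected components of the ≤1 Å adjacency graph.
5. **Consolidation.** While any two cluster centroids lie < 1.5 Å apart, the
   closest such pair is found and the *smaller* cluster deleted (ties delete
   the later-indexed cluster). Centroids are never recomputed after
   deletions.
6. **Size filter.** Clusters with ≥ 8 voxels are kept; if none qualify, all
   survivors are retained instead.
7. Each remaining cluster becomes one `PharmacophoricPoint` at its centroid,
   annotated with channel and cluster size.

Before extraction, the fragment must be **contained** in the thresholded
apolar envelope: every heavy atom within one voxel spacing of an apolar
voxel. Failure raises `FragmentUnsuitableError`, overridable with
`override_containment=True`.

Manual specification is supported via a cubic lattice of selectable points
(`strife lattice`): carbon placeholders written around the exit vector, which
the user retypes to N (donor) or O (acceptor) in any SDF editor; carbon
records are ignored on read-back.

## 3. Structural profiles (`strife.pharmacophores`)

Pharmacophore perception uses SMARTS:

- donors: `[#7;!H0;+0]`, `[#8;!H0;+0]`
- acceptors: `[OX2;+0]`, `[OX1;+0]`, `[nX2;+0]`, `[NX1;+0]`, `[NX2;+0]`, and
  `[NX3]` excluding amide/sulfonamide nitrogens
- aromatic: aromatic ring atoms

Note that hydroxyls and primary/secondary amines are both donors *and*
acceptors under this scheme.

A **coarse profile** `(n_acceptors, n_donors, n_aromatic)` counts, within the
elaboration atoms only, how many pharmacophores of each class are present
(capped per class). A **fine profile** additionally records the
graph path length from the attachment atom to each pharmacophoric atom,
giving `(type, distance)` pairs. Profiles of quasi-actives (stage 5) condition
the refine generation round.

## 4. Generative model (`strife.genmodel`, `strife.elaborator`)

### Training pairs

`enumerate_pairs` cuts each training molecule at every acyclic single bond
that is not in a ring and not part of an amide; the larger side becomes the
fragment, the smaller the elaboration (ties produce both orientations).
Elaborations are stored as dummy-marked SMILES (`[*]…`).

### Model

The model is implemented directly in NumPy (no deep-learning framework):

- a **fixed random message-passing encoder** (K = 12 rounds, hidden size 32)
  embeds the fragment graph and the partial elaboration;
- **trained softmax heads** (hand-coded gradients, SGD with momentum 0.9,
  learning rate 0.1, 25 epochs, batch size 256) predict the next token.

The token grammar covers chain atoms `C, N, O, F, S`, a carbonyl token
`O=`, and a 6-membered aromatic-ring token that can carry up to two
non-adjacent ring nitrogens. Sampling is autoregressive with a per-step
**profile-feasibility mask**: tokens that would make the requested coarse
profile unreachable within the remaining length budget are excluded. Every
sample therefore contains the fragment as a substructure and respects the
length cap. Training requires a minimum number of pairs
(`TooFewPairsError` otherwise); models save/load as `.npz`.

### Length budget

A small SVR maps exit-to-point Euclidean distance to the expected shortest
path length *p* (trained on synthetic geometry data); generation is capped at
`p + 4` atoms of headroom.

## 5. Explore → refine (`strife.pipeline`)

For each pharmacophoric point (or all points jointly with `multi=True`):

**Explore.** `n_explore` (default 250) elaborations are sampled under
single-pharmacophore coarse profiles matching the point type. Candidates pass
the 2D filters (below), are posed with the fragment constrained (stage 6),
and are measured by `min_pharm_distance` — the distance from the point to the
nearest matching-type pharmacophore of the posed elaboration. Candidates
within 1.5 Å qualify as **quasi-actives**; the closest 5 are kept.

**Refine.** The fine profiles of the quasi-actives condition a second,
focused round of `n_refine` (default 100) samples — either sampling across
the profiles (`sampled`) or a fixed number per profile (`per_profile`).
Refined candidates are 2D-filtered, posed, scored, deduplicated by canonical
SMILES, and ranked.

### 2D filters

Applied before any posing (only passing molecules are posed):

- **validity**: RDKit-parseable, contains the fragment;
- **ring double bond**: non-aromatic double bonds inside rings are rejected;
- **PAINS**: RDKit FilterCatalog PAINS families;
- **SAScore**: elaborated molecules whose synthetic-accessibility score is
  strictly greater than the fragment's are rejected (the rule is
  fragment-relative);
- **QED** (refine stage): elaborations must not fall below the fragment QED
  threshold; equality passes.

### Ranking

Each survivor's surrogate score is divided by its heavy-atom count to give a
**ligand efficiency** (more negative = better); molecules are ranked
ascending by ligand efficiency with canonical SMILES as the deterministic
tiebreak. `run_strife` writes `ranked.csv` (floats formatted `%.6f`),
`ranked.sdf` with poses, `points.sdf`, and `run_log.json`; identical seeds
give byte-identical outputs.

## 6. Posing and scoring (`strife.scoring`)

**Constrained posing.** Each candidate is embedded with ETKDG while the
fragment atoms are pinned to their input coordinates (coordinate-map
constraint, post-embedding alignment check: fragment RMSD ≤ 0.5 Å).
`n_poses` (default 10) conformers are generated per molecule.

**Dihedral refinement.** Each pose is refined by a greedy rigid-rotor scan:
every acyclic single bond whose rotating side lies entirely in the
elaboration is swept in 30° steps (two passes), minimizing the summed
distance from each target point to the nearest matching-type pharmacophore.
The fragment never moves; the procedure is deterministic. This stands in for
the pose optimization a docking program would perform.

**Surrogate score.** For a pose, the score is

```
-(w_contact · n_contained  +  w_pharm · Σ pharmacophore reward)  +  w_clash · n_outside
```

where `n_contained`/`n_outside` count elaboration heavy atoms inside/outside
the thresholded apolar envelope (tolerance = one voxel spacing) and the
pharmacophore reward decays with the distance between each target point and
its best matching pharmacophore (maximal, `w_pharm`, at exact coincidence).
More negative is better. `SurrogateBackend` bundles pocket, targets and
weights; `ExternalCommandBackend` documents the contract for wiring in a real
constrained-docking program.

## 7. Evaluation metrics (`strife.metrics`)

For a generated set against its fragment and (optionally) the training
elaborations:

- **validity**: parseable, contains the fragment, and is not the bare
  fragment;
- **uniqueness**: unique canonical SMILES among valid molecules;
- **novelty**: valid elaborations absent from the training elaboration set;
- **pass_2d**: fraction passing the stage-5 2D filters;
- **ΔQED**: mean QED(molecule) − QED(fragment) over valid molecules.

### ΔSLE (standardized ligand-efficiency delta)

For each example, the model ligand efficiencies are standardized to mean 0 /
sample SD 1 (SD with `ddof=1`, computed on the model values only), and the
ground-truth ligand efficiency is transformed with the same parameters. The
top-α model values (most negative first; α > n falls back to all n) are
averaged and the standardized ground truth subtracted:

```
ΔSLE = mean_examples( mean(top-α standardized LEs) − standardized GT LE )
```

Worked example — LEs {−2, −1, 0}, GT −1: standardized {−1, 0, 1}, GT 0;
α = 3 → ΔSLE = 0; α = 1 → ΔSLE = −1. Raw ΔSLE is negative when the model's
top candidates are *better* (more negative) than the ground truth;
`better_positive=True` negates the result for a larger-is-better reading.
Examples with fewer than two ligand efficiencies or zero variance are skipped
with a warning; if none remain, `EmptyInputError` is raised.

## Determinism and reproducibility

All stochastic components (embedding, sampling, synthetic data, posing) take
explicit seeds; `run_strife` derives per-stage seeds from its single `seed`
argument. Repeated runs with the same seed produce byte-identical
`ranked.csv` files. `scripts/acceptance.py --seed <int> --out <json>`
reproduces the headline quantities end to end.
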