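# stncoalign

Electrode–STN co-alignment from microelectrode recordings (MER).

During deep-brain-stimulation surgery, up to five parallel microelectrodes
(a "Ben-gun" cross at 2 mm spacing) advance in 0.5 mm steps through the
subthalamic nucleus (STN) while recording extracellular activity. This
package reconciles the electrophysiological picture with the MRI-derived
STN surface:

1. **NRMS features** (`mer_signal`) — per-depth root-mean-square amplitude,
   normalised by a pre-STN baseline so background ≈ 1 and STN ≫ 1.
2. **Depth classification** (`mer_classifier`) — a threshold baseline and a
   small attention-based sequence encoder (pure numpy, trains on CPU in
   seconds) label each depth inside/outside STN with bidirectional context.
3. **Co-alignment** (`coalign`) — estimates a rigid electrode shift
   `s` (‖s‖ ≤ 3 mm) and an isotropic mesh scale `α ∈ [0.8, 1.2]` by
   minimising, with Powell's method, the mean surface-distance-weighted
   disagreement between depth labels and mesh inclusion:
   `C(s, α) = (1/N) Σᵢ 1[yᵢ ≠ yᵢ*] · d(xᵢ − s, αM)`.
   No rotation: electrodes are translated, the mesh is scaled.
4. **Geometry** (`geometry`, `mesh_io`) — watertight triangle meshes with
   winding-number inclusion, exact point-to-triangle distances (numba
   kernels), isotropic scaling, volume/centroid; STL (ASCII + binary),
   PLY and legacy-VTK I/O.
5. **Shape model** (`shape_model`) — PCA over vertex-corresponded meshes:
   fit, decode (weights → mesh), encode.
6. **Metrics** (`metrics`) — fraction of STN-labelled sites inside the
   mesh, total-least-squares trajectory fitting, mean perpendicular
   (lateral) distance between trajectories, Dice overlap via voxelisation.
7. **Synthetic scenes** (`synthetic`) — seeded generators for STN-like
   meshes (~6 mm mediolateral), Ben-gun trajectories, raw MER signals
   (24 kHz, 500–5000 Hz band-pass), and fully specified ground-truth
   scenes with injected shift/scale perturbations and label noise, so the
   whole pipeline is testable without clinical data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (geometric oracle
equivalence, 50-scene parameter-recovery protocol, classifier sanity);
the recovery protocol takes several minutes.

## CLI

```sh
# generate a synthetic scene with a known perturbation
stn-coalign simulate --seed 3 --shift 1.0 0.5 -0.5 --scale 1.05 --out scene/

# estimate the correction
stn-coalign coalign --mesh scene/mesh.stl --sites scene/sites.csv \
    --multistart --refine-plateau --out result.json

# train / apply the sequence classifier
stn-coalign train --seed 1 --out model.npz
stn-coalign classify --nrms nrms.csv --method sequence --model model.npz \
    --out predictions.csv

# NRMS from raw segments; full pipeline from YAML config
stn-coalign nrms --raw raw_signals.csv --out nrms.csv
stn-coalign run --config pipeline.yaml
```

Sites CSV columns: `trajectory_id, depth_mm, x, y, z, label` (0-based
indices; depths in signed mm, target = 0, negative above target).
NRMS CSV: `trajectory_id, depth_mm, nrms`. Every pipeline run writes a
`manifest.json` from which it can be re-run byte-identically.

## Conventions

- All coordinates are native-space millimetres (RAS order in files).
- The cost transforms sites as `xᵢ − s`; `apply_coalignment` therefore
  translates electrodes by `−ŝ` and scales the mesh by `α̂` about its
  volume centroid (the scaling centre is an explicit parameter).
- Points on the mesh surface (within 1e-9 mm) count as inside.
- Non-watertight meshes are rejected, never repaired silently.
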