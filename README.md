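# graspsel

A normative model of human two-digit (thumb + index) precision-grip grasp
selection on 3D objects. Given a triangulated mesh with a mass
distribution and a pose, `graspsel`:

1. enumerates **candidate contact points** (accessible triangle centers),
2. computes five per-grasp **penalty maps** over all ordered
   (thumb, index) candidate pairs — force closure, torque, natural grasp
   axis (NGA), grasp aperture, and object visibility — each min–max
   normalized to [0, 1] per object,
3. **combines** them (equal-weight sum, or a weighted sum of squared
   penalties) and **samples predicted optimal grasps** from the low-penalty
   tail (lower 0.1th percentile, selection probability ∝ 1 − penalty),
4. **fits constraint weights** to observed grasps by bounded
   trust-region-reflective least squares (bounds [0, 1], start 0.2),
5. quantifies behavior with a 6D **grasp-similarity metric**
   (`S = 100·(1 − ‖G₁ − G₂‖ / D_max)`), medoids, within/between-subject
   similarity, chance baselines, CoM attraction, and spatial bias, and
6. runs **perturbation sweeps** (mesh subsampling, aperture-threshold
   relaxation, NGA rotation in the transverse/sagittal planes).

No external data are needed: a **polycube builder** regenerates the
10-cube stimulus family (wood cubes 9.7 g, brass 133.5 g; 25 mm edges;
128 triangles per exposed face, or 2 in coarse mode), and a
**synthetic-observer generator** produces grasp data with known
ground-truth weights for parameter-recovery experiments.

## Coordinate convention

Participant frame: **x rightward, y away from the participant, z up**;
the table plane is z = 0; lengths in mm, masses in g. Gravity acts along
−z. The visibility penalty projects onto the horizontal x–y plane. The
default NGA is [0.49, 0.87, 0] (unit-normalized), the default aperture
threshold 25 mm, and the default hand start location (280, 95, 0) mm.

The bundled L/U/S/V polycube layouts (`src/graspsel/layouts/`) are
approximate reconstructions; replace them with your own layout files
(one cube per line: `ix iy iz material`) where exact geometry matters.

## Command line

```sh
# build a polycube and export mesh + mass properties
graspsel build-object --shape L -o L.obj

# five penalty maps + overall map as TSV matrices with JSON sidecars
graspsel penalties --shape L --resolution coarse -o maps/

# sample predicted optimal grasps (deterministic given config + seed)
graspsel predict --shape L --resolution coarse -n 20 --seed 1 -o pred.tsv

# fit constraint weights to an observed grasp table
graspsel fit --shape L --resolution coarse --grasps observed.tsv -o w.json

# behavioral metrics (similarity, chance level, CoM attraction, bias)
graspsel metrics --shape L --resolution coarse --grasps observed.tsv

# perturbation sweep: NGA rotated in the transverse plane
graspsel perturb --shape L --resolution coarse --grasps observed.tsv \
    --kind nga_rotation --plane transverse --levels -90,-45,0,45,90 \
    --seeds 0,1,2 -o sweep.tsv
```

Grasp tables are tab-separated text with columns
`trial_id xT yT zT xI yI zI` (mm). Model configuration is YAML
(`nga_vector`, `aperture_threshold`, `gravity`, `hand_reference_point`,
`table_z`, `squared_combination`); every command logs the config hash
and seed.

## Python API

```python
import graspsel as gs

obj = gs.build_polycube([(i, 0, 0) for i in range(10)])   # 97 g bar
cfg = gs.ModelConfig()
cands = gs.candidate_contacts(obj, cfg.table_z)
maps = gs.compute_penalty_maps(cands, obj, cfg)           # FC, T, NGA, OGA, VIS
overall = gs.combine(maps)                                # equal weights
pred = gs.sample_optimal_grasps(overall, cands, n=20, seed=1)

obs = gs.simulate_observer(maps, gs.WeightVector(0.8, 0.1, 0.5, 0.4, 0.05),
                           cands, n_trials=20, seed=0)
fit = gs.fit_weights(gs.build_fit_problem(maps, obs))
print(fit.weights.relative())
```

## Notes

- Penalty maps are dense n×n arrays (n candidates); a full-resolution
  10-cube object has ≈4000 accessible candidates (≈16M pairs per map).
  Use `--resolution coarse` or `--subsample` for interactive work; the
  visibility map is the most expensive (O(n³) via blocked matmuls).
- Similarity is reported unclamped: because grasp distance lives in 6D
  while `D_max` is a 3D diameter, values can be negative
  (`floor_at_zero=True` clamps).
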