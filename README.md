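# conspace

Standardized tractography and a *common connectivity space*: a desk-scale
toolkit for protocol-constrained probabilistic tractography, population
tract atlases, connectivity blueprints, symmetric-KL divergence mapping,
spectral-embedding atlas translation, and tract-maturation statistics —
exercised end to end on synthetic phantoms with known ground truth.

## What's inside

| Module | Purpose |
| --- | --- |
| `conspace.io_formats` | NIfTI volumes, GIFTI surfaces, TSV label tables, JSON tract-protocol manifests, packaged tract-library metadata (42 protocols when expanded) |
| `conspace.phantom` | Synthetic fiber fields (straight / arc / crossing bundles), icosphere meshes, Dirichlet blueprint generators with controlled group divergence, tensor-based DWI signals |
| `conspace.tracking` | Probabilistic streamline propagation (0.5 mm steps, 80° curvature threshold, 2000 max steps, 1% subsidiary-fiber threshold) with seed/waypoint/exclusion/stop semantics, reverse seeding, and normalized path-density maps |
| `conspace.atlas` | Population-percentage atlases (binarize at 0.1%, average over subjects), cross-atlas correlations, intersubject-variability pair designs |
| `conspace.blueprint` | (cortex × tracts) connectivity blueprints: surface-seeded connectivity × vectorised tract maps, row normalization, group averaging |
| `conspace.divergence` | Symmetric KL divergence in bits, min-divergence maps, parcel-median matrices, joint / exclusive-OR map algebra, row entropy, bootstrap dispersion |
| `conspace.embedding` | Inverse-divergence similarity and normalized-Laplacian spectral embedding with per-system median centers |
| `conspace.maturation` | Log-linear DTI fits (b=1000 shell), tract-median metrics over 30%-thresholded atlases, per-tract age GLMs with Bonferroni correction |
| `conspace.cli` | `bxs` command binding everything with provenance sidecars |

## CLI

Every subcommand writes a `*.provenance.json` sidecar (tool version, seed,
config hash) next to its primary output.

```sh
# generate a straight-bundle phantom with protocols and ground truth
bxs phantom --shape 40,40,40 --seed 7 --out phantom/

# run a tract protocol
bxs track --fractions phantom/fractions.nii.gz \
          --orientations phantom/orientations.nii.gz \
          --protocol phantom/B0/protocol.json \
          --samples 50 --seed 7 --out density.nii.gz

# population atlas from per-subject maps
bxs atlas --maps s1.nii.gz --maps s2.nii.gz --out atlas.nii.gz

# synthetic group blueprints with controlled divergence
bxs blueprint --synthetic --vertices 200 --tracts 11 --group-shift 0.3 \
              --seed 7 --out blueprints/

# divergence matrix / min-divergence map / entropy
bxs divergence minmap --blueprint-a blueprints/group0_mean.tsv \
                      --blueprint-b blueprints/group1_mean.tsv \
                      --out minmap.tsv

# spectral embedding of a parcellated divergence matrix
bxs embed --divergence parc_div.tsv --modes 2 --out embedding.tsv

# tract-wise age GLM
bxs maturation --metrics metrics.tsv --cohort cohort.tsv --out glm.tsv
```

## Conventions worth knowing

- All volumes for one protocol must share grid and affine exactly; no
  registration/warping is performed.
- Path-density maps count each streamline once per voxel (binary
  visitation) and are normalized by the number of valid streamlines, so
  thresholds like 0.1% read as visitation probabilities.
- Divergences are in bits (log base 2); zeros are handled by adding a 1e-6
  floor to each row and re-normalizing.
- Joint/XOR divergence map algebra requires both inputs min–max rescaled
  to [0, 1]; the API enforces this explicitly.
- Medians over even counts use the midpoint convention.
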