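# avs3d

A Hubel-Wiesel cascade model of **stereo-orientation selectivity**, and an
artificial visual system (AVS) built on it for recognizing the 3D
orientation of structures in binary voxel volumes.

In the classical Hubel-Wiesel account of the primary visual cortex,
orientation selectivity emerges from a cascade: LGN cells report local
luminance, simple cells fire when those reports line up at a preferred
orientation inside a small receptive field, and complex cells pool
same-orientation simple cells into position-invariant selectivity. This
package transplants that local-to-global aggregation scheme to volumetric
space:

* **depth-selective cells** report voxel occupancy, `d = v ∈ {0, 1}`;
* **simple stereo-orientation cells** combine three depth cells forming a
  centered collinear triple inside a 3×3×3 local space,

  `s = 1 / (1 + exp(−k (Σᵢ dᵢ − θ)))`,  default `k = 10⁴`, `θ = 2.5`,

  so `s ≈ 1` exactly when the full triple is occupied;
* **complex stereo-orientation cells** sum all same-orientation simple
  cells over the volume, `c = Σᵢ sᵢ`, and the largest of the 13 complex
  responses names the global orientation.

Exactly **13** line orientations pass through the center of a 3×3×3
neighborhood (the 26 neighbors pair antipodally: 3 axes, 6 face
diagonals, 4 body diagonals), so the whole model has
13 × 27 + 2 = **353 parameters** — a 27-entry connection mask per simple
cell type plus the shared `k` and `θ`.

The same machinery doubles as a noise filter for voxelized point clouds:
an occupied element whose local space contains **no** oriented triple is
isolated background noise and can be discarded, while object structure —
which is spatially contiguous and therefore rich in local orientation
fragments — is preserved.

The package is aimed at computational-neuroscience and 3D-vision work:
it includes the physiological stimulus protocols (drifting gratings,
random-dot volumes with embedded motion fragments), a seeded oriented
line/bar benchmark generator with background-noise injection, the
positive/negative information filter with its rule variants, random and
farthest-point subsampling, and an evaluation harness with a CLI.

## Worked example

A length-5 thickness-1 segment along the face diagonal `(0, 1, 1)` in a
16³ volume:

```python
import json
from avs3d import VoxelGrid, classify, inject_noise, separate

grid = VoxelGrid.from_coords([(3, 4 + i, 6 + i) for i in range(5)], dims=(16, 16, 16))
print(json.dumps(classify(grid).to_dict()))
```

```
{"responses": [4.93e-304, ..., 3.0, ..., 4.93e-304], "predicted": 8, "n_centers": 5}
```

Template 8 is the `(0, 1, 1)` face diagonal; its complex cell reports
3.0 — the three interior voxels of the segment, each the center of one
occupied triple (a length-L segment always scores L − 2) — while the
other 12 cells emit only sub-1e-300 sigmoid dust. Adding 2% background
noise and filtering:

```python
noisy = inject_noise(grid, 2.0, seed=0)          # +82 random voxels
positive, negative = separate(noisy)
print(noisy.n_occupied, positive.n_occupied, negative.n_occupied)
print(classify(noisy).predicted_orientation)
```

```
87 4 83
8
```

Of 87 occupied voxels, the filter keeps 4 as positive (the 3 segment
interior voxels plus one noise voxel that happened to complete a triple)
and discards 83; classification still returns orientation 8.

The same operations are available from the shell:

```bash
avs recognize object.npy                       # JSON response record
avs filter cloud.ply --out kept.ply --rule any --sampler fps --n-points 64 --seed 0
avs generate objects --out data/ --seed 0      # benchmark dataset
avs evaluate --dataset data/ --seed 0          # clean + noise accuracy table
avs simulate-gratings --out trace.csv          # drift-grating response trace
```

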