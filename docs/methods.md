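# Methods

## Model

The system is a feed-forward cascade over a binary occupancy volume
`V ∈ {0,1}^(nx×ny×nz)` with three cell types.

**Depth-selective cells.** `d = v_index`: the cell fires (1) iff the
spatial element at its position exists. This is the idealized endpoint
of the biological depth pathway — occupancy stands in for whatever
mid-level machinery established that a surface element is present at
that position in depth. Coordinates outside the volume read as 0.

**Simple stereo-orientation cells.** Each of the 13 cell types is wired
to the three depth cells of one centered collinear triple
`{p − u, p, p + u}` in the 3×3×3 local space around an element `p`, and
responds `s = σ(k (Σ dᵢ − θ))` with sensitivity `k = 10⁴` and threshold
`θ = 2.5`. Because the depth inputs are binary, their sum is an integer
that can never equal θ, so at the default sensitivity the sigmoid is an
exact step function to within 10⁻¹⁰: the cell fires iff all three
positions of its triple are occupied. The sigmoid (rather than a hard
step) keeps the unit differentiable and lets users soften the gate by
lowering `k`; the exponent is clamped to ±700 before exponentiation so
the default `k` cannot overflow float64.

**Complex stereo-orientation cells.** One per orientation; each sums all
same-orientation simple cells across every local space in the volume,
`c_o = Σ s`. The argmax over the 13 complex responses is the reported
global orientation.

**Template geometry.** The 26 non-center positions of a 3×3×3
neighborhood pair antipodally into 13 directions: 3 axes, 6 face
diagonals, 4 body diagonals. Each direction's canonical representative
is the lexicographically larger of `{u, −u}`; templates are ordered
axes → face diagonals → body diagonals (lexicographically descending
within a class), giving ids 1–13. Positions within a local space are
indexed `v = 1 + (x+1) + 3(y+1) + 9(z+1)` for offsets in `{−1,0,1}³`
(x fastest), so the center is v14. Any fixed bijection would do — the
templates are defined geometrically — this one is documented so that
exported tables are stable.

**Parameter count.** Under the dense-mask convention each simple-cell
type is a 27-entry binary connection mask over its local space (three
ones selecting the triple), and `k`, `θ` are shared: 13 × 27 + 2 = 353
scalars. Nothing is learned; the count is the model's description
length, not a training budget.

## Recognition pipeline

Patch centers are the occupied voxels only. This is equivalent to
scanning all positions: an unoccupied center caps the depth sum at
2 < θ, so its simple activations are ≈ 0 (exactly < 0.5 for any k > 0)
and contribute nothing to any complex cell. The implementation
vectorizes the scan as two zero-padded array shifts per orientation
(`V(p−u) + V(p+u)` evaluated at occupied `p`), which reproduces the
per-patch definition to 10⁻⁶ against brute-force triple counting and
runs in ~1 ms for a 16³ volume.

Decisions and degenerate inputs:

* **Ties** in the argmax go to the lowest template id, and the full
  13-vector is always returned so callers can apply their own policy.
* **Featureless volumes** (all 13 responses < 0.5 — empty input,
  isolated voxels) return a distinct NONE sentinel rather than
  orientation 1. On the object benchmark NONE counts as incorrect.
* **Trace normalization** divides each complex cell's series by its own
  maximum over the trace; a cell whose maximum is below 10⁻⁹ is treated
  as silent and left at zero. The tolerance matters: inactive cells emit
  sub-10⁻³⁰⁰ sigmoid dust, and dividing such a series by its own dust
  maximum would fabricate full-scale activation. Any genuinely active
  cell contains at least one activation ≥ 0.5, nine orders of magnitude
  above the cut.

## Feature/noise separation

Each occupied element is labeled positive iff its active-orientation
count `m` (number of simple-cell types above 0.5 at that center)
satisfies the rule: `any` (m ≥ 1, the default), `single` (m = 1),
`multi` (2–12) or `all` (m = 13). All counts are computed against the
original volume before any removal — elements are judged independently,
not iteratively. With the default sharp sigmoid the 0.5 activity cut is
arbitrary within (0.1, 0.9). The partition {m = 0, single, multi, all}
is exhaustive and disjoint, and adding voxels can only raise `m`, so
positives are monotone under occupancy growth.

Subsampling utilities operate on the resulting point clouds: seeded
uniform sampling without replacement, and greedy farthest point
sampling whose first point is a seeded uniform draw and whose ties go to
the lowest point index.

## Stimulus protocols

**Drift gratings** (orientation-tuning probe). A 32×32×1 window with
bars of width 2 repeating every 8 voxels, at 0°/45°/90°/135° in-plane,
drifting 1 voxel/frame along either orthogonal direction; each
100-frame motion block is followed by a 100-frame blank rest block
(4 × 2 × 200 = 1600 frames, 800 grating + 800 blank). Bar width 2 makes
the selectivity exact: only the along-bar template ever completes a
triple, for all four orientations (width ≥ 3 would co-activate
perpendicular templates). Window size and spatial frequency are
config-exposed; the defaults are chosen so the period divides the
window, making consecutive motion frames exact 1-voxel cyclic shifts.
Diagonal stripes are clipped by the window boundary, so the preferred
cell's raw response varies a few percent with phase (normalized ≥ 0.987
rather than exactly 1).

**Random-dot volumes** (sensitivity to embedded fragments). 300 dots
placed uniformly without replacement in a 32³ volume (~0.9% occupancy);
0–5 "moving dots" are each extended one step forward and backward along
a shared direction, creating centered 3-voxel fragments of the sample's
label orientation. Moving dots are drawn among dots whose full triple
fits inside the volume. At this density accidental triples are rare
(≈ 0.3 expected per sample), so accuracy rises steeply with the number
of embedded fragments. When no fragment is embedded the label is still
drawn uniformly and a silent output is resolved by a seeded uniform
guess — the zero-fragment condition therefore measures chance level
(≈ 1/13), which is how the published curve behaves at zero. The object
benchmark does **not** guess: there NONE is simply wrong.

**Oriented line/bar objects** (recognition benchmark). 13 classes (the
canonical directions) in a 16³ volume; lengths uniform on {3,…,9};
diagonal classes are thickness-1 lines, axis classes draw thickness 1
(line) or 2 (2×2-section bar) uniformly. Splits are class-balanced at
15,600 / 5,200 / 5,200 samples, stored as a manifest of per-sample
seeds from which every volume regenerates bit-for-bit. Background noise
at intensity i% sets `round(i/100 × total voxels)` uniformly chosen
empty voxels to 1, never touching object voxels: intensity is a
percentage of the **total** volume voxel count, the simplest reading,
and is config-exposed.

## What the generators do and do not emulate

The generators produce exactly the geometry the model is defined on:
binary, axis-aligned, noise-free-or-uniform-noise volumes whose objects
are straight runs along the 13 canonical directions. Passing tests
therefore certify the cascade's selectivity, invariances and noise
behavior under those conditions — they say nothing about curved or
oblique structures (between canonical directions), graded intensities,
correlated (non-uniform) noise, or real sensor voxelization artifacts.
Clean-data accuracy is 100% *by construction* (a straight run of length
L always scores L − 2 on its own template and ~0 elsewhere); the
informative measurements are the noise curve, the random-dot curve and
the separation behavior.

## Problem sizes and measured behavior

The default test suite runs the full grating protocol (1600 frames),
200 samples per random-dot condition, a 1,300-sample benchmark split
for the clean/noise accuracy checks, and 500 random instances for the
separation property — about 15 s total. `scripts/acceptance.py` uses
the full 5,200-sample test split (~30 s). With the documented noise
model, mean accuracy over 1–5% noise is ≈ 94% and the 5%-noise point is
≈ 86%: at 5% density the expected number of accidental noise triples is
≈ 0.5 per orientation (4096 × 0.05³), so the error budget concentrates
on the shortest thickness-1 objects (L = 3, 4, true response 1–2),
which noise can out-vote. Longer objects and thickness-2 bars are
essentially never misclassified.

## Known limitations

* Orientation is categorical over 13 directions; no sub-voxel or
  continuous-angle estimation, and no multi-orientation scene parsing —
  one global argmax per volume.
* The receptive field is fixed at 3×3×3; structure at other scales is
  seen only through its local 3-voxel fragments.
* The separation rule weighs all positive elements equally; it does not
  rank elements by how much orientation information they carry.
* Depth responses are binary: no graded occupancy, color or intensity
  channels.
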