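# Methods

## Model and assumptions

The detector treats a dataset as a Euclidean point cloud whose normal
points form clusters — possibly of very different densities — and whose
outliers are points that no cluster absorbs. Everything is derived from
one exact minimum spanning tree (MST) of the full dataset:

* **Termination threshold** `T_t = mean + spread` of the `N − 1` MST edge
  weights. `T_t` acts as a global noise scale; edges well above it only
  occur between clusters or out to isolated points.
* **Threshold-scaled distance** `ted = d / T_t`. Dividing by a common
  positive constant preserves all distance orderings and makes every
  comparison in the method scale-free: multiplying the coordinates by any
  `c > 0` scales `T_t` by `c` and leaves the labeling unchanged (this is
  asserted by a test).
* **Mini-MST growth.** Prim's algorithm restricted to the not-yet-labeled
  points, using `ted` weights, seeded from the child endpoint of the
  first still-unlabeled edge of the globally sorted edge list. The tree
  keeps the accepted weights in the mini-edge-weight set `MEW`; a
  candidate is admitted while its `ted` does not exceed the adaptive
  exit condition `aec = mean(MEW) + spread(MEW)`, evaluated on the MEW
  the candidate is about to enter. Admission on exact equality matters:
  it is what lets a perfectly regular (fully tied) cluster be absorbed
  whole.
* **Cluster size floor.** A tree with fewer than
  `least_number = round(N / n)` edges (half rounds away from zero,
  floored at 1) is an outlier cluster; its members are flagged and stay
  removed from the unlabeled pool.
* **Stopping window.** While walking the sorted global edges, the mean of
  a 6-edge window (the current edge and the next 5) is compared to
  `T_t`; the walk stops once the mean is strictly greater, and every
  never-absorbed point is an outlier. Strictness is deliberate: with
  exactly tied weights (a lattice) every window mean equals `T_t`, and a
  non-strict rule would flag the entire dataset. At the tail the window
  simply averages the edges that remain.

The detector takes no outlier count or fraction; `detect()` and the
estimator expose no such parameter.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `deviation_mode` | `"std"` | spread term of `T_t` and `aec`; population standard deviation (same units as distance). `"sum_squares"` is the literal raw sum of squared deviations — dimensionally a squared distance, retained because the defining formulas can be read either way. |
| `mew1` | `"first_edge"` | first MEW entry; either the first edge's `ted` or a fixed positive value. |
| `window_len` | 6 | edges per stopping window, current edge included. |
| `least_number` | `round(N/n)` | minimum normal-cluster size in edges. |
| `normalize` | off | per-feature min–max scaling to [0, 1]. |
| `drop_duplicates` | off | collapse identical rows; duplicates inherit their representative's label. |
| `root` | 0 | Prim root; `"random"` draws from `random_state`. The MST total weight is root-invariant, and edge ties are broken by smallest point index, so runs are deterministic. |
| `size_rule` | `"ge"` | whether a tree with exactly `least_number` edges is normal. |

### Two defaults need care on continuous low-dimensional data

**`mew1="first_edge"` degenerates on tie-free data.** With one MEW entry
the spread term is zero, so `aec` equals the first edge's `ted`, and any
strictly larger second candidate — i.e. almost every candidate on
continuous data, where Prim proposes weights in roughly increasing
order — terminates the tree at two points. On quantized or normalized
data with many repeated distances the policy behaves well, which is why
it remains the default; for continuous data use a fixed `mew1=1.0` (on
the `ted` scale, 1.0 is the magnitude of `T_t` itself — an upper
bracket for intra-cluster edges).

**`least_number=round(N/n)` assumes many features.** On the benchmark
shapes this floor is far below the normal-class sizes, but in two
dimensions it is `N/2`, larger than any plausible cluster, and every
cluster would be rejected. For low-dimensional scenes the package's
convention is `least_number ≈ round(√N)` (11 for the 121-point canonical
scene), a floor that grows with the dataset but stays below cluster
scale. Both settings are the ones used by every 2-D evaluation in the
test suite and the acceptance script.

## Synthetic scenes

`make_scenario` draws isotropic Gaussian clusters (given centers,
spreads, counts) and plants outliers uniformly over the data bounding
box (plus a 5-unit margin), rejecting candidates within
`clearance × spread` of any cluster center; generation fails loudly if
the rejection cap is hit. The canonical `fig1_default` preset —
40/30/25/20 points with spreads 0.5/1/1.5/2 at the corners of a 40-unit
square, 6 outliers at clearance 5 — realizes the density-ladder scene
the method is designed for: intra-cluster nearest-neighbor distances
increase with spread (asserted), centers are 20× the largest spread
apart, and planted outliers are verifiably remote. `make_appendix_like`
adds five small 2-D morphologies (density contrast, three clusters,
ring, half-moons, exact lattice) with 3–10 planted outliers each; their
sizes and outlier counts are package conventions.

What the generator does *not* emulate: correlated or anisotropic
features, categorical/quantized attributes (and hence the heavy
distance ties of normalized medical tables), overlapping clusters, and
label noise. Passing the synthetic suites therefore demonstrates the
geometric mechanics of the method, not its performance on real medical
corpora.

## Numerical choices

* Exact `O(N²)` Prim on a dense distance matrix (scipy `cdist`); no
  spatial indexing — the package targets desk-scale data (thousands of
  points).
* Candidate ties in Prim and in mini-MST growth break to the smallest
  point index; equal-weight edges keep their insertion order under the
  stable sort. Detection is therefore bit-reproducible for a fixed
  configuration.
* `T_t = 0` (all points identical) is short-circuited to a single
  normal cluster; `ted` would otherwise be undefined.
* Degenerate growth (fewer than two unlabeled points) returns a
  single-point tree with no edges, which the size rule then flags.
* Rounding for reports is 2 decimal places; all internal statistics keep
  full precision.

## Known limitations

* **Rim orphaning.** `aec` is a mean-plus-spread of the weights accepted
  so far, and Prim accepts small weights first, so the largest
  attachment distances of a cluster — its outermost points, beyond
  roughly 2.5σ for a Gaussian cluster — can exceed `aec` and be left
  behind. An orphan is never rescued: its only MST edges lead into the
  labeled cluster, and edges with a labeled endpoint are skipped. The
  practical signature is perfect recall with moderate precision (about
  0.76 on the canonical scenes, roughly two rim points per 121-point
  scene), consistent with the method's published benchmark profile.
* **Masking by extreme points.** One point vastly farther than the data
  diameter inflates `T_t`, shrinking every `ted`; moderate outliers can
  then be absorbed into cluster trees and escape detection. The
  monotone-safety property (adding an extreme point never un-flags an
  existing outlier) holds on compact, tie-structured clusters and is
  tested there, but fails on diffuse Gaussian scenes.
* No outlier scores or ranking — the output is a hard partition — and no
  streaming or approximate-neighbor mode.

## Problem sizes used by the test and acceptance suites

Oracle equivalence uses 100 random instances with `N ≤ 60`, `n ≤ 5`
against scipy's independent MST routine (tolerance 1e-9 relative).
Planted-outlier recovery uses 20 seeded canonical scenes of 121 points.
Everything runs in seconds on one CPU.
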