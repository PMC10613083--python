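# minimst

Unsupervised outlier detection for tabular numeric data — medical cohorts
in particular — built on iteratively grown *mini* minimum spanning trees
(the MMOD method). Its selling point is that it needs **no outlier count,
fraction, or contamination parameter**: the thresholds that separate
clusters from outliers are derived from the data itself, which makes the
detector usable on "black-box" datasets where the outlier proportion is
unknown, and robust on datasets whose clusters have very different
densities.

## The method

Given `N` points in `R^n`:

1. Build one exact Euclidean MST with Prim's algorithm and sort its edges
   by non-decreasing weight. The **termination threshold**

   `T_t = mean(d_i) + std(d_i)`

   over the `N − 1` edge weights `d_i` is a global noise scale for the
   dataset. (A literal raw sum-of-squared-deviations variant of the
   spread term is available as `deviation_mode="sum_squares"`.)

2. Replace the Euclidean distance with the **threshold-scaled distance**
   `ted(x, y) = d(x, y) / T_t`, which is dimensionless and scale-free.

3. Walk the sorted edge list. Each edge whose endpoints are still
   unlabeled seeds a **mini-MST**: a Prim-style tree grown over the
   unlabeled points with `ted` weights. The tree records its accepted
   edge weights in the set `MEW`; a candidate edge whose `ted` exceeds
   the **adaptive exit condition** `aec = mean(MEW) + std(MEW)` stops the
   growth. Trees with at least `least_number = round(N / n)` edges become
   normal clusters; smaller trees are outlier clusters.

4. A sliding window (6 edges by default) runs over the sorted global
   edge weights; once its mean exceeds `T_t` the walk stops and every
   point not absorbed into an accepted cluster is an **outlier**.

Because the densest cluster owns the shortest MST edges, the walk reaches
it first, and clusters are carved out in density order — dense regions
are held to strict exit conditions, sparse ones to lenient ones.

## Worked example

Simulate the canonical scene — four Gaussian clusters of different
densities (40/30/25/20 points, spreads 0.5/1/1.5/2) at the corners of a
40-unit square, plus 6 scattered remote outliers — then detect:

```sh
minimst simulate --preset fig1 --seed 7 --out fig1.csv
minimst -v detect fig1.csv --label-col label --mew1 1.0 --least-number 11 \
        --out labels.csv --report report.json
```

which logs

```
N=121 n=2 T_t=5.17572 least_number=11 mini_msts=4 outliers=7
precision=0.86 recall=1.00 f_measure=0.92 (m=6 returned=7 truth=6)
```

Reading: the MST's edge-weight statistic gave `T_t ≈ 5.18`; four
mini-MSTs were accepted as normal clusters (sizes 40/29/25/20 in the
report); 7 points were flagged, including all 6 planted outliers
(recall 1.00) plus one cluster rim point (precision 0.86). The two
explicit options are the documented settings for continuous 2-D data
(`--mew1 1.0` fixes the initial MEW entry; `--least-number 11 ≈ √N`
replaces `round(N/n)`, which is degenerate in two dimensions — see
`docs/methods.md`).

The same run in Python:

```python
from minimst import MiniMSTOutlierDetector, evaluate
from minimst.synthetic import fig1_default, make_scenario

points = make_scenario(fig1_default(seed=7))
det = MiniMSTOutlierDetector(mew1=1.0, least_number=11)
flags = det.fit_predict(points.coordinates)          # -1 = outlier
report = evaluate(det.detection_result_, points.truth_labels)
print(report.rounded())                              # (0.86, 1.0, 0.92)
```

`MiniMSTOutlierDetector` follows the scikit-learn API (`get_params`,
`clone`, pipelines); fitted attributes include `labels_` (cluster ids,
−1 for outliers), `threshold_` (`T_t`) and `detection_result_` with full
per-tree diagnostics.

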