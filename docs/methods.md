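# Methods

This note documents the statistical procedures, the modeling choices
behind the synthetic data, and the numerical conventions used throughout
`cellconcord`.

## Problem setting

A region of interest (ROI) is a ~2 mm² field of an IHC-stained whole
slide image, ~2150×2150 px at 0.23 µm/px, containing on the order of a
thousand cells of three classes: tumor cells, CD3⁺ T-lymphocytes, and
non-specified stromal cells. Several *sources* (human raters,
semi-automatic software, detectors) each produce an independent list of
cell centers with class labels. No identifiers link the lists: deciding
which cells are "the same cell" is part of the evaluation problem.

## Gated correspondence

Two sets A and B are matched by building the Euclidean distance matrix
between cell centers and solving the minimum-cost one-to-one assignment
(Hungarian algorithm via `scipy.optimize.linear_sum_assignment`). A pair
is only acceptable when its distance is at most the gate g (default
25 px, one average cell radius). Two gating conventions exist:

- **Pre-gating (default):** distances > g are replaced by a forbidden
  cost larger than any achievable in-gate total before solving. The
  solver then returns the matching that first maximizes the number of
  in-gate pairs and, among those, minimizes total distance. This is the
  convention used everywhere downstream.
- **Post-filtering (`pregate=False`):** the ungated global optimum is
  solved first and out-of-gate pairs are dissolved afterwards. This can
  discard pairs that a gate-aware matching would keep (both conventions
  are exposed because the choice is a genuine degree of freedom).

Equal-cost optima are resolved deterministically by the solver;
distances are continuous so exact ties are measure-zero in practice.
Matching is *class-blind*: labels play no role in the assignment, only
in the downstream tallies. Box overlap (IoU) is deliberately not used —
the one-click annotation style makes box extents nominal.

Unit tests verify the matcher against exhaustive enumeration of all
gate-feasible matchings for up to 7 cells per side.

## Extended confusion matrix and kappa variants

A match between sources A (rows) and B (columns) is tallied into a 4×4
matrix over {tumor, CD3⁺, non-specified, missing}: matched pairs land in
the 3×3 core, cells unmatched in A land in the "missing" column, cells
unmatched in B in the "missing" row. The (missing, missing) cell is
structurally zero.

With n_ij the counts, margins n_i·, n_·j, grand total N, joint total
J = Σ_{i,j≤3} n_ij, and t the missing class:

| variant | P_o | P_e |
|---|---|---|
| standard (3×3 core) | Σ n_ii / J | Σ n_i· n_·i / J² |
| regular category | (Σ n_ii + n_tt) / N | (Σ n_i· n_·i + n_t· n_·t) / N² |
| listwise deletion | Σ n_ii / J | Σ (n_i· − n_it)(n_·i − n_ti) / J² |
| Gwet | Σ n_ii / J | Σ n_i· n_·i / ((N − n_t·)(N − n_·t)) |

with κ = (P_o − P_e)/(1 − P_e) in all cases (sums over the three real
classes; regular-category margins include the missing class). Because
n_tt = 0, missingness can only depress the regular-category κ; the gap
between it and listwise deletion isolates cell omission from label
confusion. Degenerate inputs (no cells, no jointly labeled cells,
P_e = 1, a rater with no labels) raise an explicit undefined-statistic
error rather than returning 0.

Interpretation uses the Landis–Koch bands with left-open intervals
(κ ≤ 0.2 slight, ≤ 0.4 fair, ≤ 0.6 moderate, ≤ 0.8 substantial,
≤ 1.0 almost perfect; κ < 0 poor). κ = 0 falls in "slight", a boundary
the original band list leaves formally unassigned.

Multi-ROI aggregation pools confusion counts before computing κ
(micro-averaging); per-ROI output is also available. Pooling was chosen
because a single misclassification on a sparse ROI would otherwise
dominate an average of per-ROI κ values.

## Consensus and the diverse class

The consensus of ≥2 raters keeps every annotated cell (raters are
assumed to rarely hallucinate cells). Cells are clustered by greedy
agglomeration: all cross-rater cell pairs within the gate are visited in
ascending distance order and two clusters merge when no rater
contributes to both *and* every cross-cluster member pair is within the
gate (complete linkage). The cluster label is the strict-plurality vote
of its members; any tie — most commonly support 2 with two distinct
labels, or support 3 with three — yields the **diverse** label.
Support-1 clusters keep their single label. Diverse cells are excluded
from agreement and detection evaluation.

An earlier design folded raters sequentially into the evolving
consensus via gated Hungarian matching; its output depended measurably
(~3% of cells at 5 px click jitter) on the fold order. The
agglomerative rule depends only on cell geometry, not on rater naming
or input order (residual order dependence exists only for exactly tied
distances at exactly coincident positions), and is what ships. Tests
bound the rename sensitivity below 1% of cells.

## Detection scoring

At a score threshold σ, detections with score < σ are discarded,
diverse reference cells and detections matched to them are removed
entirely (neither TP nor FP — the reference offers no usable label
there), and the remainder is matched. Per class c: TP = matched pairs
labeled c on both sides; FN = reference cells of c unmatched or matched
to another predicted class; FP = detections of c unmatched or matched
to another reference class. TP + FN therefore equals the number of
non-diverse reference cells of c at every threshold.

**Average precision.** The default sweep uses the 11 thresholds
σ ∈ {0.0, 0.1, …, 1.0}. Within the sweep, detections are kept when
score > σ strictly: the top threshold then always contributes the
empty-detection anchor (recall 0, precision 1 by the empty-claim
convention), which makes AP = 1 exactly for a perfect detector even
when all scores are exactly 1.0. Points are ordered by increasing
recall (ties by decreasing threshold) and

AP = Σₖ (Recall_{k+1} − Recall_k) · Precision_k,

i.e. each precision is weighted by the recall increase to the next
point. An arbitrary threshold list (e.g. all unique scores) can be
passed for a finer sweep; the 11-point rule is the default. AP is
undefined — reported as absent, not 0 — for classes with no reference
cells. Mean AP averages the defined classes.

AP is *approximately* non-increasing as the gate shrinks. It is not
exactly monotone: the matcher is class-blind, so changing the gate can
re-pair a handful of cells across classes and move a per-class AP by
O(10⁻²) in either direction. Tests assert the collapse at small gates
and bound the non-monotonicity, rather than asserting exact
monotonicity.

**NMS and stitching.** Duplicate detections (from overlapping inference
patches or model ensembles) are merged by greedy non-maximum
suppression on centroids: repeatedly keep the highest-score remaining
detection and suppress all detections within the radius (default =
gate, 25 px; score ties broken by source id then position). Patch
stitching translates patch-local detections by their patch origin
(grid stride = patch size − overlap, default 256 − 128), validates that
detections lie inside their patch, concatenates, and applies NMS.

## Synthetic data

The generator exists so that every statistic can be validated against
planted parameters; its defaults encode the study conditions the
package is meant for.

- **Layout:** sequential inhibition (dart throwing with rejection
  inside a 15 px hard-core radius) on a 2150×2150 px ROI, 1500 cells by
  default — the per-ROI annotation counts observed on real test slides
  are in the 1100–1500 range. The hard core keeps the 25 px gate
  essentially unambiguous at this density. Labels are i.i.d. from the
  class proportions; the `hnscc-like` and `tnbc-like` presets set the
  CD3⁺/non-specified ratio to 0.62 and 0.16, the extremes observed
  across tumor indications, with tumor fixed at 40%.
- **Raters:** per-class miss probability (default 0.1, matching the
  ~20% spread in total annotation counts between the most and least
  complete real raters), a row-stochastic 3×3 label-confusion matrix
  (default 95% fidelity), and isotropic Gaussian click jitter (default
  3 px, small against the 25 px gate).
- **Detectors:** per-class Bernoulli recall (default 0.9), clutter
  detections ~ Poisson (default 50/ROI) placed uniformly with labels
  from the empirical class prior, Beta(8, 2) scores for true and
  Beta(2, 5) for clutter detections, jitter as above.

All randomness flows from a single top-level seed through named
substreams (`layout`, `rater:<id>`, `detector:<id>`), so identical
configurations yield byte-identical CSV output and the components are
independently reproducible.

What the generator does **not** emulate: spatial clustering of classes
(tumor nests, lymphocyte aggregates), anisotropic or systematic rater
bias, density gradients, staining artifacts, or correlated errors
between raters. Tests passing on synthetic data therefore validate the
*evaluation machinery* — matching, tallying, formulas, consensus — not
the behavior of any real detector or rater population.

## Verification strategy and problem sizes

- Matching: exhaustive-enumeration oracle on 200 random instances with
  ≤ 7 cells per side.
- Kappa: independent transcriptions of the four defining formulas on
  100 random 4×4 matrices (machine precision), plus a hand-computed
  fixed example.
- Closed form: two raters flipping the true label with probability ε
  (uniformly to the other two classes) on a shared equal-prevalence
  layout give standard κ = ((1−ε)² + ε²/2 − 1/3)/(2/3); checked at
  ε ∈ {0, 0.1, 0.3} with n = 5000 cells within 3 Monte-Carlo SEs.
- Parameter recovery: planted detector recall and rater miss rates
  recovered within 3 binomial SEs at n = 2000.
- Bookkeeping identities (provenance-exact TP/FP, planted diverse
  fractions, conservation of support) at n in the hundreds.

The acceptance script runs a five-ROI study at the default conditions
(5 × 1500 cells, three raters, one detector); these sizes keep the full
verification suite in the tens of seconds on one CPU while leaving all
Monte-Carlo tolerances comfortably tight.

## Known limitations

- The CSV reader identifies one (roi, source) per file; multi-source
  files must be split by the caller.
- Greedy NMS and greedy agglomerative clustering are heuristics; both
  are deterministic and tested against oracles at small n, but neither
  is globally optimal for pathological geometries.
- κ confidence intervals, weighted κ, and Fleiss-style multi-rater κ
  are out of scope; agreement among >2 raters is reported pairwise.
- AP gate-monotonicity holds only approximately (see above).
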