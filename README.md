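# cellconcord

Cell-level evaluation of immunohistochemistry (IHC) annotations and
detections.

Quantifying T-lymphocytes on IHC-stained tissue requires single-cell
annotations: every tumor cell, CD3⁺ cell, and remaining ("non-specified")
stromal cell in a region of interest (ROI) gets a position and a class
label. Comparing two such annotation sets — two pathologists, a
pathologist versus semi-automatic software, or annotations versus an
automatic detector — is harder than comparing ordinary categorical
ratings, because the raters do not share a list of items: each rater may
miss cells the other found. `cellconcord` implements the evaluation
machinery for exactly this situation:

- **Gated correspondence.** Two sets of cells are put in one-to-one
  correspondence by minimum-cost bipartite assignment (Hungarian
  algorithm) on the Euclidean distance matrix of cell centers, accepting
  only pairs within a distance gate (default 25 px ≈ the radius of an
  average cell at 0.23 µm/px). Distances beyond the gate are forbidden
  before solving, so the result is the maximum-cardinality gate-feasible
  matching of minimum total distance.
- **Agreement with missed cells.** From the matched correspondence a
  4×4 *extended* confusion matrix over {tumor, CD3⁺, non-specified,
  missing} is tallied, and chance-corrected agreement is computed four
  ways: standard Cohen's κ = (P_o − P_e)/(1 − P_e) on jointly labeled
  cells, plus the three missing-data adaptations of De Raadt *et al.* —
  *Regular Category* (missing is a fourth class), *Listwise Deletion*
  (only jointly labeled cells), and *Gwet* (listwise P_o, but
  singly-labeled cells still enter P_e). Comparing the variants
  separates the two sources of disagreement: cell omission versus label
  confusion. κ values carry their Landis–Koch interpretation
  (moderate, substantial, almost perfect, …).
- **Consensus with a tie class.** Three (or more) raters are merged
  into a consensus: every annotated cell is kept, labels are decided by
  majority vote, and cells with no strict plurality (typically two
  raters, two labels) get the special **diverse** label, which is
  excluded from downstream evaluation.
- **Detection scoring.** Scored detections are evaluated per class
  (TP/FP/FN) across the 11 score thresholds σ ∈ {0.0, 0.1, …, 1.0};
  average precision is the recall-increment-weighted sum of precisions,
  AP = Σₖ (Recall_{k+1} − Recall_k)·Precision_k. Greedy non-maximum
  suppression merges duplicate detections from overlapping inference
  patches (default 256 px patches, 128 px overlap) or model ensembles.
- **Synthetic ground truth.** A generator produces hard-core cell
  layouts (~1500 cells per 2150×2150 px ROI), simulated raters (per-class
  miss rates, label confusion, click jitter) and simulated detectors
  (per-class recall, clutter, Beta-distributed scores), with full
  provenance so every statistic can be checked against planted
  parameters.

## Worked example

Simulate one ROI with three raters and a detector, then evaluate:

```bash
cellconcord simulate --preset hnscc-like --n-cells 800 --seed 11 --out demo
cellconcord kappa --sets demo/raterA.csv --sets demo/raterB.csv \
                  --sets demo/raterC.csv --out demo/kappa.csv
```

which prints, per rater pair (excerpt):

```
roi_id source_a source_b           variant       po       pe    kappa interpretation  n_effective
pooled   raterA   raterB          standard 0.916795 0.356189 0.870762 almost_perfect          649
pooled   raterA   raterB  regular_category 0.757962 0.304608 0.651940    substantial          785
pooled   raterA   raterB listwise_deletion 0.916795 0.356189 0.870762 almost_perfect          649
pooled   raterA   raterB              gwet 0.916795 0.356395 0.870721 almost_perfect          649
```

The pattern is the interesting part: the simulated raters (10% miss
rate, 95% label fidelity) *almost perfectly agree* on cells they both
labeled (listwise/Gwet κ ≈ 0.87), while the Regular Category κ ≈ 0.65
reveals that most disagreement comes from cells one rater missed.
`n_effective` is the number of cells entering P_o — 649 jointly labeled
versus 785 in the union.

```bash
cellconcord consensus --sets demo/raterA.csv --sets demo/raterB.csv \
                      --sets demo/raterC.csv --out demo/consensus.csv
# 799 consensus cells, diverse fraction 0.0275
cellconcord eval --reference demo/truth.csv --detections demo/detector.csv \
                 --out demo/report.json
# mAP 0.9026
```

2.75% of consensus cells were two-rater ties ("diverse"); the simulated
detector (90% recall, 50 expected clutter detections per ROI) scores a
mean average precision of 0.90 against the ground truth.

The same operations are available as library functions
(`match_sets`, `kappa_regular_category`, `build_consensus`,
`average_precision`, …); the CLI is a thin wrapper.

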