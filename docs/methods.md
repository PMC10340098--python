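# Methods

## Model

`netdr` scores a drug–disease pair by the topological and transcriptional
similarity of two gene modules on a weighted functional interaction network
(FIN): the drug-affected protein network (DAPN) and the disease gene
network (DGN). The working assumptions are

1. **Network locality** — disease genes and the genes a drug perturbs are
   not required to coincide; effects propagate to direct interaction
   partners, so modules are seed sets plus 1-hop neighbors, and all metric
   computations (degrees, walks, neighborhoods) are module-local: they run
   on the induced subnetwork, never the full FIN.
2. **Signature reversal** — a therapeutic drug pushes disease-perturbed
   genes back toward baseline, so for shared genes the signed sum
   z_drug + z_disease is near zero. The damping factors `0.5^|·|` and
   `e^{−|·|}` encode exactly this: cancellation preserves a gene's
   topological score, any residual perturbation demotes it.
3. **Edge weights as evidence** — weights in (0, 1] quantify functional
   similarity; weights below 0.1 are treated as noise and pruned (a weight
   of exactly 0.1 survives; the filter is "less than"). Nodes left without
   edges are dropped.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `weight_floor` | 0.1 | minimum retained edge weight |
| `drug_z_threshold` | 1.0 | drug DEG filter, strict: \|z\| > 1 |
| `fdr_threshold` | 0.01 | disease DEG filter, strict: FDR < 0.01 |
| `fc_threshold` | 2.0 | disease DEG filter, inclusive on linear scale: 2^\|log2FC\| ≥ 2 |
| `damping` | 0.75 | PageRank damping factor |
| `alpha` | 0.7 | neighborhood-scoring self weight |
| `epsilon` | 0.1 | neighborhood-scoring edge-weight cutoff (strict >) |
| `n_thresholds` | 100 | ROC rank cutoffs at 1%…100% of the ranked list |
| `auc_cutoff` | 0.6 | combined-AUC candidate significance threshold |

Unmeasured genes have z = 0 everywhere, which makes every damping factor
exactly 1 — absence of evidence never moves a score.

## Metric conventions and numerical choices

* **Adamic-Adar.** k_z is by default the plain (unweighted) module-local
  degree, matching the inverse-log-weighted similarity convention, under
  which a common neighbor always has k_z ≥ 2 and log k_z > 0. An optional
  weighted-degree mode uses node strength instead; strengths can fall
  below 1 there, so denominators are floored at log(1 + k_z) — documented,
  finite, and covered by the brute-force oracle in the tests. Natural
  logarithm throughout. The implementation is a dense
  B·diag(1/log k)·Bᵀ product; the test oracle is an independent triple
  loop.
* **PageRank.** Undirected edges act as two directed edges; transition
  probability is proportional to edge weight; teleportation is uniform
  (no personalization). Power iteration stops at L1 change < 1e−12
  (1000-iteration cap raises with the residual); returned scores are
  normalized to sum exactly 1. Tests cross-check a dense linear solve and
  networkx.
* **Neighborhood scoring.** X_i = α·x_i + (1−α)·(Σ_{j: w_ij>ε} x_j)/N,
  where N counts only supra-threshold neighbors (the same neighbors being
  averaged); N = 0 degrades to α·x_i. The operation is linear in the z
  map.
* **z map fed to neighborhood scoring.** The pipeline feeds it the
  *residual perturbation magnitude*: |z_drug + z_disease| for genes in
  both modules, |own-side z| otherwise — the same quantity the AA/PR
  damping factors act on. Ranking ascending then means "most neutralized
  first". The alternative of feeding the signed own-module z was examined
  and rejected: a signed ascending order is symmetric under sign flips of
  the module z-scores, and on the planted-signal benchmark it carries no
  information (reversal drug indistinguishable from decoys, mean combined
  AUC 0.500). The residual form makes ascending order meaningful and is
  consistent with the reversal principle the other metrics implement.
* **Branch membership.** "In both modules" is evaluated against module
  *member* sets (seeds ∪ neighbors), because the metrics score all module
  members.
* **Ranking and ROC.** AA1/AA2/PR1/PR2 rank descending, NS ascending; ties
  break lexicographically by gene ID, making every downstream number
  deterministic. Rank cutoffs are round-half-up of p%·n with a floor of
  one gene; duplicate cutoffs collapse. Anchor points (0,0) and (1,1) are
  added (the percent grid never contains the empty prediction set), points
  are sorted by FPR, and the AUC is the trapezoid. At full threshold
  resolution this equals the Mann–Whitney statistic exactly. A reference
  set that is empty on — or covers — the ranked list leaves TPR or FPR
  undefined; the drug-metric pair is reported as NA and logged, never
  fatal.
* **Precision/recall/F1** are reported at k = |reference ∩ ranked| (the
  break-even cutoff, where precision = recall by construction).
* **Caching.** The DGN and its base AA/PR scores are drug-independent and
  computed once per disease; the z-adjustment depends on each drug and is
  re-applied per drug. Results are identical to fresh computation (tested).

## Synthetic-data generator

The generator produces studies with the statistical structure the method
assumes, so every pipeline stage and the planted-signal benchmark run
without any external download.

* **Network** — Erdős–Rényi (default) or Barabási–Albert at mean degree 10
  over 500 genes; weights Beta(0.7, 5), whose mass concentrates below 0.1
  like real FIN weight histograms, then pruned by the standard 0.1 floor
  (≈ 44% of edges survive). Resampled until the largest component holds
  ≥ 90% of surviving nodes.
* **Disease cohort** — a connected module of 40 genes grown by BFS,
  emulating a coherently up-regulated disease program: z = 3 + 1.5·|N(0,1)|
  (the magnitude range of cohort DE z-statistics at FDR < 0.01 and
  |FC| ≥ 2), FDR ~ U(0, 0.009), log2FC ≥ 1; background genes receive
  sub-threshold values, so the DEG filter recovers exactly the planted
  module. Because a functional module interacts more densely than the
  network background, 2 extra intra-module edges per gene (weights from
  the same Beta, resampled above the floor) are planted.
* **Drug library** — one reversal drug and 24 decoys, all sharing the full
  measured-gene universe and equally sized DEG sets of 1.5× the module
  size (perturbation signatures affect more genes than a disease DEG
  list). The reversal drug perturbs 80% of the module genes with
  z = −(r·z_dis + √(1−r²)·σ·η) (correlation ≈ r with the negated disease
  signature; exact negation at r = 1) plus random off-module filler; a
  drug that perturbed the module exactly would make DAPN ≡ DGN and the
  AUC degenerate, and real drugs never hit a disease program completely.
  Decoys place their DEG sets uniformly at random. At r = 0 the library
  is all decoys.
* **Reproducibility** — one RNG seeded per study drives network, disease
  and drugs in that order.

### What the benchmark does and does not show

Passing the planted-signal benchmark shows the pipeline detects a genuine
reversal signature embedded in a network-localized module against
size-matched random competitors, robustly across seeds. It does **not**
emulate L1000 measurement noise, cell-line-specific baselines,
dose–response structure, correlated background expression, or the
hub-biased incompleteness of curated interactomes; absolute AUC values on
real cohorts will differ.

Two further measured properties deserve note:

* **The null is not centred at 0.5.** With no reversal planted, the median
  combined AUC over decoys is ≈ 0.35, not 0.5. This is a real property of
  the z-damped statistic, not a bug: a decoy's reference genes — its
  chance overlaps with the disease module — retain the full disease
  perturbation, are damped hardest, and sink to the bottom of its ranking.
  The statistic therefore actively *anti*-ranks non-reversing drugs, and
  0.5 is only approached as the disease z-scores shrink to noise — the
  regime where no method could recover the planted drug either. Candidate
  cutoffs on real data should be read against an empirical drug-library
  distribution, not against 0.5.
* **Partial reversal can score below the null.** The strength sweep is
  monotone on the metric-pooled mean (0.35, 0.40, 0.49, 0.63 at strengths
  0, 0.3, 0.6, 0.9), but PageRank alone dips slightly at strength 0.3: a
  half-reversing drug leaves residuals |z| ≈ 2 on exactly its reference
  genes, which the exponential damping punishes harder than random
  placement. The damping factors are steep; weak reversers are not
  half-rewarded.

## Known limitations

* Gene identifiers are opaque, case-sensitive strings; symbol/alias
  harmonization is upstream curation.
* The disease z-score is consumed as an input column; the package does not
  derive it from counts (the DE pipeline is out of scope).
* AUC significance is by fixed cutoff; no permutation p-values.
* Modules use 1-hop neighborhoods only; no diffusion or multi-hop
  propagation.
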