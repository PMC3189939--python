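# Methods

## The statistic

Both enrichment directions in this package reduce a 2×2 contingency table to
the one-sided Fisher exact p-value, the inclusive upper tail of a
hypergeometric distribution:

P(X ≥ k) = Σ_{i=k}^{min(n,K)} C(K,i) C(N−K, n−i) / C(N,n)

* **FGA (gene axis).** N = genes in the universe (symbols surviving the
  intensity filter, deduplicated), K = functional-group genes in the
  universe, n = query gene-list size, k = overlap. One-sided
  over-representation only; depletion is out of scope.
* **CAFET (sample axis).** N = cohort size S_T, K = |group 1| = S_G,
  n = samples carrying the dysregulation signature (S_P for a single gene,
  S_FP — the union over member genes — for a functional group), k = the
  flagged samples falling in group 1 (S_C / S_FC).

The tail is evaluated in log space (log-gamma binomials combined by
log-sum-exp). This matters twice: binomials such as C(138, 90) overflow
naive factorial arithmetic, and reference p-values reach 10⁻¹⁸, where a
complementary-CDF subtraction (1 − CDF) would return 0. Terms with
i < n − (N−K) are combinatorially impossible and skipped. The kernel is
tested against three independent routes: literal enumeration of all draws
(small populations), exact rational combinatorics over every valid query
with population ≤ 25 (relative agreement 1e−12), and
`scipy.stats.hypergeom.sf` deep in the tail.

Multiple testing uses the Benjamini–Hochberg step-up,
q_(i) = min_{j≥i} p_(j)·m/j capped at 1, mapped back to input order with a
stable sort. m counts only the tests actually performed: gene sets failing
an eligibility gate are excluded *before* testing and do not inflate m.

## Dysregulation flags

For a gene and direction, each probe's baseline is its **median across all
samples**; a sample is flagged up when any probe value is strictly greater
than 2.5× that probe's median, down when strictly below 0.5× (the asymmetry
reflects that additive background intensity compresses apparent
down-regulation on a linear scale). A gene with several probes flags the
union of its probes' flagged samples ("at least one probe" rule). A probe
with median 0 can never flag down and flags up for any positive value; this
degenerate case is logged. An alternative baseline — the mean over a caller-
supplied reference sample set (e.g. the control group) — is available via
`reference_samples`; the median baseline is the default because it needs no
grouping and is robust to the perturbation itself unless a majority of
samples is affected.

Group-level eligibility: a functional set is tested only when at least 5
member genes flag at least one sample each (`min_contributing_genes`,
overridable). Up and down directions are always separate batches with
separate BH.

## Pipeline conventions

* **Probe filter.** Probes whose maximum intensity across samples is below
  100 (strict) are removed; intensities are linear-scale on input, log2 is
  always an explicit operation (`log2(value + pseudocount)`, pseudocount 1).
* **Differential expression.** Per probe, Welch's unequal-variance t-test on
  log2 intensities (a robust default for two-group microarray comparison —
  no moderated variance, no covariates), BH across all tested probes, and a
  pass requires FDR < 0.05 **and** linear group-mean ratio strictly above
  2.5. A gene is DE when any probe passes; a gene with probes passing in
  opposite directions appears in both direction lists. Zero variance in both
  groups yields p = 1 at equal means and p = 0 (flagged degenerate,
  perfectly separated) otherwise, keeping the decision rule continuous on
  toy fixtures.
* **Clustering.** UPGMA (average linkage) on Euclidean distances between
  sample columns of the log2 matrix, via SciPy. Columns are sorted
  lexicographically by sample id first, making the dendrogram invariant to
  input order and tie-breaking deterministic across platforms. The two-group
  cut is the root split; which side is "group 1" is a labeling choice — an
  anchor sample id, a majority class label, or by default the smaller
  subtree. An optional top-k-variance probe selection is provided but off by
  default.
* **Signature score.** Per gene: average the log2 probe rows, z-score across
  samples with the n−1 standard deviation (zero-variance genes become zero
  rows); a sample's score is Σ_up z − Σ_down z. Scores therefore sum to ~0
  across samples and are invariant to per-gene rescaling of raw intensities.
  Missing signature genes are dropped with a warning, never imputed.

## Synthetic cohorts

`generate_cohort` emulates the marginal structure the thresholds assume:
i.i.d. log-normal intensities, 2^N(8, 0.5) per probe and sample (positive,
right-skewed, well-defined median), optional multi-probe genes named
`{gene}_p{k}`, a two-group partition (default 50/50 of 100 samples), one
planted 20-gene pathway and size-matched decoy sets drawn from the
non-planted genes. Three regimes:

* **concentrated** — every planted gene ×4 in every group-1 sample. Note the
  per-gene median then sits between the two modes (≈2× baseline), so a
  planted cell clears the 2.5×-median gate with probability ≈0.5 per gene —
  the union over 20 genes still covers group 1 essentially completely.
* **distributed** — each group-1 sample has exactly **one** planted gene ×4,
  assigned round-robin: the strongest form of the "one member per sample"
  argument. A perturbed cell (2 log2 units up, vs a 1.32-unit threshold at
  noise sd 0.5) is flagged with probability ≈0.91, so group-1 coverage is
  near-complete but not certain.
* **null** — no perturbation; used for type-I calibration.

What the generator does **not** emulate: inter-gene correlation, batch
effects, probe-level artifacts, heavy-tailed outliers. Passing tests
therefore demonstrate the statistical mechanics of the method — coverage
counting, the tail, eligibility, FDR — not robustness to those real-data
features.

## Problem sizes used in the checked claims

The regime-contrast check runs 50 seeds per regime at the default cohort
size (1000 genes × 100 samples) and requires the planted set at FDR < 0.05
in ≥ 90% of seeds for the detecting method and ≤ 10% for the blind one.
Null calibration pools 10 seeds × 100 decoy sets (~870 eligible groups; the
observed false-positive rate at p < 0.05 must stay below 0.05 plus a
binomial 99% margin — the discreteness of the hypergeometric makes the test
conservative, so the observed rate is typically ~0.03). The enumeration
sweep covers every valid query with population ≤ 25.

## Known limitations

* Coverage enrichment needs many samples; with small cohorts the sample-axis
  table has little power and the gene-axis test is the appropriate tool.
* The median baseline breaks down when a majority of samples is perturbed
  (the median chases the perturbation) — visible in the concentrated regime
  above; the reference-mean baseline mode exists for that situation.
* GO annotations are used as given (no ontology propagation); genes are
  matched by exact case-sensitive symbol with no alias resolution.
* p-values are exact Fisher one-sided tails; no mid-p correction or
  permutation null is offered.
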