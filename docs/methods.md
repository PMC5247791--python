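# Methods

## The model

`dcnet` analyses a biological state transition observed through `m`
parallel gene-expression datasets, each with samples in two conditions
(`A` = reference/control, `B` = perturbed/tumour). Its object of study is
the pair of condition-specific co-expression networks and, above all, the
**differentially correlated pairs (DCPs)**: gene pairs whose correlation
changes significantly between conditions and which are an edge in exactly
one of the two networks. A *gain* is an edge present only in the B
network, a *loss* an edge present only in the A network; genes
participating in at least one DCP are *DC genes*.

### Cross-dataset meta-analysis scheme

Every inferential stage applies the same three-step scheme to its
per-dataset statistic (mean difference, correlation, correlation
difference or partial correlation):

1. **Direction filter** — the statistic's sign must agree in at least
   `k_required` of the `m` datasets. Exact zeros and untestable
   dataset/feature combinations count toward neither direction; a tie
   between opposite signs fails. An optional veto (off by default) fails
   a feature when any dataset carries the opposite sign at nominal
   significance.
2. **Fisher combined probability** — `X = -2 Σ log p_i` over the
   *agreeing* datasets, referred to χ² with `2·n_agreeing` degrees of
   freedom. Combining only the agreeing datasets keeps the combined
   p-value interpretable as evidence for the consensus direction.
3. **Benjamini–Hochberg FDR** over the combined p-values of the features
   that survived the filter (not over all conceivable features,
   mirroring the sequential-filter design).

Stage-level nominal thresholds act as a *support* rule: DEG calling and
network edges additionally require the per-dataset p-value below the
stage threshold in at least `k_required` agreeing datasets, while the DCP
stage screens the *combined* p-value (`p_diff`) — the difference test's
contract names no per-dataset gate, and the combined-level screen is the
reading that uses the stage threshold coherently.

### Stages and defaults

| stage | statistic | per-dataset test | preset `bcko` | preset `cervical` |
|---|---|---|---|---|
| DEGs | mean(B) − mean(A) | paired t (paired design) or Welch t | p<0.05, q<0.10, k=2/2 | external DEG list or same machinery, k=3/5 |
| network edges | Pearson r per condition | t with df = n−2 | p<0.20, q<0.025 | p<0.10, q<10⁻⁸ |
| DCPs | z_B − z_A, z = atanh r | normal, SE = √(1/(n_B−3)+1/(n_A−3)) | screen p<0.20, combined p<0.10, q<0.02 | q<0.0025 |
| LPC edges | local partial correlation | t with df = n−k−2 | — | screen p<0.40, q<0.05 |

The moderated ("random-variance") t of the original microarray tooling is
replaced by the classical paired/Welch t: the moderation hyper-parameters
are not recoverable, and the classical test keeps the pipeline fully
specified. Zero-variance degenerate tests return p = 0 with an infinite
t when the mean difference is non-zero (overwhelming evidence,
deterministic and testable) and p = 1 when it is exactly zero.

### PUC filter

Networks drop "unexpected" correlations: an edge is kept only when its
consensus correlation sign equals the product of its two genes'
differential-expression directions (+ for UP/UP and DN/DN pairs, − for
discordant pairs). This sign-concordance reading matches the observed
pattern that co-regulated pairs carry positive partial correlations; it
is switchable off (`puc=False`).

### Local partial correlation (LPC)

With more genes than samples the global precision matrix is not
estimable, so the partial correlation of each nominally correlated pair
(Pearson p < `p_lpc_screen`, default 0.40) is computed from the pair's
*local* sub-matrix: the pair plus all genes significantly correlated with
either member (genes touching only the neighbours are excluded). The
sub-matrix is inverted and
`partial_r = −Ω_ij / √(Ω_ii Ω_jj)`; the p-value uses a t statistic with
`df = n − k − 2`, `k` the conditioning-set size. Singular sub-matrices
receive a 10⁻⁸ diagonal ridge with a logged warning.

When the neighbourhood is too large it is capped at `⌊n/2⌋` genes, ranked
decreasingly by `max(|r to gene_i|, |r to gene_j|)` with ties broken by
lexicographic gene id. The public `cap_neighborhood` fires at
`|neighbours| > n` (the literal size-versus-samples rule); the network
builder fires it already at `|neighbours| > n − 3`, because any larger
conditioning set would drive `df = n − k − 2` below 1 and leave the edge
untestable — the two triggers coincide in the regime the cap was designed
for (`|neighbours| ≫ n`). Datasets with fewer than 6 samples in a
condition are skipped for LPC (the capped df would vanish). With an empty
conditioning set the machinery reduces exactly to the Pearson edge test,
and with a saturated conditioning set to the global precision-matrix
partial correlation — both reductions are regression-tested.

### Topology of DC genes

Given an externally supplied key-driver set, two statistics locate each
gene of the perturbed network:

* **minimum shortest path (MSP)**: the smallest unweighted distance to
  any key driver (0 for drivers; undefined, and excluded from group
  comparisons with a logged count, when no driver is reachable);
* **bipartite betweenness centrality (BBC)**: Brandes-style accumulation
  of `σ_st(v)/σ_st` over ordered pairs (s, t) with sources = key drivers
  and targets = peripheral genes (degree exactly 1). Endpoints receive no
  credit; fractional path counting is used because raw counts are
  ambiguous under shortest-path multiplicity and coincide with fractions
  when paths are unique.

DC-versus-rest contrasts use the tie-corrected Mann–Whitney rank-sum test
(without continuity correction, so identical groups give p = 1) and a
seeded label-permutation test on the group mean difference with
`p = (1 + #{|stat*| ≥ |stat|}) / (n_perm + 1)`, default `n_perm` 10 000.
The BBC comparison set excludes key drivers and peripheral genes.

### Enrichment and knockdown metrics

Causal-gene over-representation in a gene group versus a background uses
the one-sided ("greater") Fisher exact test by default, with the odds
ratio Haldane-corrected (+0.5 per cell) when a zero cell occurs. The
knockdown metrics implement the two-step growth normalisation:
`A/B index = cell index after / before treatment` per well, then
`inhibition index = (control A/B − treatment A/B) / control A/B` per
replicate experiment (positive = growth inhibition), tested with a
one-sample one-sided t against 0 over replicates.

## The synthetic-data generator

`generate_truth` plants, in a universe of 300 genes (default):

* **80 DEGs** with mean shifts of 1.5 marginal SDs applied to condition B
  only (case-versus-control semantics), split between UP and DN;
* **5 causal hubs**, each the designated representative of an
  equicorrelated 5-gene block present only in condition B's correlation
  matrix at r = 0.8 — all 50 within-block pairs are truth *gains*.
  Positive semi-definiteness forbids a star with r = 0.8 hub–leaf edges
  and independent leaves (it would need Σr² ≤ 1), so hubs are cliques;
  block members share a regulation direction so planted positive
  correlations are PUC-concordant;
* **10 loss pairs** (disjoint pairs at r = 0.8 in A only) and **10 shared
  pairs** (r = 0.8 in both conditions) — the shared backbone yields edges
  in *both* networks and exercises the rule that such pairs are never
  DCPs;
* matrices are eigenvalue-clipped to the nearest PSD correlation matrix
  if needed, and generation fails if any planted entry drifts more than
  0.02 (the default block construction needs no repair).

`sample_datasets` draws each dataset's samples from multivariate normals
with the condition matrices, on a per-gene log-scale baseline of
N(7, 1). Defaults mirror the two-dataset paired knockout design
(2 datasets, 12 + 12 samples).

* **Paired design**: each A/B sample pair shares a per-gene intercept of
  variance τ² = 0.15 (capped at half the smallest eigenvalue of the
  planted matrices, effectively 0.10 at the r = 0.8 defaults) carved
  *out of* the unit marginal variance: residual covariance `C − τ²I` plus
  the shared intercept. Within-sample correlations therefore equal the
  planted matrices exactly, while paired differences have variance
  `2(1 − τ²) < 2` — the pairing benefit a paired t exploits.
* **Heterogeneity** h: each condition-B sample activates each causal-hub
  block independently with probability 1 − h; inactive blocks revert to
  the reference structure for that sample. This emulates multi-causal
  tumours in which different patients run different driver programmes,
  diluting gain correlations as h grows.

What the generator does **not** emulate: probe-level microarray noise
(saturation, probe effects), batch structure, non-Gaussian marginals,
and missingness (tests cover missing-data handling with hand-built
matrices instead). Recovery results on synthetic data therefore speak to
the statistical machinery, not to array preprocessing.

## Calibration and known limitations

Problem sizes used by the test suite and the acceptance script — 300
genes, 2 datasets of 12 + 12 paired samples, 100–200 replicates — are the
package's scaled-down stand-in for the original study designs, chosen so
the whole analysis reruns from scratch in well under a minute per batch.

At exactly this design the pipeline has a hard analytical power ceiling
worth knowing about. The DEG rule demands per-dataset p < 0.05 in both
datasets; with 12 pairs, 1.5 SD effects and paired-difference variance
2(1 − τ²), the classical paired t has per-dataset power ≈ 0.94, so
per-gene sensitivity is capped near 0.94² ≈ 0.88 — the measured value.
Gain-DCP sensitivity is further bounded by both genes being called DEGs
(≈ 0.88²) and by the Fisher-z difference test, whose per-dataset
noncentrality at r: 0 → 0.8 and n = 12 is `atanh(0.8)/√(2/9) ≈ 2.33`;
pooled gain sensitivity lands near 0.57 with empirical DCP FDR ≈ 0.05 and
no gain/loss misclassification. Larger samples or a variance-moderated
test would raise the ceiling; the package deliberately ships the
classical, fully specified tests.

Other numerical choices: correlations are computed on complete-case
samples per pair and need n ≥ 4 (Fisher z requires n − 3 > 0); |r| = 1
maps to p = 0; consensus ties fail the direction filter; all randomness
flows from explicit seeds (`numpy.random.default_rng` /
`SeedSequence.spawn`) and every pipeline output is byte-reproducible for
a fixed config and seed.
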