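# Methods

`regnet` infers regulator–target relationships in tumour expression data by
combining four statistical components: per-sample sparse linear models of
gene expression, post-selection inference for the regulators those models
pick, a permutation test for each regulator's per-gene contribution, and a
sequence-level featurization that turns motifs, peaks and annotations into
the binding-site count matrix the models consume. A synthetic-data generator
with planted ground truth provides the test bed. This note records the
model, the numerical choices, and what the synthetic studies do and do not
establish.

## The expression model

For each tumour sample the log2 expression of gene *g* is modelled as

    y_g = w0 + wC·C_g + wM·M_g + Σ_f w_f·N_gf + ε_g,   ε_g ~ N(0, σ²)

where `C_g` is the gene's copy-number level (GISTIC-style, −2…+2), `M_g` its
promoter-methylation beta-value in [0, 1], and `N_gf` the count of binding
sites of regulator *f* (a TF in the promoter, or a miRNA/RBP in the 3'UTR).
One model is fitted per sample, so regulator activity may differ between
tumours; genes play the role of observations.

The fit minimises the lasso objective `(1/2n)·‖y − w0 − Xw‖² + λ‖w‖₁` by
cyclic coordinate descent with soft-thresholding on the Gram matrix.
Numerical choices:

* **Standardisation.** Counts, copy-number levels and beta-values live on
  incomparable scales, so features are centred and scaled to unit variance
  before penalisation; coefficients are reported back on the original scale.
  The intercept is never penalised. Constant (zero-variance) columns are
  excluded from updates and keep coefficient zero.
* **Convergence.** A sweep ends the descent when the largest coefficient
  change is below 1e-8 (at most 1e5 sweeps). The returned fit records its
  KKT residual; the test suite requires ≤ 1e-6 and verifies global
  optimality against an exhaustive sign-pattern QP oracle on small problems.
* **Penalty scale.** λ is reported on the 1/(2n) objective scale (sklearn's
  `alpha` convention). λ_max — the smallest penalty with an all-zero
  solution — is `max_j |x_jᵀ(y−ȳ)|/n` on standardised columns.
* **Tie-breaking.** Coordinates are updated cyclically in the column order
  of the feature matrix, which fixes the solution path deterministically.

λ is chosen at the minimum of K-fold (default 10) cross-validated squared
error over a 100-point log-spaced path from λ_max down to λ_max·1e-3, with
seeded fold assignment. Predictive performance is measured as the Spearman
rank correlation between predicted and observed expression of held-out
genes, averaged over folds and then samples. Evaluation uses *nested* CV —
λ re-selected inside every training split — because selecting λ on all
genes first and then scoring held-out genes leaks information; the leaky
single-CV variant remains available (`nested=False`) for comparison.
Feature-class ablation refits the model without one class (CNV, METH, TF,
MIRNA or RBP) on the same folds and reports the percentage reduction in
mean held-out Spearman.

## Selective inference for candidate regulators

Classical tests are invalid for coefficients the lasso picked adaptively.
At fixed λ the event "active set A with signs s" is a polyhedron
{y : Ay ≤ b}; conditional on it, the relaxed least-squares coefficient
η_jᵀy of an active feature is a Gaussian truncated to an interval [V⁻, V⁺]
computable from the polyhedron. We implement this fixed-λ polyhedral test,
conditioning on both the active set and the signs, with two-sided p-values
by default.

* The design is standardised and the response centred exactly as in the
  fit; every constraint vector lies in the centred subspace, where the
  projected noise covariance is again σ²I, so the centring is exact rather
  than approximate.
* Truncated-Gaussian tail ratios are evaluated in log space
  (`log_ndtr`-based interval probabilities) so that extreme truncations do
  not underflow; a degenerate interval returns p = 1.
* σ is estimated as the degrees-of-freedom-corrected residual SD of
  unpenalised least squares on all features when n > p + 1 (the regime of
  every analysis here), otherwise on the lasso-active set.
* λ passed to inference is each sample's CV-selected value, converted to
  the unscaled (1/2)-objective convention the polyhedron is written in
  (λ·n).

Under a global null with fixed design the pooled selective p-values are
uniform; the suite checks this with a KS test over 500 seeded replicates.
Candidate regulators are ranked by the number of samples in which they are
active *and* selectively significant (p < 0.05); a table row reports
`n_selected` and the percentage over all samples, and the candidate list
keeps regulators selected in strictly more than a configurable number of
samples.

## Target discovery by permutation

Removing regulator *r* from a fitted model means zeroing its fitted
contribution (no refit): ŷ₋ᵣ = ŷ − w_r·x_r. The statistic for gene *g* is
the change in squared prediction error summed across samples. Its null
distribution comes from B replicates in which the rows of every
prediction-relevant feature column are permuted independently — fresh
permutations per column, per sample and per replicate — and the summed
error change recomputed with the original coefficients. Only columns with
nonzero coefficients (plus the probed regulator) are actually shuffled:
permuting a column whose coefficient is zero cannot change any prediction,
so the restriction is exact, not an approximation. Permuting per sample
rather than once per replicate makes the null a sum of independent
contributions, which concentrates it and gives the test its per-gene
resolution.

The empirical p-value is `(1 + #{null ≥ observed}) / (B + 1)` — one-sided,
since a target's error should increase on removal, and never zero (minimum
1/(B+1); at the production default B = 5000 that is ≈ 2e-4, matching the
callable q-threshold). Benjamini–Hochberg correction is applied per
regulator across genes. A target call additionally requires a *positive*
observed error change: a gene with no binding site for the regulator has an
identically zero statistic and cannot be evidence of regulation, and
without this requirement the one-sided comparison is anti-conservative for
such genes (their permuted-design null has negative mean, since inserting a
random site into the prediction usually worsens it). Desk-scale studies in
the test suite use B = 500 with q ≤ 0.05; the defaults are B = 5000,
q ≤ 2e-4.

Validation utilities compute exact overlap counts between predicted and
reference target sets, and compare log-fold-change ECDFs across the four
disjoint gene groups (reference targets; additional predicted targets;
genes with a motif but in neither set; genes with no site) with pairwise
KS statistics.

## Feature building

* **Promoters** are the strand-independent ±flank window (default 2000 bp)
  around the TSS, clipped at the chromosome start. Coordinates are 0-based
  half-open (BED) throughout; overlap means ≥ 1 shared base.
* **TF sites** are PFM log-odds matches on both strands whose *exact* score
  p-value under a 0-order background (default uniform, configurable) is
  below 1e-4, optionally restricted to open-chromatin intervals
  (peak-required mode for DNase). The exact p-value uses the standard
  motif-scanner construction: log-odds scores are discretised into 1000
  bins over the score range and the null score distribution of a random
  k-mer is built by dynamic programming; the same integerised scores are
  used to score windows, so scan decisions and p-values are mutually
  consistent, and the DP tail equals exhaustive enumeration of the
  integerised scores exactly. (Against *float*-score enumeration the
  binned p-values can differ in the extreme tail where a single k-mer
  straddles a bin edge; the suite checks close agreement at moderate p and
  exact agreement at the shared discretisation.) A pseudocount of 1e-4 on
  PFM probabilities keeps log-odds finite. A p-threshold ≥ 1 is vacuous
  and reports every valid window.
* **miRNA/RBP sites** are exact k-mer matches in the 3'UTR (single strand;
  minus-strand genes are reverse-complemented first). RBP k-mers are the
  top 10 highest-probability k-mers of the RBP's PFM — ties broken
  lexicographically, computed by best-first search — optionally restricted
  to CLIP peaks after subtracting background-binding intervals (interval
  set-difference via an interval tree). Overlapping matches all count; a
  position matching several listed k-mers counts once.
* **Assembly** intersects counts, CNV and methylation on gene identifiers,
  drops regulators with no site in any retained gene, and (separately,
  idempotently) merges features with identical count vectors into one
  column that records its members.

Preprocessing for real inputs: scaled-estimate × 1e6 → TPM; drop genes
≤ 0.1 TPM in more than 70% of samples (strictly more; a gene at exactly
70% is kept); log2(TPM + 1); per-gene methylation probe chosen by the most
negative Pearson correlation with expression (zero-variance probes cannot
win; ties break on probe id; an all-positive gene warns); miRNAs below
1 CPM of the miRNA library in more than 70% of samples are dropped. All
filters are idempotent.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
planted ground truth for every test:

* Regulator site counts are Poisson(site_density) — equivalently a
  zero-inflated construction with presence rate 1 − exp(−site_density) and
  zero-truncated Poisson counts, which has the same law. CNV is a GISTIC
  level drawn from {−2…2} (probabilities 0.05/0.2/0.5/0.2/0.05) plus
  N(0, 0.1) jitter; methylation is Beta(2, 2) and enters with a negative
  weight by default, methylation being canonically repressive.
* True weights are drawn once per planted regulator, |w| ~ U(weight_range)
  with random sign, then multiplied per sample by U(0.8, 1.2): per-sample
  models see coherent but non-identical effects, as the per-sample fitting
  strategy assumes.
* A regulator's true target set is exactly the genes where it has ≥ 1 site.
* Matched tumour/normal LFC tables shift the planted targets of a chosen
  regulator by a configurable mean (default 1.0) over N(0, 0.5) noise.
* Sequence fixtures emit one synthetic chromosome per gene (promoter +
  spacer + 3'UTR, all genes on the + strand; the builder itself handles −
  strands), near-deterministic PFMs (0.91 on each consensus base), DNase
  peaks covering each promoter and CLIP peaks covering each 3'UTR. Every
  region is rejection-sampled against the *builder's own counting
  functions* until the planted counts are reproduced exactly, so the
  round trip sequences → counts is an identity by construction, not
  approximately.

Desk-scale study conditions (chosen once as this package's defaults):
regulator recovery uses 2000 genes × 40 samples with 48 regulators + CNV +
METH, ten planted with |w| ∈ [0.5, 2] and unit noise; the ablation study
plants all ten regulators in the RBP class and evaluates ten samples; the
target-discovery study uses 1000 genes × 80 samples at site rate 0.1
(≈ 100 targets per regulator) with |w| ∈ [1, 2] — the strong-regulator
regime, mirroring the fact that target discovery is run on top-ranked
candidates — and B = 500 permutations.

### What the synthetic studies do not show

The generator draws independent Gaussian noise, independent site counts and
a linear, additive model — exactly the model the pipeline fits. Passing
tests therefore establish the *correctness and calibration of the
machinery* (solver optimality, selective-inference uniformity, permutation
exactness, recovery under the assumed model), not robustness to the ways
real tumour data violate it: correlated features from co-binding,
non-Gaussian and heteroskedastic expression noise, count matrices shared
imperfectly across samples, batch structure, or regulators acting through
unmeasured channels. Real-data headline numbers (absolute Spearman values,
selection percentages, CLIP-overlap fractions) depend on those violations
and on external databases, and are not reproduced here.

## Known limitations

* Expression is treated per sample; no information is shared across
  samples beyond the common feature matrix (no multi-task penalty).
* "Removal" of a regulator reuses the fitted coefficients; a full-refit
  sensitivity variant exists in principle but the permutation null is
  defined for the reuse contract.
* 3'UTR k-mer positions for minus-strand genes are reported in transcript
  coordinates; peak filtering for such genes assumes peaks cover whole
  UTRs (true of the synthetic fixtures).
* Elastic net, group penalties, interaction (competitive/cooperative
  binding) terms and RNA secondary structure are out of scope.
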