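# Methods

## The design being modeled

The package analyzes a paired multi-source sEV study: for each patient,
sEV cargo profiles from tumor tissue (T), adjacent normal tissue (N), a
tumor organoid culture (O), and plasma (B), plus a small panel of pure
CAF-culture sEV profiles and a labeled single-cell reference of the tumor
microenvironment. The scientific questions are (i) which cargo is
tumor-enriched, (ii) which of that cargo in-vitro models fail to
reproduce and whether stromal cells (CAFs) explain it, (iii) which cell
types produce the tissue sEV pool, and (iv) whether tissue-derived
candidates survive as circulating diagnostic markers.

## No-replicate exact test

With one library per source per patient there are no replicates, so the
per-feature T-vs-N comparison uses the exact conditioned-binomial test
(the classical exact procedure for comparing two sequencing libraries):
conditional on the total count n = x + y, x follows Binomial(n, p) with
p = N_A/(N_A + N_B) fixed by the two library sizes. The two-sided p-value
sums the probability of every outcome whose point-probability does not
exceed the observed one (method of small p-values), with a 1 + 1e-7
relative tolerance when comparing point-probabilities, the same
convention R's `binom.test` uses. Because the binomial pmf is unimodal
the rejection region is two tails; the implementation locates the inner
tail boundary by vectorized bisection, which is exactly equivalent to
full enumeration (the tests verify equality to 1e-12 for all x + y ≤ 50)
but fast enough to run genome-wide on every patient.

Fold changes are library-size-normalized ratios with a 0.5 pseudocount on
both counts so zeros stay finite. An up-call requires fold change > 1.5
AND raw p < 0.05 (the joint rule applied symmetrically to down-calls with
the reciprocal threshold); BH-adjusted p-values are always computed and
reported alongside, and callers can switch the thresholds to adjusted
values. A detection floor (raw count ≥ 5 in at least one of the two
samples, config-exposed) keeps the exact test from making trivial calls
at tiny counts.

Counts from biological tissue are overdispersed relative to the binomial
sampling model, which inflates the raw exact-test p-values; in that
regime the fold-change threshold is the binding part of the joint rule.
This mirrors how the joint FC-and-p filter is used in practice and is why
the synthetic null calibration is asserted on the joint call rate, not on
p alone. The replicated group test (Welch's t on log2 intensities or
log2-CPM, geometric-mean fold changes, BH correction) is exactly
calibrated on log-normal data; features with zero variance in both groups
are reported as p = 1.

"Up in more than half (4 of 7) of patients" is implemented as support ≥ 4
out of 7 — the majority-vote signature. The same ≥ 4 rule defines the
lost-set consensus; "not upregulated in O" means failing the same joint
up-call used for the T contrast. "Expressed in CAF sEVs" defaults to
CPM ≥ 1 in all CAF samples (no published numeric floor exists for this
notion; both floor and sample count are config-exposed).

## Source attribution

`build_signature` averages per-cell CPM within clusters and defines the
specificity share S[g,k] = mean_k(g)/Σ_k' mean_k'(g); markers are the
top-m genes per cluster by specificity × log1p(mean), with lexicographic
tie-breaking so marker lists are deterministic.

Proportions come from nonnegative least squares of the CPM-scaled bulk on
the signature's marker-gene rows, renormalized to sum to one. Noiseless
convex mixtures of signature columns are recovered to 1e-6 (NNLS is exact
there); sampled bulks at depth 2×10⁶ recover proportions with RMSE ≈ 0.01
at K = 4.

The cell-weighted fold change apportions each differential gene's log2FC
across clusters by S[g,k]p̂ₖ renormalized per gene, so each gene's row
sums exactly to its log2FC (conservation is asserted to 1e-9); clusters
are ranked by mean |cwFC| over the differential genes. Genes expressed in
no cluster receive a uniform share — they cannot be localized. This is a
reconstruction of the proportion- and specificity-weighted intent of
published cell-weighted fold-change tools, not a line-for-line port.

Abundance attribution splits each gene's bulk mass by S[g,k] (soft
assignment; conservation-exact, so Tissue-sEV% sums to one) and compares
each cluster's cargo share to its cell share via the release index
log10(Tissue-sEV%/Cell%), base 10 by convention here. Soft assignment
shrinks attributed shares toward uniform on genes expressed in several
clusters: with a reference whose clusters share a common expression
baseline, the attributed deviation from uniform is roughly proportional
to the marker mass fraction of the profiles. Signs and ranks of the
release index are preserved (the tests assert the high-releasing cluster
shows the unique positive index in ≥ 95% of replicates), but magnitudes
are conservative; with a disjoint-support reference the attribution is
exactly unbiased, which is how the Monte-Carlo consistency test is
constructed. The immune/nonimmune summary is the abundance-weighted mean
release index per flag.

## Gene-set scoring

ORA is the hypergeometric upper tail of the query/set overlap inside a
declared universe (default: all detected features — the appropriate
universe for detection-limited sEV assays), BH-corrected across sets.
ssGSEA ranks each sample's features (average ranks on ties), then walks
the ranking accumulating the difference between the rank^0.25-weighted
in-set ECDF and the unweighted out-of-set ECDF; the score is the sum of
the deviations, normalized across samples by the global score range.
Being rank-based it is invariant to per-sample monotone transforms. A set
covering the whole universe has no out-of-set ECDF and scores zero by
convention.

## Diagnostic panel

The funnel is a logged triple intersection: detected in ≥ 6 of 7 plasma
samples (detection = raw count ≥ 1, config-exposed), ∩ an externally
supplied plasma-up list, ∩ a tissue-up list (both are plain-text inputs
standing in for database contrasts; no live queries). Per-gene AUC is the
Mann–Whitney rank statistic with ties counted one half, with a DeLong
95% CI. The combined model is an SVM on log2-CPM features standardized on
training statistics only; linear and RBF kernels over cost 10⁻²…10² (and
an RBF width grid) compete by cross-validated AUC on a stratified
training split (default 70%, 5 folds); the validation split never touches
model selection, and train/validation AUCs carry stratified-bootstrap
(2000 replicates) percentile CIs. DeLong for single genes and bootstrap
for the model were chosen because the model's decision values are not a
fixed per-gene statistic; no CI method is canonical for the combined
score.

## Synthetic cohorts

All generators draw negative-binomial counts (mean μ, size/dispersion
parameter φ, variance μ + μ²/φ) around structured means, with φ = 50 by
default — moderate bulk-RNA overdispersion; no empirical dispersion
estimate exists for tissue sEV RNA-seq, so this is a stated default, not
an inference. Defaults define the study conditions used throughout the
tests: 2000 genes, 4 clusters (Epithelial, CAF, Endothelial, Immune) with
50 markers each at 16× background (comfortably above the 8× floor the
marker-recovery checks assume, so empirical own/other ratios stay above 8
under sampling noise), 150 cells per cluster, 7 patients, depth 2×10⁶,
planted tumor effect log2FC = 2 on 300 genes of which 50 are organoid-lost
and 60% of those CAF-expressed, per-cluster release rates spanning a 10×
range with CAFs highest and immune cells lowest (distinct by default so
rank-recovery checks are well-posed), plasma = 10% tumor signal + 90%
normal background, and a 140-case/118-control diagnostic cohort with
marker effect log2FC = 1.5.

Key modeling choices:

* **Organoid purity.** O profiles are drawn from the tumor-epithelial
  cluster alone; the planted lost genes carry the tumor shift in T but
  not in O. This is the generative analogue of organoids lacking
  stromal/immune cargo, and it is what the lost-set logic recovers.
* **Planting on non-marker genes.** Tumor-up and lost genes are drawn
  from genes without cluster-specific expression, because the epithelial
  purity of O otherwise shifts marker baselines in O-vs-N and would
  confound the planted truth.
* **CAF expression.** Lost genes outside the planted CAF-expressed subset
  are silenced in the CAF profile; the planted subset is floored at the
  profile median so it is unambiguously detected.
* **Diagnostic variability.** Case/control samples carry per-person
  per-gene log2-normal biological noise (sd 1.0) plus log-normal library
  variation; without it, marker separation is limited only by sequencing
  noise and every per-gene AUC saturates at 1.0. With it, single-marker
  AUCs land in the realistic 0.8–0.9 range at the default effect size.
* **Determinism.** Every generator consumes a `numpy` seed sequence
  derived from its config seed; identical configs give bit-identical
  outputs.

What the generator does not emulate: sequencing reads or UMIs, isolation
chemistry, miRNA-specific biology (feature classes are labels only),
batch effects, or correlated gene modules. Passing recovery tests on
these cohorts therefore demonstrates that the statistical machinery is
correct and calibrated under the stated generative model — not that the
thresholds are optimal for any particular real dataset.

## Problem sizes and numerical conventions

The test-suite and the acceptance script run the full default conditions
(depth 2×10⁶, 2000 genes); recovery metrics average over 5–10 seeded
cohorts, deconvolution RMSE over 20 bulk replicates, release-index sign
recovery over 100, and classifier power over 10–25 seeds — sizes at which
every asserted margin is stable from seed to seed. Ties in marker
selection and in rankings break lexicographically; p-values are clamped
to (0, 1]; degenerate inputs (zero-variance features, empty sets,
all-zero bulks, single-class labels) either get the documented null
convention or a named validation error rather than silent NaNs.

## Known limitations

* The exact two-library test assumes binomial sampling; on overdispersed
  tissue counts its raw p is anti-conservative and the joint FC + p rule
  carries the specificity. No empirical-Bayes dispersion sharing across
  patients is attempted.
* Abundance attribution magnitudes shrink toward uniform in proportion to
  profile overlap between clusters; only signs and ranks of the release
  index should be interpreted.
* The external funnel lists are caller-supplied; the package performs no
  database retrieval, identifier normalization, or miRNA target
  prediction.
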