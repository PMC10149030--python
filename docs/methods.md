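# Methods

This note documents the statistical models behind `epipanel`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Cohort model

The unit of analysis is a bundle of aligned matrices: gene × sample
log-scale expression (logTPM), probe × sample methylation beta-values in
[0, 1], a probe → gene promoter map (optionally with a signed distance to
the TSS, negative = upstream), gene × sample integer copy-number calls in
{−2, −1, 0, +1, +2}, and per-sample annotations (tumor/normal, matched
pair, subtype label in {1, 2, 3, unknown}). Samples are aligned by
intersecting identifiers across platforms rather than erroring, because
real cohorts rarely measure every sample on every platform; dropped
samples are logged. Missing values use the `NA` token on disk and NaN in
memory, and all statistics exclude them pairwise. Display z-scores use the
sample (n−1) standard deviation; constant features map to all-zero rows
and are flagged rather than producing NaNs.

## Subtype signatures: moderated t with a fold-change threshold

Signatures come from one-vs-rest contrasts of labeled tumors. Per gene,
logFC is the difference of group means and the pooled variance s²g has
dg = nA + nB − 2 residual df. Variances are shrunk toward an
inverse-chi-square prior,

    s̃²g = (d0·s0² + dg·s²g) / (d0 + dg),

and the moderated statistic t = logFC / (s̃g·√(1/nA + 1/nB)) is referred
to a t distribution with d0 + dg df (standard normal when d0 is
infinite). The prior (d0, s0²) is estimated by a method of moments on
eg = log s²g − ψ(dg/2) + log(dg/2): the excess of var(eg) over the mean
sampling variance ψ′(dg/2) identifies ψ′(d0/2), solved by Newton
inversion of the trigamma function; a non-positive excess means the
spread of the gene variances is fully explained by sampling noise and
d0 = ∞. d0 = 0 recovers the ordinary pooled t-test exactly, which is
the unit-test oracle.

Because genes with tiny but nonzero effects are uninteresting for
signature building, significance is assessed against a fold-change
threshold τ rather than zero:

    p = P(T ≥ (|logFC| − τ)/se) + P(T ≥ (|logFC| + τ)/se),

which reduces to the two-sided t p-value at τ = 0 and tends to 0.5 as
|logFC| → τ with a wide second tail. BH step-up adjustment is applied
across genes; the up (down) set keeps genes with logFC > +τ (< −τ) at
adjusted p < α = 0.05.

Two deliberate choices:

* **Threshold default.** The function default is τ = 1.5 log2 units, the
  conventional "large fold change" criterion for signature derivation
  from well-separated clusters. The pipeline default is τ = 0.5, matched
  to the simulated study conditions: the generator plants a 1.0-sd
  expression shift, and a threshold test at τ = 1.5 has essentially zero
  power against a 1.0 effect (the sampling sd of logFC at these group
  sizes is ≈ 0.15), so a usable τ must sit below the effect being
  sought. Both are exposed in the configuration. The interpretation of
  the threshold as log2 units (not a 1.5-fold ratio) follows the
  convention of threshold tests operating on the model's log2
  coefficient.
* **Minimum set size.** A direction with fewer than `min_set_size = 5`
  genes is emptied. The rank score of a one- or two-gene "set" is
  dominated by single-gene rank noise (a 1-gene set contributes a full
  ±0.5 component with near-uniform distribution), which measurably
  destabilizes downstream classification while carrying no set-level
  signal.

## Single-sample scoring and label transfer

For a sample with n genes ranked ascending (average ties), an up set of
size m scores

    (meanRank(up) − (m+1)/2) / (n − m) − 0.5  ∈  [−0.5, +0.5],

i.e. 0 when the set sits at the middle of the transcriptome; the down set
is scored identically on reversed ranks (n + 1 − rank) and the two
components add, giving a score in [−1, 1]. Only within-sample ranks
enter, so the score is exactly invariant to any monotone transform of a
sample's expression — no between-sample normalization is needed. A set
spanning the whole transcriptome has an undefined span and is defined to
score 0 (flagged); an all-constant sample ties every rank and scores 0.

Unlabeled tumors are classified by k-nearest neighbors (default k = 30)
in score space. Score dimensions are standardized with the *training*
mean/sd, because signature sets differ in size and hence score variance.
Class probabilities are unweighted neighbor fractions — exact multiples
of 1/k — and the assignment is the argmax. Determinism is guaranteed by
ordering equal distances by training sample id and breaking class ties
with the label of the nearest neighbor among the tied classes; permuting
the training set can therefore never change an assignment.

## Silencing screen and targetability

Per gene, promoter methylation is summarized as the mean beta of mapped
probes (max is available), and Spearman's ρ against expression is
computed across tumors (Pearson available; rank-based is the default
because beta-values and logTPM live on very different scales). The
p-value uses the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df,
two-sided, BH-adjusted across genes. The normal-tissue criterion is a
one-sided Mann–Whitney test that normal expression exceeds tumor
expression. Candidate = (ρ ≤ −0.3) ∧ (BH p < 0.05) ∧ (normal-higher
p < 0.05); the ρ cutoff and α are configuration, since "strong inverse
correlation" has no canonical numeric value.

Hypermethylation calls are per-probe: the threshold for each probe is its
maximum beta across **all** normal samples, and a tumor is called for a
gene iff any promoter probe **strictly** exceeds its own threshold
(default `any-probe` rule; a `summary` rule comparing mean-probe
summaries is available and is more conservative). By construction no
normal sample can ever be called against the full normal set. "No loss"
means copy-number call ≥ 0; −1 and −2 are excluded because reactivating a
deleted locus is not a sensible therapy. Missing CNV is treated as
no-loss but counted and flagged. Targetable = hypermethylated ∧ no-loss.

Panel coverage is the percentage of tumors with ≥ 1 targetable panel
gene, reported overall and per subtype group (empty groups give NaN, not
0). The greedy selector adds the gene with the largest marginal overall
coverage, breaking ties by the higher minimum per-group coverage and then
lexicographically; coverage is submodular, so greedy coverage is at least
(1 − 1/e) of the best panel of the same size — verified against
exhaustive subset search in the tests.

## Off-target scan

A site is a genomic 20-mer whose 3′-adjacent 3-mer matches the PAM
pattern (IUPAC, matched exactly; PAM positions never count toward the
mismatch budget, the Cas-OFFinder convention) and whose Hamming distance
to the protospacer is ≤ 3 (default). Both strands are scanned; minus
hits report the forward-strand 0-based half-open protospacer interval
(1-based inclusive reporting is start+1..end). Ambiguous genome bases
never match. Bulges are not modeled — the contract is mismatch-only — and
no index is built: the scan is a vectorized sliding-window comparison
sized for the fixture-scale contigs this package targets, not for
human-genome throughput. Regulatory proximity is modeled as overlap with
BED features expanded by a window (default 2,000 bp, configurable, since
"proximity to a regulatory element" has no canonical distance).

## qPCR quantification and adaptive FDR

Per replicate, ΔCt = Ct(target) − mean Ct(housekeeping genes); the
arithmetic mean of Cts equals the geometric mean of abundances, the
standard multi-reference convention. ΔΔCt is the condition-vs-control
difference of mean ΔCt and fold = 2^(−ΔΔCt) with amplification efficiency
fixed at 2. Replicates missing a housekeeping measurement are dropped
with a warning; wells at the 40-cycle cap are undetected, and a
comparison whose replicates are all capped is flagged censored (its fold
is a bound). The BKY two-stage procedure runs BH at q′ = q/(1+q),
re-estimates the null fraction from the r1 rejections, and reruns BH at
q* = q′·m/(m − r1); it rejects a superset of BH at q′ and matches the
statsmodels implementation on random inputs.

## Synthetic cohorts: what is and is not emulated

Defaults: 3 × 100 tumors, 40 matched normals, 2,000 genes, 200 signature
genes per subtype shifted +1.0 sd, 12 silenced genes each hypermethylated
in 40% of tumors, target anticorrelation ρ = −0.8, logit-scale beta noise
0.5, two probes per gene with 0.25 probe-level noise, 10% copy-loss
probability, 70% of tumors labeled.

Expression is Normal(μg, 1) logTPM with the subtype shift added in the
subtype's tumors. Beta-values are generated on the logit scale
(unmethylated ≈ logit 0.2, hypermethylated ≈ logit 0.7) and inverse-logit
transformed, so they are in [0, 1] by construction. For silenced genes,
expression couples to the methylation latent *relative to the
unmethylated baseline* (expr = μ − γ·(m − logit 0.2)/sd(m) + ε with
γ = ρ/√(1−ρ²)), so hypermethylated tumors are shifted down and never up;
the realized tumor-wide Spearman ρ is checked at generation time and the
coupling redrawn/strengthened (bounded retries) if a draw misses
−(strength − 0.1). Matched normals share a small per-pair offset with
their tumor, keep low methylation, and take no silencing shift. Copy
number is iid categorical. All sub-generators (cohort, genome/guides,
qPCR) draw namespaced sub-streams from one integer seed, so equal seeds
give bit-identical artifacts.

Not emulated: array probe chemistry and detection noise, batch and
purity effects, count-level sampling (inputs are already log-abundance),
correlated CNV segments, and any relationship between copy number and
expression. Tests passing on these cohorts demonstrate the correctness
and calibration of the algorithms under the assumed structure — not
robustness to the full messiness of real tumor data.

## Numerical conventions and scales

Ranks use average ties throughout. BH is implemented as the step-up
min-accumulation (note it is *not* idempotent on its own output; the
guaranteed invariants are step-up monotonicity, adj ≥ p, cap at 1).
Probabilities from the threshold test are clipped to (0, 1]. The trigamma
inversion runs Newton from x = 0.5 + 1/y to relative tolerance 1e−10.
Spearman p-values with |ρ| = 1 are set to 0 rather than NaN. Test and
acceptance workloads are sized for a single CPU: oracle equivalence runs
500 scoring instances, 50 × 10-kb genome scans and 1,000 coverage
matrices; recovery checks use the default 300-tumor cohort (50 seeds for
the screen); calibration uses 10,000 null genes/tests. The acceptance
script repeats the same computations once per stage at the same sizes.

## Known limitations

* The moderated-t stand-in does not reproduce limma's trend fitting,
  array weights, or voom precision weights; it is calibrated (type-I
  error ≈ 0.05 on nulls) but not numerically interchangeable with limma
  output on real arrays.
* The screen's t-approximate Spearman p-values are approximate for small
  cohorts; with < 10 tumors the screen refuses to run.
* Hypermethylation thresholds from the normal **maximum** are sensitive
  to outlier normals; the summary rule is provided as a more conservative
  alternative, and both assume the normal set is uncontaminated.
* The off-target scan is exhaustive and unindexed; scanning a mammalian
  genome with it is possible but slow by design trade-off.
* Greedy panels are near-optimal ((1 − 1/e) guarantee), not optimal; for
  ≤ 12 candidate genes exhaustive search is feasible and used as the test
  oracle, but the pipeline always reports the greedy trajectory.
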