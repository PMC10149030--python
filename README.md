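# epipanel

Tumor suppressor genes (TSGs) in hepatocellular carcinoma and other solid
tumors are frequently silenced not by mutation or deletion but by promoter
DNA hypermethylation. Such loci are attractive targets for CRISPR-activation
(CRISPRa) therapies: the gene body is intact, so restoring transcription is
possible in principle — but only in patients whose tumor actually carries the
epigenetic lesion and has not also lost the locus. `epipanel` is a toolkit
for finding these genes in a multi-omic tumor cohort and for assembling
small gene panels such that (nearly) every patient harbors at least one
targetable gene. It is written for computational biologists working with
TCGA-style cohort matrices (RNA-seq log-abundance, Illumina array
beta-values, GISTIC-style copy-number calls).

## What it computes

**Subtype label transfer.** Cohorts are often only partially annotated with
molecular subtypes (integrative clusters), because clustering required all
platforms to be present. `epipanel` derives per-subtype expression
signatures from the labeled tumors with an empirical-Bayes moderated
*t*-test (per-gene variances shrunk toward a prior: s̃²g =
(d₀s₀² + dg s²g)/(d₀ + dg), with (d₀, s₀²) estimated by method of moments
on log variances) and a fold-change threshold test
(p = P(T ≥ (|logFC|−τ)/se) + P(T ≥ (|logFC|+τ)/se), testing |logFC| > τ
rather than ≠ 0), with Benjamini–Hochberg FDR control. Each sample is then
scored against each signature with a rank-only single-sample statistic
(the mean within-sample rank of the signature genes, mapped to
[−0.5, +0.5]; invariant to any monotone transform of the sample), and
unlabeled tumors are assigned by *k*-nearest neighbors (k = 30) in
signature-score space, with exact 1/k probabilities and a deterministic
tie-break.

**Silencing screen.** For every gene, the Spearman correlation ρ between
the promoter beta-value summary and expression across tumors, with a
one-sided Mann–Whitney test that expression is higher in normal tissue.
Candidates satisfy ρ ≤ −0.3, BH-adjusted p < 0.05, and normal-higher
p < 0.05.

**Targetability and panels.** A gene is *hypermethylated* in a tumor when
any promoter probe strictly exceeds that probe's maximum beta across all
normal samples, and *targetable* when additionally the copy-number call is
≥ 0 (no loss). Panel coverage is the percentage of tumors with ≥ 1
targetable panel gene; a greedy set-cover selector orders genes by marginal
coverage (guaranteed ≥ (1 − 1/e) of the optimal panel of the same size).

**Supporting computations.** An exhaustive gRNA off-target scan (20-nt
protospacer, IUPAC PAM, Hamming distance ≤ 3, both strands) with
BED-feature proximity annotation; ΔΔCt qPCR quantification with multi-gene
housekeeping normalization (fold = 2^(−ΔΔCt)); and the two-stage
Benjamini–Krieger–Yekutieli FDR procedure.

**Synthetic cohorts.** A first-class simulator generates cohorts with the
structure the analysis assumes — three expression-separable subtypes,
genes whose promoter methylation anticorrelates with expression in a
patient subset, matched normals, categorical copy-number calls — together
with the ground truth, so every stage is testable without any download.

## Worked example

```python
from epipanel import CohortSimConfig, simulate_cohort, derive_signatures
from epipanel import score_matrix, knn_assign, promoter_summary
from epipanel import anticorrelation_screen, call_hypermethylation
from epipanel import targetable_matrix, greedy_panel

cohort, truth = simulate_cohort(CohortSimConfig(seed=0))

labels = cohort.labeled_tumors()
signatures = derive_signatures(cohort.expression[labels.index], labels,
                               logfc_threshold=0.5)
scores = score_matrix(cohort.expression[cohort.tumors], signatures)
unlabeled = cohort.tumors.difference(labels.index)
assigned = knn_assign(scores.loc[labels.index], labels,
                      scores.loc[unlabeled], k=30)
accuracy = (assigned["assigned"] == truth.subtype[unlabeled]).mean()
print(f"transferred labels for {len(unlabeled)} tumors, "
      f"accuracy vs ground truth: {accuracy:.3f}")

beta = promoter_summary(cohort.methylation, cohort.promoter_map)
results = anticorrelation_screen(cohort.expression, beta, cohort.annotations)
candidates = results.index[results["candidate"]].tolist()
print(f"screen: {len(candidates)} candidate silenced genes "
      f"(planted: {len(truth.silenced_genes)})")

hyper = call_hypermethylation(cohort.methylation, cohort.promoter_map,
                              cohort.normals, cohort.tumors)
tm = targetable_matrix(hyper, cohort.cnv)
panel, trajectory = greedy_panel(tm.targetable.loc[candidates],
                                 truth.subtype.astype(str), max_size=4)
print(trajectory[["gene_id", "overall_pct"]].to_string(index=False))
```

prints

```
transferred labels for 90 tumors, accuracy vs ground truth: 1.000
screen: 12 candidate silenced genes (planted: 12)
gene_id  overall_pct
 G01695    40.333333
 G00176    64.000000
 G01785    78.333333
 G01268    87.333333
```

The default cohort plants 12 silenced genes among 2,000 in 300 tumors with
40 matched normals; 70% of tumors carry a known subtype label. The screen
recovers all 12 planted genes with no false candidates, the 30% held-out
tumors are assigned to the correct subtype, and a 4-gene panel already
covers 87% of tumors (each gene is hypermethylated in only ~40% of
patients, so combinations are required for full coverage).

The same pipeline is available from the shell:

```sh
epipanel run-all --seed 0 --outdir run0        # simulate + full analysis
epipanel simulate --outdir cohort --seed 0     # just write the cohort TSVs
epipanel screen --expression ... --methylation ... --promoter-map ... \
    --annotation ... --out candidates.tsv
epipanel offtarget --genome genome.fa --guides guides.tsv --out hits.tsv
epipanel qpcr --ct ct.tsv --housekeeping GAPDH,GUSB --control vehicle \
    --out folds.tsv
```

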