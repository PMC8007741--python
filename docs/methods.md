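# Methods

This note records the models, parameter choices and numerical decisions
behind `diapausetx`, in the order the pipeline runs.

## Normalization

Relative expression is RPKM with `mapped_reads(j)` defined as the column
sum of the supplied count matrix. In the original workflow that number
came from the aligner log; a counts-first pipeline has only the matrix, so
the column sum is used and documented as the operative definition. This
choice preserves the identity Σᵢ RPKM(i,j)·length_kb(i) = 10⁶ for every
sample, which the tests assert exactly.

Log transformation adds a pseudocount of 1 (log₂[RPKM+1]); z-scores
standardize each transcript across all 16 samples with the sample (n−1)
standard deviation. Zero-variance transcripts get an all-zero z-row and
are flagged: they can never pass the strict non-overlap filter, so the
convention is semantically inert downstream.

The expression floor keeps transcripts with ≥ 1 cpm in ≥ 4 of the samples,
computed on raw library sizes before TMM, matching the conventional
filter-then-normalize order.

## Differential expression

Counts are modeled per transcript as NB(μ, φ) with Var = μ + φμ², log
link, a group-mean design (EF, LF, EC, LC) and offset log(Nⱼ·fⱼ), where fⱼ
is the TMM factor. TMM follows the published procedure exactly: reference
sample by 75th-percentile count fraction closest to the mean; M/A values
over transcripts nonzero in both libraries; double trim (30% on M, 5% on
A) by ranks; inverse asymptotic-variance weights; factors rescaled to
geometric mean 1. One test cross-checks the factors against the
Bioconductor implementation to ~1e-10.

Dispersion estimation is a deliberate simplification of the reference
package's empirical-Bayes machinery, validated by parameter recovery
rather than numeric identity:

- **Gene-wise**: method of moments from within-group residuals of counts
  scaled to a common effective library size, floored at 0.
- **Common**: profile maximum likelihood over all genes with a Cox–Reid
  adjustment for the plugged-in group means (−½ Σ log I(β̂) per gene and
  group). A trimmed mean of the gene-wise values was tried first and is
  biased low — the sampling distribution of a moment estimator at 12
  residual df is strongly right-skewed, and symmetric trimming cuts the
  long right tail — which made the null LRT anticonservative. The pooled
  adjusted likelihood over thousands of genes is nearly unbiased.
- **Tagwise**: linear shrinkage φ* = (w₀·φ_common + dᵢ·φ̂ᵢ)/(w₀ + dᵢ) with
  prior weight w₀ = 20 against the residual df dᵢ, floored at 1e-6.

Because the design is one-hot, the IRLS normal equations decouple into one
coefficient per group, each solved by damped Newton on the score
Σ(y−μ)/(1+φμ) (step clipped at ±5, max 50 iterations, tolerance 1e-10).
A group with all-zero counts is fitted at the mean floor 1e-8 before
log-fold-changes are formed. The global test compares 4 means against 1
(df 3); each pairwise test merges the two contrasted groups (df 1);
p-values come from the χ² approximation and are BH-adjusted per contrast.
The DEG set used downstream is the global-test set by default
(`deg_definition="pairwise_union"` switches to the union of pairwise
sets); the captions this choice mirrors are ambiguous, so both are
provided.

Calibration on the generator's null design (2,000 transcripts, 4×4, no
effects): raw-p rejection ≈ 0.06 at the 0.05 level; with 10% planted
|log₂FC| ≥ 1.5 effects, sensitivity ≥ 0.99 and empirical FDR ≈ 0.08–0.12
at BH 0.05. The residual mild liberality is the χ² approximation at 4
replicates per group with estimated dispersions.

## Phenotype protocol

Samples are embedded by t-SNE (perplexity 5, ≤ 50,000 iterations, exact
gradient at n = 16) on Euclidean distances over log₂(RPKM+1) features,
repeated 10 times with derived seeds; the representative run minimizes the
final KL divergence, and the fraction of repeats whose DBSCAN partition
equals the representative's is reported as a stability score. The
n ≥ 3·perplexity + 1 precondition guarantees full perplexity
neighborhoods.

DBSCAN is implemented deterministically: a point's Eps-neighborhood
includes itself, cores need ≥ MinPts neighbors, clusters are connected
components of cores, and border points join the cluster of their
lowest-index core neighbor, so labels never depend on point order.

Eps is scanned over every unique pairwise distance (≤ 120 candidates at
n = 16). Candidate partitions with ≥ 2 clusters are scored by the Dunn
index — minimum single-linkage inter-cluster distance over maximum
complete-linkage diameter — computed on the **full partition with
DBSCAN's noise points as one extra group**. Scoring with noise excluded
is degenerate: the score is maximized by shrinking Eps until only tight
MinPts-sized cores remain and declaring everything else noise, which
contradicts both the protocol's published full-coverage partitions and
the behavior of the R implementation it used (feeding dbscan's 0-labeled
noise vector to a partition-based Dunn treats noise as a group). Ties
resolve to the partition with fewer noise points, then to the smallest
Eps; the *reported* Dunn value for the chosen partition is the classic
noise-excluded index, and `dunn_index` itself (noise excluded, error on
< 2 clusters, +inf on zero diameter) is unchanged. If no Eps yields ≥ 2
clusters the protocol returns a single cluster at the maximum distance
with Dunn undefined.

## Co-expression modules

The network is unsigned: adjacency |r|^β with β = 14 on row-standardized
log₂(RPKM+1); the topological overlap matrix is
TOMᵢⱼ = (Σᵤ aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ). Modules come from
average-linkage clustering of 1 − TOM with a static cut at height 0.99,
a minimum size (default 100), grey for the unassigned remainder, and a
merge step that fuses modules whose eigengenes correlate above
1 − merge_threshold (default 0.25). The static cut replaces the dynamic
hybrid tree-cut of the reference package; recovery of planted modules,
not numeric identity, is the validation target. Colors follow the
standard sequence by decreasing size (turquoise, blue, brown, yellow, …).

Eigengenes are the first principal component of the module's standardized
expression (unit norm, sign oriented to correlate non-negatively with the
module mean profile); module–trait relationships are Pearson correlations
of eigengenes against binary group and single-sample indicators with
two-sided t-transform p-values, plus five-number summaries per group for
boxplot export.

## GO handling

Only `is_a` edges are honored; the OBO subset reader accepts `[Term]`,
`id`, `name` and `is_a` stanzas, detects cycles on load, and either
rejects or auto-declares undeclared parents. A filter for a term is the
set of transcripts annotated to the term or any descendant. Enrichment is
the classic one-sided per-term Fisher/hypergeometric test against the
GO-annotated universe with BH correction across terms, annotations
propagated to ancestors by default (both modes available). The reference
workflow used a decorrelating weighted algorithm whose scheme is not
described in the source; results here are explicitly labeled
classic-Fisher.

## Indicator panels

A transcript joins the field_up panel when its minimum z-score over all
field samples strictly exceeds its maximum over all culture samples
(culture_up symmetric); ties exclude, since exact ties in continuous
z-scores signal degenerate data. Timepoints are pooled within source, so
the constraint spans 8 vs 8 samples. Candidates are the DEGs annotated to
the configured GO terms; panels record per-term provenance, and global
z-scores (not z-scores recomputed within the DEG subset) are used.

## Species composition

Composition per sample is the marker-read share per species; the expected
cross-mapped fraction is (non-focal share) × efficiency with the 30%
default efficiency. A transcript is flagged cross-map-prone when it
receives ≥ 1 cpm from the simulated congener read set — an operational
version of a qualitative criterion. The robustness check reruns the
phenotype protocol with and without the flagged transcripts under the
same seed policy and reports the adjusted Rand index between partitions.

## Synthetic data: what it emulates and what it does not

The generator draws NB counts (gamma–Poisson) with mean
library_size × relative abundance × 2^(planted log₂ effects):

- **Design**: 16 samples, EF/LF (field, diapause program) and EC/LC
  (culture, reproductive program), 4 replicates each; library sizes
  log-normal around 10⁶ (scaled down from sequencing depth for desk-scale
  runs); transcript lengths log-uniform on 300–10,000 bp; baseline log₂
  abundance N(0, 1.2); dispersions gamma with mean 0.1 and shape 4 —
  a biological CV around 30% with moderate spread, the regime the fixed
  shrinkage prior (w₀ = 20) is designed for.
- **GO tags** sized 584 (oogenesis-like), 717 (lipid-storage-like), 70
  (fatty-acid-like), 1064 (RNA-metabolism-like), realized as an `is_a`
  DAG with one root, one parent term per tag and two child terms each;
  tagged transcripts are annotated to the children so each tag's closure
  has exactly the configured size.
- **Program effect**: RNA-metabolism-like down in field (log₂FC −0.3),
  fatty-acid-like up in field (+0.4), lipid-storage-like up in field
  (+0.3). **Maturation effect**: the oogenesis-like set responds in LC
  only, 60% up and 40% down at |log₂FC| 1.8 — a mixed-direction response,
  as process-level regulation typically is, which also keeps library
  composition balanced so the maturation signal does not leak into
  unrelated GO filters through the RPKM denominator.
- **Modules** are shared latent factors with group-specific levels,
  per-sample jitter (SD 0.4) and per-gene loadings N(0.8, 0.1) with
  exactly half the signs flipped — unsigned networks group anti-correlated
  genes, and sign balance prevents a module from shifting library
  composition. Defaults: a storage module (±1.0 field vs culture) inside
  the lipid tag, a maturation module (LC level 3.0) and a culture module
  (0.6) in the background.
- **Indicators**: 40 per direction, planted inside the panel tags with
  log₂FC 3.0 at dispersion ≤ 0.05 — about 6 generator SDs on the log
  scale, chosen from a power calculation so that strict 8-vs-8
  non-overlap holds with probability ≈ 1 per gene, while bulk
  program-effect genes (≲ 1 SD) pass at < 1%: that contrast is what makes
  panel precision and recall ≥ 0.9 achievable at n = 4 per group.
- **Contamination**: field samples carry congener proportions between 0.10
  and 0.32; injection re-attributes round(p × efficiency × N) reads onto
  600 cross-map-prone background transcripts (multinomial over fixed
  Dirichlet weights) while thinning the focal counts without replacement
  (multivariate hypergeometric), so each library's total is exactly
  preserved and composition effects are isolated from depth effects.
  Marker (mtCOI-like) counts are multinomial draws of 10,000 reads at the
  true composition. Cross-mapping is spread over many transcripts, as it
  is in real references, rather than concentrated in a few.

Truth labels record expected per-contrast log₂ differences (blocks,
indicators and realized module loadings; jitter is noise, not signal),
module membership, indicator ids, per-sample congener proportions and the
prone set.

What the generator does **not** emulate: raw reads, mapping ambiguity,
GC/length biases within a library, batch effects, correlated dispersion–
abundance trends, more than one congener, or realistic mtCOI evolution.
Passing tests therefore demonstrate that the workflow recovers planted
structure of realistic magnitude under the study's design — not that it
is robust to every artifact of real libraries.

## Problem sizes and determinism

Default runs use 4,000 transcripts × 16 samples; calibration studies use
2,000 transcripts; module recovery uses 3 planted 120-gene blocks among
560 genes. These sizes keep every stage, including 10-repeat t-SNE
batteries, comfortable on a single CPU while leaving all planted
structure recoverable. All entry points are deterministic given their
seeds: generator output is byte-identical per (config, seed), t-SNE
repeats use seeds derived from one base seed, and DBSCAN/Eps selection,
module labeling and heatmap ordering are tie-broken deterministically
(lowest index / fewest noise / smallest Eps first).

## Known limitations

- The χ² LRT is mildly liberal at 4 replicates per group (null rate ≈
  0.06 at nominal 0.05); quasi-likelihood F-tests, which would fix this,
  are out of scope.
- The static-height module cut can absorb background genes whose chance
  correlation with a module factor is high at 16 samples; planted-module
  ARI ≈ 0.9 rather than 1.
- Classic Fisher enrichment inherits the DAG's term–term correlation, so
  parent and child terms co-appear in enrichment lists.
- t-SNE at perplexity 5 with 4-sample groups places small groups close
  together; cluster counts are reliable only because the protocol repeats
  the embedding and reports stability.
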