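# Methods

## Models and procedures

### Region model and counting

A gene locus is a half-open genomic interval containing ≥ 1 exon. The
exonic region of gene *g* is the union of its exons; the intronic region is
the locus minus the exonic unions of **all** genes overlapping that span, so
a nested or overlapping gene's exons are never mistaken for another gene's
pre-mRNA signal. Bases claimed by more than one gene (exon–exon or
intron–intron overlap between genes) form an ambiguity mask.

Uniquely mapped reads are classified per read: any exonic overlap with
exactly one gene → exonic (a mature-mRNA fragment may straddle an
exon–intron boundary); fully contained in exactly one gene's intronic
region with no exonic overlap anywhere → intronic; touching two genes →
discarded `ambiguous_gene`; partial intronic overlap → discarded
`boundary`; everything else → `unassigned`. The conservation identity
exonic + intronic + discarded = input reads holds exactly per sample.
Duplicate reads are not removed. Strandedness is a flag
(`unstranded`/`forward`/`reverse`); synthetic data default to unstranded,
and `reverse` matches dUTP-based stranded total-RNA libraries.
Internally all coordinates are 0-based half-open; GTF is converted at the
boundary (1-based closed), BED6 is native.

### Normalization and dispersion

Size factors are median-of-ratios against the per-gene geometric-mean
reference over genes expressed in all samples, rescaled to geometric mean 1
(a pseudocount fallback exists for degenerate matrices). Exonic and
intronic matrices are normalized **separately**: intronic library
composition differs systematically from exonic.

Dispersion α (variance μ + αμ²) is estimated per gene by method of moments
on normalized counts within design cells, α̂₍MoM₎ = max(0, (s² − μ̄)/μ̄²),
followed by a robust trend fit α(μ) = a₀ + a₁/μ and an empirical-Bayes
shrink on the log scale toward the trend. The shrink weight is
v_prior/(v_prior + v_samp,g), where v_samp,g ≈ (2/d)·((1/μ+α)/α)² is the
per-gene sampling variance of the log MoM estimate (d = residual df) and
v_prior is the robust excess spread of gene estimates around the trend,
floored at 0. When genes share a dispersion the excess spread vanishes and
all genes collapse to the trend — this is what keeps the likelihood-ratio
test's type-I error at its nominal level with 3 replicates, where raw
gene-level estimates are too noisy to plug in; genuinely heterogeneous
dispersions retain gene-level signal (log-scale correlation ≈ 0.9 with
truth at n = 10/group in our checks). This machinery is deliberately
simpler than the Cox-Reid/MAP apparatus of DESeq2-class tools: we promise
calibration and recovery on NB data, not numerically identical output to
any external tool.

### Differential expression and interaction tests

Per gene, an NB GLM with log link and log-size-factor offsets is maximized
at fixed α̂ (Poisson exactly when α = 0). Wald tests report log₂FC, SE, z
and p for a single coefficient; likelihood-ratio tests compare nested
models (2Δℓ ~ χ²_Δdf) and serve the cross-model interaction design
`phenotype + mutated_gene + time + phenotype:mutated_gene` against the
no-interaction reduction. Factors use treatment coding with explicitly
declared reference levels (wild-type, CTR, fdx1b). Fold-changes are raw
MLEs — no shrinkage estimator. Non-converged genes carry NaN p-values and
are excluded from the BH denominator; all-zero genes are never tested.
DE calls use padj ≤ 0.01 and |log₂FC| ≥ 0.25 by default. BH adjustment is
one shared code path (statsmodels step-up with NaN passthrough and range
validation).

### EISA

Exonic and intronic counts for a gene are stacked into one joint NB GLM
with condition, region, and condition:region terms and per-column offsets
from the region-specific size factors; the interaction coefficient **is**
Δexon − Δintron and its Wald test propagates both regions' uncertainty
(a two-step subtraction estimate is reported alongside for transparency;
the two agree on noiseless saturated designs). The joint model's dispersion
is the maximum of the exon- and intron-level estimates — conservative by
construction. Genes with mean normalized intronic count < 8 (configurable)
are labelled `low_intron` and excluded from testing: intronic coverage is
roughly an order of magnitude below exonic, and below this depth the
interaction SE is dominated by Poisson noise. Classification at FDR 0.05,
|Δdiff| ≥ 0.25: interaction-significant only → `post_transcriptional`;
exon-DE-significant only → `transcriptional`; both → `mixed`; neither →
`none`. The half-life proxy is log₂((normalized exon mean + c)/(normalized
intron mean + c)) per condition with pseudocount c = 0.5 to tame zeros;
the mutant-minus-control shift is positive when mRNA is stabilized.

### Competitive gene-set enrichment

Given per-gene statistics (best supplied as z-scale values) the competitive
test compares a set's mean statistic against the remaining genes with a
two-sample t whose variance is inflated by VIF = 1 + (m−1)ρ̂. ρ̂ is the
mean pairwise correlation of the set members' **residual** rows (raw data
would mix in the signal itself), floored at 0.01 when not estimable. The t
reference uses the model's residual df when residuals are supplied — the
correlation estimate's own noise otherwise makes the test anti-conservative
(~0.07 at nominal 0.05 in our null simulations; with the residual-df
reference it calibrates to 0.04–0.06). Barcode data are the 1-based ranks
of set members after sorting statistics descending (ties broken by gene id)
plus a triangular-kernel-smoothed relative density curve normalized so 1.0
is the uniform expectation. The hypergeometric overlap test is computed
with exact integer arithmetic (Fractions), so the PMF sums to exactly 1 and
the upper tail is correct to float rounding.

### Metabolite panels and the patient LMM

Concentration panels are log₂-transformed (HPLC-style data) or
glog-transformed, glog(x) = log₂((x + √(x² + λ²))/2), with λ defaulting to
the median SD of the lowest-intensity quartile of features (NMR-style
data); glog → log₂ as λ → 0. Per feature, OLS `y ~ genotype*treatment`
(vectorized across features) tests the interaction coefficient by t-test
with BH across features — the interaction asks whether the mutant–wild-type
difference changes under treatment, i.e. whether treatment rescues the
difference. BH is applied within assay by default. PCA is SVD on the
centered (optionally scaled) samples × features matrix with a deterministic
sign convention (largest-|loading| positive); constant features are dropped
when scaling.

The patient model is y ~ age + treatment + (1|patient) with a random
intercept per patient, fitted by **maximum likelihood** (not REML, because
the LRT compares models with different fixed effects): the variance ratio
θ = σ_b²/σ_e² is profiled out — given θ, the GLS fixed effects and the ML
σ_e² are closed-form via Woodbury — leaving a 1-D bounded optimization,
with the boundary σ_b² = 0 always checked. SEs are large-sample ML SEs
(no small-sample correction); on a balanced paired design the treatment
estimate equals the mean within-patient difference and its SE equals the
population-SD-based paired SE, which is the oracle our tests check to
1e-6. The treatment LRT uses χ²₁ (a fixed-effect test; no boundary issue).
Patient values are modelled on the log₂ scale; the generator emits both the
model-scale value and the exponentiated concentration.

## The synthetic-data generator

The generator emulates: non-overlapping gene loci with 1–6 exons across a
few chromosomes; NB exonic/intronic counts in which a transcriptional
effect δ_txn shifts both regions and a post-transcriptional effect δ_pt
shifts exonic counts only (single-exon genes have intronic count 0);
uniformly placed fixed-length single-end reads fully inside one exon or one
intron (no junction reads, no sequencing error, no GC or fragment-length
bias, no FASTQ); log-normal 2×2 metabolite panels with planted interaction
coefficients; and paired patient panels with per-patient baseline shifts.
All randomness flows from one top-level seed through named, CRC-keyed child
streams so each stage regenerates independently and byte-identically.

Default study conditions mirror the experimental design this pipeline
serves: 3 biological replicates per genotype for RNA-seq, 50 bp single-end
reads, 2×2 genotype × treatment with 5 samples per cell for metabolites,
and 5 patients sampled on and off treatment. Gene-level defaults: base
mean log-normal with median 200 (≈ 25 M reads over ~25 k loci), intronic/
exonic coverage ratio 0.1 (the intronic depth of total-RNA libraries is
not published for this design; the ratio is an explicit free parameter),
and dispersion α = 0.01 — pooled 20-larvae isogenic samples are highly
reproducible, and detecting hundreds of genes at |log₂FC| ≥ 0.25 with
padj ≤ 0.01 and n = 3, as this kind of study does, is only possible when
gene-wise dispersion is of this order.

What passing tests on these data do **not** show: robustness to junction
reads, multi-isoform structure, positional coverage bias, outlier samples,
batch effects, or normalization breakdown when a large fraction of the
transcriptome shifts in one direction (median-of-ratios assumes most genes
unchanged — our half-life benchmark plants effects in 10 % of genes for
exactly this reason, after observing that a 1/3 planted fraction leaks
composition bias into the measured shift).

## Numerical choices and degenerate inputs

GLM convergence: statsmodels IRLS, tol 1e-10, 100 iterations; failures are
flagged, p set to missing, and logged. The LRT statistic is floored at 0
against tiny negative 2Δℓ from finite tolerance. Dispersions are floored
at 1e-8. The LMM profile is optimized on log θ over [−12, 12] (bounded
scalar minimization, xatol 1e-10) with an explicit θ = 0 boundary
comparison. Barcode ties break deterministically by gene id. PCA signs are
fixed per component. Hypergeometric probabilities use integer binomials
exclusively. Empty alignment files, empty gene lists, all-zero genes,
constant features, single-state patients, and rank-deficient designs all
have defined behavior (documented errors or flagged exclusions) rather
than silent misbehavior.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` size their simulations to the
designs above: 2,000 genes × 6 samples for EISA recovery, 5,000 null genes
× 24 samples for interaction-LRT calibration, 50 random mini-genomes ×
10,000 reads against a brute-force per-read scan, 1,000 random p-vectors
against a textbook BH implementation, 400 correlated null sets for the
competitive-test calibration, the full (N ≤ 25, K, n, k) hypergeometric
grid, 200 patients for LMM component recovery with 500 null metabolites for
LRT calibration, 500 genes (10 % stabilized) for the half-life proxy, and a
300-gene end-to-end pipeline run executed twice for checksum identity.

## Known limitations

- EISA sensitivity is information-bounded: with 3 replicates per group and
  dispersion α, SE(Δexon − Δintron) ≥ 0.373·√(α/0.05) log₂ even at
  infinite depth, so single-gene stability effects below ~1.5 log₂ are hard
  to flag at FDR 0.05 under high dispersion; the package reports honest
  uncertainty rather than inflating power.
- The NB LRT retains a small intrinsic liberality at few replicates
  (~0.056 at nominal 0.05 with 24 samples even with the true dispersion).
- No junction-aware quantification, multi-mapping rescue, UMI handling,
  fold-change shrinkage, outlier replacement, or batch correction.
- The half-life proxy is relative, never an absolute half-life.
- The competitive test is the parametric variant; no rank-based version,
  no GO DAG propagation, no gene-set downloads — set collections are
  user-supplied GMT files or generated synthetically.
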