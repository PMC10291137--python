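# Methods

`pdxplore` implements a cross-species multi-omics comparison between
patient osteosarcoma-style tumors (diagnosis and relapse biopsies) and
patient-derived xenograft (PDX) models grown subcutaneously and
paratibially in mice.  Because a PDX mixes human tumor cells (the
graft) with mouse stroma, vessels and immune cells (the host
microenvironment, ME), every stage of the analysis must keep the two
species apart — from raw reads up to principal components.  This note
documents the models, the rules, their parameters and the design
decisions behind each stage, and what the synthetic cohorts used in
testing do and do not demonstrate.

## Read partitioning (`xenosplit`)

A chimeric index stores every canonical k-mer (lexicographic minimum of
a k-mer and its reverse complement; default k = 21, odd so that no
k-mer is self-complementary) of the graft and host references in three
disjoint sets: graft-only, host-only, shared.  Each read is classified
by evidence counting:

| graft-only hits | host-only hits | shared hits | class |
|---|---|---|---|
| >0 | 0 | any | graft |
| 0 | >0 | any | host |
| >0 | >0 | any | ambiguous |
| 0 | 0 | >0 | both |
| 0 | 0 | 0 | neither |

Mates of a pair always travel together: identical classes persist, any
graft/host conflict is ambiguous, a species class dominates
both/neither, and both dominates neither.  The five output classes
partition the input exactly.  The original tool's internal
probabilistic marking is not reproduced — the published five-class
output contract is implemented with this transparent rule instead,
which is auditable and, on genomes with disjoint k-mer content,
exact.  The index is an in-memory set structure intended for genomes up
to a few hundred kb (the synthetic references); whole-genome indexing
is explicitly out of scope.

## Somatic variant filtering and conservation (`variants`)

Calls carry supporting reads, depth, VAF and two population allele
frequencies (1000 Genomes-style and Kaviar-style).  A call is kept iff

* `alt_reads >= 5` (removal is "fewer than five", so 5 is kept),
* `vaf >= 0.05`,
* both population AFs `<= 0.01` (removal is "more than 1%", so 0.01
  is kept).

All three thresholds are configurable; a missing population AF counts
as 0 by default (strict mode rejects such calls as incomplete).
Variant identity for set operations is the `(chrom, pos, ref, alt)`
tuple (1-based, VCF convention); gene-level collapsing is available but
changes Jaccard values and is off by default.

Sample similarity uses the Jaccard distance `d = 1 − |A∩B|/|A∪B|`
(`d(∅,∅) = 0`).  Longitudinal origin of an alteration is a function of
the timepoints it appears in: *diagnosis-conserved* (at diagnosis and
in at least one PDX), *relapse-emergent* (absent at diagnosis, at
relapse and in at least one PDX), *pdx-private* (only in PDX), else
*not-conserved*.  The per-patient mutation-gain ratio is
|later set| / |earlier set|.

## Copy-number categories (`cna`)

Segment categories from integer total copy number and length:
deletion (cn = 0), loss (cn = 1), focal amplification (cn ≥ 7 on
< 5 Mb, strict), amplification (cn ≥ 7 otherwise), gain (2 ≤ cn < 7).
Read literally, the gain band includes the diploid state and would
label every normal segment; by default cn = 2 is reported as *neutral*
and excluded from alteration sets, with `as_printed=True` restoring the
literal rule.  Genes (half-open, 1-based intervals) inherit the
category of any overlapping non-neutral segment, the most extreme
winning (focal amplification > amplification > gain; deletion > loss).
CNA Jaccard uses (gene, category) elements by default; a fixed-width
bin alternative exists because the element resolution materially
changes the distance.

## Fusion consensus (`fusions`)

Per-tool calls from up to five callers are grouped by ordered gene pair
(A::B ≠ B::A — the 5'/3' roles matter) per sample; breakpoints are
reported as per-side medians because callers disagree by a few bases.
A fusion needs ≥ 3 distinct tools (a tool repeating itself counts
once), then ≥ 1 junction read in the re-alignment evidence table.
Validation re-searches every sample: a pair validated anywhere is
looked up in all samples' evidence, adding presence (never new pairs)
where supported — this mirrors the sensitivity-rescue re-search step.
The categories 3'-altered / 5'-altered / truncated have no published
definition, so the implemented rule is a declared interpretation:
truncated when the 3'-partner breakpoint falls in its last exon (no
downstream continuation); otherwise the partner contributing less than
50% of its span (configurable) is the altered one, ties resolved
toward the side losing more, then toward 3'.

## Expression deconvolution (`deconvolution`)

The PDX human fraction contains tumor-cell transcripts only, so genes
expressed in patient tumors but absent from it are microenvironment
genes.  A gene is called ME iff

1. its normalized mean in the PDX human fraction is ≤ 3 counts
   (normalization scales each library to the cohort mean library size,
   keeping the count scale so absolute "reads" thresholds stay
   meaningful), and
2. a negative-binomial rate comparison between the patient and
   PDX-human groups rejects equality at BH-adjusted α = 0.05 with a
   patient/PDX fold ≥ 4 (pseudocount 0.5).

The rate test models counts as NB with size-factor offsets, a pooled
method-of-moments dispersion per gene, and a Wald statistic on the
continuity-corrected log-rate difference.  The original analysis
delegated this step to a DE package; implementing the test explicitly
keeps the stage self-contained and auditable, and its thresholds
(α, fold, absence mean) are declared rather than inherited.  All-zero
genes are excluded and reported.  The tumor matrix is the human count
matrix with ME genes removed (a partition of the gene universe).

The cross-species ME matrix takes the ME genes' counts in patient
samples and their mouse orthologs' counts in the PDX mouse fraction,
reduces the ortholog map to 1:1 pairs (many-to-many dropped and
reported), and scales each species group independently — CPM, log1p,
then per-gene standardization within the group — before concatenating.
The per-group standardization is the declared meaning of scaling "by
the nature of the samples": it removes species-specific location and
scale so only relative patterns are compared.

## Component analysis (`components`)

PCA runs on gene-centered log-normalized expression via SVD; the sign
of each component is fixed by making its largest-magnitude gene loading
positive, so outputs are reproducible across runs and platforms.  A
component is selected iff it explains **more than** 5% of total
variance (a 5.0% component is rejected) and a two-sided Wilcoxon
rank-sum test of its scores between the two sample groups
(patient/PDX, or human/mouse), BH-corrected across the
variance-passing components, is not significant at α = 0.05.  The
separation test is unspecified in the original description; rank-sum
was chosen for its distribution-freeness, with a t-test alternative.
Variance is gated before the separation test (cheaper; configurable).

Kept components are interpreted by their top signed contributors (ties
broken by gene id) and by preranked gene-set enrichment on the signed
loadings: a weighted Kolmogorov–Smirnov running sum with weight
|loading|, a gene-label permutation null, and
`p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (1 + n_perm)` (minimum attainable
p = 1/(n_perm+1)), BH-corrected across sets.  Reversing the ranking
flips the enrichment score's sign exactly.

Proteomics support: proteins with a missing-value rate below 34% are
imputable; the rest are dropped and reported.  Imputation is iterative
low-rank completion — missing cells start at row means, then alternate
rank-r SVD reconstruction (default rank 2, the choice the original
"PCA function" leaves open) and missing-cell replacement until the
largest change is below 1e-5 or 500 iterations.  Observed cells are
never modified.

## Doubling time (`growth`)

Exponential growth between 200 and 400 mm³ makes log2(volume) linear
in time with slope 1/Td.  Selecting measurements by their own noisy
volume biases Td upward (~6% at 5% measurement noise, independent of
sampling density): near the window edges, inclusion correlates with the
sign of the error, attenuating the slope.  `doubling_time` therefore
starts from the observed-volume window (bounds inclusive) and refines
membership against the fitted curve for up to 3 rounds, which removes
the bias; `n_refine=0` restores the plain rule.  Fewer than two
in-window points is undefined; a non-positive slope is flagged.  The
recovery tests use curves sampled every 0.2 days over 12 days from
150 mm³ (about 25 in-window points) — with sparser, caliper-style
sampling the per-curve error grows to ~10% at the same noise level.

## Synthetic cohorts: what they emulate and what they do not

The generators in `pdxplore.synthetic` are first-class, tested code and
define the conditions under which the pipeline is validated:

* **Cohort design** — 8 patients by default, four timepoints each
  (diagnosis, relapse, subcutaneous PDX, paratibial PDX), sample names
  `<model>_<Pat|PDX>_<D|R|sc|pt>`.
* **Reads** — two random genomes sharing a verbatim block covering a
  chosen fraction; paired reads with per-pair true class.  No
  sequencing-error or quality model, and no real-genome repeat
  structure: classification accuracy on these genomes is an upper
  bound for real data.
* **Variants** — per patient: shared variants in all four samples,
  relapse-gained in relapse + both PDX, PDX-private in one PDX.
  Evidence fields of planted variants pass all filters; a decoy
  fraction (default 0.5) fails exactly one rule each, so filter
  accuracy is measurable per rule.  Keys are `(chrom, pos, ref, alt)`;
  genes are synthetic symbols `G0001…`.
* **CNA** — non-overlapping alteration segments with copy numbers in
  {0, 1, 4, 7, 10} and lengths straddling the 5 Mb focality boundary,
  mirroring the variant clonal design, over a 3-chromosome toy genome
  with genes tiled every 1 Mb.
* **Fusions** — each planted fusion is reported by a random subset of
  the five callers with jittered breakpoints, and assigned junction
  reads that are zero or positive, planting both survivors and
  non-survivors of the ≥3-tool and ≥1-read rules.
* **Expression** — negative-binomial counts (dispersion 0.2,
  variance µ + 0.2µ²) over a low-rank log-mean: a baseline
  (log2-normal, median ≈ 32 counts), one species factor whose score
  depends only on the patient-vs-PDX split, and two biology factors
  with scores balanced across the species groups (orthogonal to the
  species contrast) so PCA can separate them from the species axis.
  The species factor loads only on genes with baseline above ~16
  counts: a gene silenced in the PDX human fraction but high in
  patients is, by this pipeline's definition, an ME gene, so the
  species factor must not manufacture such genes outside the planted
  ME set.  ME genes have patient means of 50–500 counts, hard zeros in
  the PDX human fraction (an optional leakage mean relaxes this), and
  mouse orthologs in the mouse fraction following the same per-patient
  program (log2 amplitude 1.5), which is what makes patient and PDX
  microenvironments of the same model recognizably similar.  Real
  bulk data has no hard zeros, correlated library composition, and
  no clean 1:1 orthology — passing these tests shows the machinery is
  correct, not that real ME separation is this easy.
* **Proteins** — rank-2 log-abundance with Gaussian noise (sd 0.05)
  and MCAR missingness at 20%, plus a 10% slice of proteins with ~60%
  missingness to exercise the filter.
* **Growth** — V(t) = v0·2^(t/Td) with multiplicative lognormal noise
  parameterized by its coefficient of variation (volumes stay
  positive; proportional measurement error).

Every generator is byte-deterministic under a fixed seed, and every
planted quantity is recoverable from the emitted files.

## Numerical and design choices

* Pseudocount 0.5 for fold changes and zero-rate continuity
  correction; BH correction everywhere multiple tests are combined.
* PCA keeps components with singular values above 1e-12 of the
  largest; variance fractions are relative to total centered variance.
* Enrichment sets overlapping the universe in fewer than 5 genes are
  skipped and reported, never silently tested.
* The pipeline manifest records every output's sha256; identical
  configuration and seed reproduce identical checksums.
* Cohort-specific figures from the original study (number of removed
  ME genes, variance explained by selected components, conserved
  fusion counts, mutation-gain ratio of the real cohort) depend on
  undeposited patient data and are deliberately not targets of any
  test here; the synthetic recovery and property contracts above
  replace them.

## Known limitations

* The k-mer index is memory-bound and unsuitable for mammalian-scale
  references.
* The NB Wald test is asymptotic; with very few samples per group
  (< 3) its size is approximate, and the ME call then leans mostly on
  the absence rule.
* Fusion-type annotation uses gene spans, not reading frames; it
  cannot distinguish in-frame from out-of-frame events.
* The ME/tumor split assumes the PDX human fraction is pure tumor;
  residual mouse reads misassigned upstream would blur it.
* Doubling-time estimation assumes a single exponential phase within
  the volume window; Gompertz-like deceleration inside the window
  biases Td upward.
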