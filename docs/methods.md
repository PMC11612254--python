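# Methods

This note documents the models and procedures implemented in `casomics`,
their assumptions, the parameters that matter, the synthetic-data design, and
the numerical choices made where the design was genuinely open.

## Somatic SNV filtering

Paired design: a late-passage test sample is compared against an isogenic
early-passage reference. A variant call is retained as a high-confidence
somatic SNV only if all six criteria hold, evaluated in this order for the
`first_failed` label (all are always evaluated for the complete failure set):

1. **Reference VAF** ≤ `ref_sample_max_vaf` (default 0, i.e. literally zero
   alternate reads in the reference). The threshold is exposed because a
   strict zero is fragile under sequencing noise in other datasets.
2. **Biallelic SNV** — exactly one alternate allele and single-base ref/alt.
   Multi-allelic sites are rejected whole (biallelicity is a site-level
   property) and indels are rejected (SNV-only pipeline).
3. **Depth** ≥ `min_depth` (default 20 reads) in the test sample.
4. **Alt depth** ≥ `min_alt_depth` (default 3 reads) in the test sample.
5. **Not germline-like heterozygous.** No published operational definition
   exists for this criterion, so the package uses a VAF-band heuristic: a
   test-sample VAF inside `het_band` (default [0.40, 0.60], inclusive) is
   germline-like. When a population-site list is supplied, membership in the
   list is additionally required — both readings are supported and the
   band-only default is an explicit interpretation, not a claim about how
   any particular study implemented it.
6. **Autosomal** — X/Y calls are excluded (hemizygous sites defeat diploid
   VAF logic).

The filter is monotone (relaxing one threshold can only grow the passing
set) and idempotent; both are property-tested. Substitution spectra collapse
purine-reference SNVs into the six pyrimidine-reference classes.

## Consequence calling and burden

Feature classes are assigned by interval containment with precedence
exon > UTR > intron > intergenic across transcripts (the most severe context
wins, matching common annotator behavior). CDS hits are resolved by mutating
the codon in transcript orientation (reverse-complement on minus-strand
transcripts) and translating: stop-gain → nonsense, identical residue →
synonymous, otherwise missense. Splice sites are the first/last 2 bp of an
intron (the common annotator default window). Records whose REF disagrees
with the genome at that position are rejected. Consequence labels use
`non_coding` for UTR/intron positions and `none` for intergenic ones; amino
acid changes are attached only to missense/nonsense/synonymous calls.

Burden rates divide SNV counts by merged, non-overlapping feature lengths;
UTR bases count as exonic territory for rates but UTR SNVs are reported
separately in count tables. Rate comparisons between samples use the exact
conditional binomial test for two Poisson rates (count in A given the total
is Binomial with the length share as the null proportion), with
Benjamini–Hochberg adjustment across feature classes. The test choice is a
package decision: published per-feature fold-changes rarely name their test,
so printed p-values elsewhere are not treated as reproducible targets.

## Impact scoring (B / H / combined)

* **B score:** B = −Σ min(s(Ref, Alt), 0) over missense substitutions, with
  s from the BLOSUM100 matrix (embedded verbatim from the NCBI distribution,
  1/3-bit units, provenance header retained). Negative log-odds mark
  exchanges that are rare among near-identical proteins and therefore more
  likely to be functionally consequential; frequent exchanges contribute 0.
* **H score:** H = −Σ log₂ pₖ over substitutions exactly matching a hotspot
  table entry (gene, ref residue, position, alt residue). A position-only
  matching mode (gene, position) is available behind a flag and uses the
  smallest p-value at the residue; the exact key is the default because
  hotspot lists are residue-change specific.
* **Combined:** tanh(B + H), a standardized score from 0 toward 1.

Properties (all machine-tested): scores are nonnegative, additive over
substitutions, permutation-invariant, monotone under profile growth, and
gene-set restriction equals profile intersection. Repeated identical
substitutions each contribute — the sums run over occurrences, with no
de-duplication. One numerical caveat: in double precision `tanh(x)` reaches
exactly 1.0 once x ≳ 19, so heavily mutated samples score exactly 1.0 rather
than strictly below it; the documented [0, 1] range is exact.

Ambiguity codes (B, Z, X) and stop (*) are rejected by the scorer: stop
gains are nonsense, not missense, and never reach scoring.

## CNV calling

Segments carry log₂ copy ratios versus the reference sample. A segment is a
gain when log₂ ratio > 0.85 and a loss below −0.85 — "absolute copy ratio
exceeding 0.85" is read on the log₂ scale, the native statistic of
segment-based copy callers; a raw-ratio reading would call nearly every
segment and cannot be what a stringent cutoff means. The threshold applies
to segment means (segment-level application is the package's documented
choice). Per-gene copy log₂FC is the length-weighted mean of overlapping
segments over the gene body — a weighted mean, not a max, because the
quantity of interest is the average dosage across the gene.

## Chromatin accessibility

* **DAR statistics** can be supplied by any caller or computed internally:
  depth-normalized counts, two-sided Wilcoxon rank-sum per peak
  (cluster vs rest), BH adjustment, and fold changes on the normalized
  (not log) scale, matching how marker-detection tools report log₂FC.
* **Selection** is strict: FDR < 0.01 AND log₂FC > 0.3; both boundaries
  exclusive exactly as stated.
* **Grouping**: k-means (k = 10 default) with k-means++ initialization,
  25 restarts, fixed seed recorded in output — k-means is not deterministic
  without these choices.
* **Module scores**: per-peak z-scores across cells (degenerate SD-0 peaks
  score 0), set mean minus a size-matched control-set mean, controls drawn
  one-per-peak from 25 quantile bins of mean accessibility (seeded). A random
  peak set scores ~0 by construction.
* **Co-accessibility** is a declared simplification: peak pairs within
  `distance_max` whose binarized accessibility correlates (Pearson) above
  0.05 across cells. It shares only the threshold semantics with
  graphical-lasso co-accessibility networks, which are deliberately not
  re-implemented; the downstream consumer — genes whose 1 kb upstream region
  overlaps a linked peak become candidate targets — is preserved.
* **TF activity** follows the motif-deviation scheme: per cell, the observed
  fraction of counts in a motif's peaks minus the expectation from overall
  peak abundances, z-scored against 50 seeded background peak sets matched
  on mean accessibility. Backgrounds are matched on accessibility only:
  synthetic peaks carry no sequence, so GC matching is out of scope here.
  Motifs are then ranked per focal peak by the Pearson correlation between
  the peak's accessibility and each motif's activity across cells.
  AUC-based marker reporting for DARs is omitted: the contrast such an AUC
  would be computed over is ambiguous, and nothing downstream consumes it.

## Concordance

Per-gene, per-modality patterns are log₂((mean_cond + c)/(mean_ref + c))
vectors across conditions with the reference entry exactly 0; the
pseudocount c defaults to 1 count per cell-mean for stability and is
exposed. Similarity between two patterns is 1/(1 + d) with d the Euclidean
distance — finite at d = 0 (unlike a raw reciprocal 1/d) and strictly
decreasing in d, so every ranking conclusion is unaffected by the bounded
form; this deviation from a literal "inverse of the distance" is deliberate
and documented. Paired two-sided t-tests compare per-gene similarities (raw
similarities, not logs; a flag is not provided because the raw scale is the
documented one — transform upstream if needed). An all-zero difference
vector returns p = 1 rather than a 0/0 NaN.

Peak-shape classification operates on fold-change profiles around peak
centers: center window ±200 bp, flank ±2 kb. `center_specific` requires
center mean > t_hi (0.3) with flank mean < t_lo (0.1); `broad` requires both
above t_hi; anything else is `unchanged`. The thresholds operationalize a
qualitative published distinction (no numeric rule exists in the source
analyses) and are recorded with every call. The published genomic bounds of
the three 20q11.21 sub-regions ship as a default configuration; the
classifier itself is coordinate-agnostic.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with planted truth under one
seeded NumPy generator (fixed config ⇒ byte-identical files):

* **Paired variants** — planted somatic records: true VAF ~ Beta(10, 30)
  (mean 0.25, a subclonal load; the source study reports no VAF
  distribution, so this default is a declared assumption), depth = 20 +
  Poisson(15), alt reads Binomial(depth, VAF). Contaminants each violate
  exactly one criterion: germline-like records have VAF ~ N(0.5, 0.03)
  truncated to [0, 1]. Constraints are enforced by seeded rejection
  resampling so every record's manifest fate is exact rather than
  probabilistic; the resampling only redraws read counts, leaving the Beta
  law of true VAFs intact (KS-tested).
* **Genome/annotation** — random sequence; toy genes with 100 bp 5′UTR,
  three 120 bp CDS exons (length divisible by 3), 400 bp introns, 150 bp
  3′UTR, alternating strands.
* **Copy segments** — a planted gain locus (log₂ 0.9, a 20q11.21-like
  event) in the late conditions. Segment noise is per-bin SD (default 0.1)
  divided by √bins with 1 kb bins, because a segment's reported ratio is a
  mean over coverage bins; segment-level noise therefore shrinks with
  segment length, which is what makes a 0.9 gain reliably separable at the
  0.85 cutoff.
* **Count matrices** — negative binomial (variance m + φm², shared
  dispersion φ = 0.3) over four conditions (reference + three passages, 150
  cells each by default). ATAC signal of every in-locus gene scales with DNA
  content (2^0.9); *concordant* genes get an extra epigenetic boost
  (`locus_effect`, default 2×) applied equally to accessibility and
  expression, while *copy-only* genes get no expression response. This is
  the biology under test: expression follows chromatin state, not copy
  number alone — so accessibility–expression similarity is high exactly for
  the epigenetically activated genes, and copy–expression similarity is low
  for the copy-only genes.
* **Driver TF** — one motif maps exactly onto the epigenetically boosted
  peaks; decoys map to random unboosted peaks.

Not emulated: read-level data (FASTQ/BAM), linked mates or fragment-length
structure, GC and mappability biases, doublets and empty droplets, realistic
nucleosome or promoter architecture, clonal substructure, or trajectory
dynamics. Passing tests therefore demonstrate the correctness and
calibration of the computations under a faithful statistical skeleton of the
experiment — not performance on raw sequencing artifacts, which upstream
callers (aligners, Mutect2-class callers, Cell Ranger, peak callers) are
responsible for.

## Problem sizes and numerical choices

Test and validation runs use desk-scale sizes chosen to give each check
adequate statistical power: 50 planted-pass + 60 contaminant variant records
for filter-oracle equivalence; ~2,000 SNVs over a 2 Mb toy genome for the
3× intron-vs-exon burden recovery (standard error of the log-ratio ≈ 0.08,
comfortably inside the 20% band); 2,000 null replicates for rate-test
calibration; 600 cells (4 × 150) for concordance with 30 + 30 planted genes;
100 seeded simulations of 300 cells each for driver-TF identification.
Determinism everywhere flows from explicit seeds: k-means restarts, module
score and chromVAR-style backgrounds, and every generator draw. Degenerate
cases are defined, not special-cased silently: zero-depth VAF is 0,
zero-variance peaks z-score to 0, genes without segment overlap are NaN
(flagged), motifs without peaks are skipped with a warning.

## Known limitations

* The consequence caller handles one transcript model per gene layout well;
  it resolves overlapping transcripts by severity precedence but does not
  implement canonical-transcript ranking, regulatory-region annotation, or
  multi-nucleotide variants.
* The co-accessibility estimator ignores partial correlations; linked pairs
  are marginal associations, not a network model.
* The germline-like criterion is a heuristic; with real data a population
  resource should be supplied via `population_sites`.
* Genome builds are the caller's responsibility: the package is
  genome-agnostic and performs no liftover between assemblies.
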