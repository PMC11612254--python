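# casomics

Genomic and single-cell multi-omics characterization of **culture-adapted
pluripotent stem cells**.

Human pluripotent stem cells kept in culture for years acquire recurrent
genetic lesions — somatic point mutations (often in *TP53*), and copy-number
gains such as the 20q11.21 amplification carrying *BCL2L1* and *TPX2* — plus
epigenetic changes that together produce "culture-adapted" phenotypes
(survival advantage, abnormal mitosis). Assessing these lesions from paired
whole-genome, scRNA-seq and scATAC-seq data requires a chain of bespoke
computations that are usually buried in one-off analysis scripts. `casomics`
packages that chain as a tested, reusable library and CLI for researchers who
monitor stem-cell line integrity:

* **Somatic SNV filtering** — six high-confidence criteria applied to
  paired variant calls (test passage vs isogenic early-passage reference):
  reference VAF 0, biallelic SNV, depth ≥ 20, alt depth ≥ 3, exclusion of
  germline-like heterozygous VAFs, exclusion of X/Y; plus collapsed
  substitution spectra (C>A, C>G, C>T, T>A, T>C, T>G).
* **Consequence and burden** — a minimal codon-aware consequence caller
  (missense/nonsense/synonymous/splice-site) and length-normalized mutation
  rates per feature class (exon, intron, intergenic), compared between
  samples with an exact conditional rate-ratio test.
* **Tumorigenic-impact scoring** — per sample and gene set
  (e.g. a TP53-interaction network → "T score", COSMIC Tier 1 → "C score"):

      B = −Σᵢ min(BLOSUM100(Refᵢ, Altᵢ), 0)         (rarity of exchanges)
      H = −Σₖ log₂ pₖ   over hotspot-matched sites  (published hotspot p-values)
      score = tanh(B + H) ∈ [0, 1]

* **CNV calling** — gains/losses from copy-ratio segments at |log₂ ratio| >
  0.85 and per-gene copy log₂ fold-changes (length-weighted over gene bodies).
* **Chromatin accessibility post-processing** — DAR selection (FDR < 0.01,
  log₂FC > 0.3), k-means DAR grouping (k = 10), background-corrected module
  scores, correlation-based co-accessibility links (> 0.05) with 1 kb-upstream
  target-gene assignment, and motif-deviation TF activity scores ranked by
  per-peak Pearson correlation.
* **Locus concordance** — per-gene log₂FC patterns for CNV/ATAC/RNA,
  inverse-Euclidean similarity 1/(1 + d), paired t-tests (does expression
  track chromatin state or copy number?), and peak-shape classification
  (center-specific vs broad vs unchanged).

A synthetic-data module generates every input with planted ground truth
(filter fates, a 20q11.21-like gain, concordant vs copy-only genes, a driver
TF), so the whole pipeline runs and is validated without any external data.

## Worked example: impact scores

```python
from casomics import (HotspotTable, MutationProfile, Substitution,
                      load_blosum100, score_samples)

matrix = load_blosum100()
hotspots = HotspotTable({("TP53", "R", 175, "H"): 0.25})
profile = MutationProfile(
    sample_id="P4",
    substitutions=(
        Substitution("TP53", "R", 175, "H"),   # hotspot; BLOSUM100 score -1
        Substitution("KRAS", "G", 12, "D"),    # BLOSUM100 score -4
        Substitution("BRD4", "M", 7, "L"),     # BLOSUM100 score +3
    ),
)
scores, ledger = score_samples(
    [profile], matrix, hotspots,
    gene_sets={"tp53_network": {"TP53"}, "cosmic_tier1": {"TP53", "KRAS", "BRD4"}},
)
print(scores.to_string(index=False))
```

prints

```
sample     gene_set  b_score  h_score  combined
    P4 cosmic_tier1      5.0      2.0  0.999998
    P4 tp53_network      1.0      2.0  0.995055
```

Reading the rows: restricted to the TP53 network, only R175H counts — its
rare-exchange contribution is 1 (−(−1)) and its hotspot contribution is
−log₂ 0.25 = 2, so the combined score is tanh(3) ≈ 0.995. Over the wider
set, G12D adds 4 more to B (BLOSUM100 −4) while the conservative M7L
exchange (+3) adds nothing; scores closer to 1 indicate a heavier load of
rare and hotspot missense changes.

## End-to-end demo on synthetic data

```bash
cas run --seed 7 --outdir demo_run
```

simulates a paired VCF, annotated toy genome, copy segments, ATAC/RNA count
matrices and a hotspot table, then runs every stage (filter → burden → score
→ cnv → atac → concord), writing per-stage TSVs and a provenance manifest of
file hashes; a rerun with the same seed reproduces the manifest exactly.
Individual stages are available as `cas simulate | filter | burden | score |
cnv | atac | concord`.

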