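"""Variant consequence calling and length-normalized mutation burden.

Each passing SNV is assigned a genomic feature class (exon/CDS, 5'/3' UTR,
intron, intergenic; precedence exon > UTR > intron > intergenic when
transcripts disagree) and, for CDS hits, a coding consequence obtained by
mutating the codon in transcript orientation and translating. Burdens are
SNV counts divided by the merged (non-overlapping) base-pair length of each
feature class, as in per-feature mutation-frequency comparisons; UTRs are
merged into the exonic territory for rate tables but reported separately in
count tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, merge_intervals, subtract_intervals
from .io import GeneModel, Transcript, VariantRecord

SPLICE_WINDOW = 2  # bases of intron adjacent to an exon boundary

FEATURE_CLASSES = ("intergenic", "intron", "exon", "utr5", "utr3")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ConsequenceCall:
    variant_id: str
    chrom: str
    feature_class: str  # intergenic | intron | exon | utr5 | utr3
    coding_consequence: str  # missense | nonsense | synonymous | splice_site | non_coding | none
    gene: str = ""
    transcript: str = ""
    aa_ref: str = ""
    aa_pos: int = 0
    aa_alt: str = ""

    @property
    def aa_change(self) -> str:
        if self.coding_consequence in {"missense", "nonsense", "synonymous"}:
            return f"{self.aa_ref}{self.aa_pos}{self.aa_alt}"
        return ""


@dataclass(frozen=True)
class FeatureBurden:
    feature_class: str
    snv_count: int
    feature_length: int  # merged, non-overlapping bp
    @property
    def rate(self) -> float:
        return self.snv_count / self.feature_length


# ---------------------------------------------------------------------------
# Consequence calling
# ---------------------------------------------------------------------------


def _cds_positions(tx: Transcript) -> list[int]:
    """Genomic 0-based positions of the CDS in transcription order."""
    pos = [p for iv in tx.cds for p in range(iv.start, iv.end)]
    return pos[::-1] if tx.strand == "-" else pos


def _classify_in_transcript(tx: Transcript, pos0: int) -> str | None:
    """Feature of pos0 within one transcript: cds/utr5/utr3/splice/intron, or
    None when outside all exons and introns of the transcript."""
    for iv in tx.cds:
        if iv.start <= pos0 < iv.end:
            return "cds"
    for iv in tx.utr5:
        if iv.start <= pos0 < iv.end:
            return "utr5"
    for iv in tx.utr3:
        if iv.start <= pos0 < iv.end:
            return "utr3"
    for iv in tx.introns():
        if iv.start <= pos0 < iv.end:
            near = pos0 < iv.start + SPLICE_WINDOW or pos0 >= iv.end - SPLICE_WINDOW
            return "splice" if near else "intron"
    return None


_SEVERITY = {"cds": 0, "splice": 1, "utr5": 2, "utr3": 2, "intron": 3}


def call_consequence(
    variant: VariantRecord,
    genes: Sequence[GeneModel],
    genome: dict[str, str],
) -> ConsequenceCall:
    """Assign feature class and coding consequence to a biallelic SNV.

    The CDS codon is mutated in transcript orientation (reverse-complemented
    on the minus strand) and translated; a variant whose ref allele does not
    match the genome at its position is rejected.
    """
    if not variant.is_biallelic_snv:
        raise ValueError(f"consequence calling requires biallelic SNVs: {variant.record_id}")
    if variant.chrom not in genome:
        raise KeyError(f"chromosome {variant.chrom} absent from genome")
    pos0 = variant.pos0
    ref_base = genome[variant.chrom][pos0]
    if ref_base != variant.ref:
        raise ValueError(
            f"{variant.record_id}: ref allele {variant.ref} inconsistent with "
            f"genome base {ref_base}"
        )

    hits: list[tuple[int, Transcript, str]] = []
    for gene in genes:
        if gene.chrom != variant.chrom or not (gene.start <= pos0 < gene.end):
            continue
        for tx in gene.transcripts:
            kind = _classify_in_transcript(tx, pos0)
            if kind is not None:
                hits.append((_SEVERITY[kind], tx, kind))
    if not hits:
        return ConsequenceCall(
            variant_id=variant.record_id, chrom=variant.chrom,
            feature_class="intergenic", coding_consequence="none",
        )
    hits.sort(key=lambda h: h[0])
    _, tx, kind = hits[0]

    if kind == "splice":
        return ConsequenceCall(
            variant_id=variant.record_id, chrom=variant.chrom,
            feature_class="intron", coding_consequence="splice_site",
            gene=tx.gene_id, transcript=tx.transcript_id,
        )
    if kind in {"utr5", "utr3", "intron"}:
        return ConsequenceCall(
            variant_id=variant.record_id, chrom=variant.chrom,
            feature_class=kind if kind != "intron" else "intron",
            coding_consequence="non_coding",
            gene=tx.gene_id, transcript=tx.transcript_id,
        )

    # CDS hit: translate the mutated codon in transcript orientation
    if tx.cds_length % 3 != 0:
        raise ValueError(f"CDS length of {tx.transcript_id} not divisible by 3")
    positions = _cds_positions(tx)
    offset = positions.index(pos0)
    codon_idx, within = divmod(offset, 3)
    codon_pos = positions[codon_idx * 3: codon_idx * 3 + 3]
    bases = [genome[variant.chrom][p] for p in codon_pos]
    alt_base = variant.alts[0]
    if tx.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_base = alt_base.translate(_COMPLEMENT)
    ref_codon = "".join(bases)
    alt_codon_list = list(bases)
    alt_codon_list[within] = alt_base
    alt_codon = "".join(alt_codon_list)
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_alt == "*" and aa_ref != "*":
        consequence = "nonsense"
    elif aa_alt == aa_ref:
        consequence = "synonymous"
    else:
        consequence = "missense"
    return ConsequenceCall(
        variant_id=variant.record_id, chrom=variant.chrom,
        feature_class="exon", coding_consequence=consequence,
        gene=tx.gene_id, transcript=tx.transcript_id,
        aa_ref=aa_ref, aa_pos=codon_idx + 1, aa_alt=aa_alt,
    )


# ---------------------------------------------------------------------------
# Feature territories and burden
# ---------------------------------------------------------------------------


def feature_territories(
    genes: Sequence[GeneModel], genome_lengths: dict[str, int]
) -> dict[str, list[GenomicInterval]]:
    """Merged, non-overlapping territory per feature class.

    ``exon`` covers all exonic bases (CDS and UTRs), ``intron`` is gene body
    minus exons, ``intergenic`` the genome minus gene bodies; ``utr5``/
    ``utr3`` are also reported (they are subsets of ``exon``). Together,
    exon + intron + intergenic partition the genome.
    """
    exons = [iv for g in genes for tx in g.transcripts for iv in tx.exons]
    bodies = [g.body for g in genes]
    chrom_ivs = [
        GenomicInterval(chrom, 0, length) for chrom, length in genome_lengths.items()
    ]
    exon_t = merge_intervals(exons)
    intron_t = subtract_intervals(bodies, exons)
    intergenic_t = subtract_intervals(chrom_ivs, bodies)
    utr5_t = merge_intervals(iv for g in genes for tx in g.transcripts for iv in tx.utr5)
    utr3_t = merge_intervals(iv for g in genes for tx in g.transcripts for iv in tx.utr3)
    return {
        "exon": exon_t,
        "intron": intron_t,
        "intergenic": intergenic_t,
        "utr5": utr5_t,
        "utr3": utr3_t,
    }


@dataclass
class BurdenResult:
    rates: list[FeatureBurden]  # exon (incl. UTR), intron, intergenic
    counts_by_class: pd.Series  # per called feature class (UTRs separate)
    counts_by_consequence: pd.Series
    per_chromosome: pd.DataFrame  # chrom x feature_class counts

    def rates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"feature_class": b.feature_class, "snv_count": b.snv_count,
                 "feature_length": b.feature_length, "rate": b.rate}
                for b in self.rates
            ]
        )


def burden_table(
    calls: Sequence[ConsequenceCall],
    genes: Sequence[GeneModel],
    genome_lengths: dict[str, int],
) -> BurdenResult:
    """Length-normalized burden per feature class plus per-chromosome counts."""
    territories = feature_territories(genes, genome_lengths)
    lengths = {
        cls: sum(len(iv) for iv in ivs) for cls, ivs in territories.items()
    }
    if lengths["exon"] + lengths["intron"] + lengths["intergenic"] == 0:
        raise ValueError("zero total feature length; annotation or genome empty")

    df = pd.DataFrame(
        [
            {"variant_id": c.variant_id, "chrom": c.chrom,
             "feature_class": c.feature_class,
             "coding_consequence": c.coding_consequence}
            for c in calls
        ],
        columns=["variant_id", "chrom", "feature_class", "coding_consequence"],
    )
    # rate classes merge UTRs into the exonic territory
    rate_class = df["feature_class"].replace({"utr5": "exon", "utr3": "exon"})
    rates = []
    for cls in ("exon", "intron", "intergenic"):
        if lengths[cls] == 0:
            raise ValueError(f"feature class {cls} has zero merged length")
        rates.append(
            FeatureBurden(
                feature_class=cls,
                snv_count=int((rate_class == cls).sum()),
                feature_length=lengths[cls],
            )
        )
    counts_by_class = (
        df["feature_class"].value_counts().reindex(FEATURE_CLASSES, fill_value=0)
    )
    counts_by_consequence = df["coding_consequence"].value_counts()
    per_chrom = (
        df.groupby(["chrom", "feature_class"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )
    return BurdenResult(
        rates=rates,
        counts_by_class=counts_by_class,
        counts_by_consequence=counts_by_consequence,
        per_chromosome=per_chrom,
    )


def compare_burdens(
    burden_a: Sequence[FeatureBurden], burden_b: Sequence[FeatureBurden]
) -> pd.DataFrame:
    """Rate ratio (A/B) and exact rate-ratio p-value per feature class.

    Under equal rates, the count in A given the total n = nA + nB is
    Binomial(n, LA/(LA+LB)) with the feature lengths as exposures — the
    exact conditional (binomial) test for two Poisson rates. P-values are
    Benjamini-Hochberg adjusted across classes. Classes with zero counts in
    both samples get an undefined ratio and are flagged.
    """
    by_class_b = {b.feature_class: b for b in burden_b}
    rows = []
    for a in burden_a:
        if a.feature_class not in by_class_b:
            raise KeyError(f"feature class {a.feature_class} missing from burden B")
        b = by_class_b[a.feature_class]
        n = a.snv_count + b.snv_count
        p0 = a.feature_length / (a.feature_length + b.feature_length)
        if n == 0:
            rows.append(
                {"feature_class": a.feature_class, "count_a": 0, "count_b": 0,
                 "ratio": np.nan, "p_value": np.nan, "undefined": True}
            )
            continue
        ratio = a.rate / b.rate if b.snv_count > 0 else np.inf
        pval = stats.binomtest(a.snv_count, n, p0, alternative="two-sided").pvalue
        rows.append(
            {"feature_class": a.feature_class, "count_a": a.snv_count,
             "count_b": b.snv_count, "ratio": ratio, "p_value": pval,
             "undefined": False}
        )
    out = pd.DataFrame(rows)
    defined = ~out["undefined"]
    out["q_value"] = np.nan
    if defined.any():
        out.loc[defined, "q_value"] = multipletests(
            out.loc[defined, "p_value"], method="fdr_bh"
        )[1]
    return out
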