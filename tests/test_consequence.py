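"""Consequence calling against a full-transcript retranslation oracle,
feature territories, and burden statistics."""

import numpy as np
import pytest
from Bio.Seq import Seq

from casomics.consequence import (
    FeatureBurden,
    burden_table,
    call_consequence,
    compare_burdens,
    feature_territories,
)
from casomics.intervals import GenomicInterval
from casomics.io import GeneModel, SampleCall, Transcript, VariantRecord
from casomics.simulate import simulate_genome


def snv(chrom, pos0, ref, alt):
    return VariantRecord(
        chrom=chrom, pos=pos0 + 1, ref=ref, alts=(alt,),
        calls={"P4": SampleCall(30, 10), "P1": SampleCall(30, 0)},
    )


def single_exon_gene(chrom, cds_start, cds_len, strand):
    iv = GenomicInterval(chrom, cds_start, cds_start + cds_len, strand)
    tx = Transcript(
        transcript_id="t1", gene_id="g1", chrom=chrom, strand=strand,
        exons=[iv], cds=[iv],
    )
    return GeneModel(gene_id="g1", chrom=chrom, start=iv.start, end=iv.end,
                     strand=strand, transcripts=[tx])


class TestCodonExamples:
    # CDS 'ATG TGG GGA TAA' starting at offset 10 on the plus strand
    GENOME = {"t1": "A" * 10 + "ATGTGGGGATAA" + "A" * 10}
    GENE = single_exon_gene("t1", 10, 12, "+")

    def test_stop_gain_is_nonsense(self):
        call = call_consequence(snv("t1", 15, "G", "A"), [self.GENE], self.GENOME)
        assert call.coding_consequence == "nonsense"
        assert call.aa_change == "W2*"

    def test_third_position_wobble_is_synonymous(self):
        call = call_consequence(snv("t1", 18, "A", "G"), [self.GENE], self.GENOME)
        assert call.coding_consequence == "synonymous"
        assert (call.aa_ref, call.aa_pos, call.aa_alt) == ("G", 3, "G")

    def test_missense(self):
        # TGG -> TCG: W2S
        call = call_consequence(snv("t1", 14, "G", "C"), [self.GENE], self.GENOME)
        assert call.coding_consequence == "missense"
        assert call.aa_change == "W2S"

    def test_minus_strand_codon_orientation(self):
        # genomic TTATCCCCACAT reverse-complements to CDS ATGTGGGGATAA
        genome = {"t2": "C" * 30 + "TTATCCCCACAT" + "C" * 10}
        gene = single_exon_gene("t2", 30, 12, "-")
        call = call_consequence(snv("t2", 36, "C", "T"), [gene], genome)
        assert call.coding_consequence == "nonsense"
        assert call.aa_change == "W2*"

    def test_ref_mismatch_is_error(self):
        with pytest.raises(ValueError, match="inconsistent"):
            call_consequence(snv("t1", 15, "T", "A"), [self.GENE], self.GENOME)

    def test_intergenic(self):
        call = call_consequence(snv("t1", 2, "A", "G"), [self.GENE], self.GENOME)
        assert call.feature_class == "intergenic"
        assert call.coding_consequence == "none"


class TestSpliceAndFeatures:
    @pytest.fixture()
    def toy(self):
        chrom = "t3"
        exon1 = GenomicInterval(chrom, 10, 22, "+")   # 12 bp CDS
        intron = (22, 52)
        exon2 = GenomicInterval(chrom, 52, 64, "+")
        tx = Transcript(
            transcript_id="t1", gene_id="g1", chrom=chrom, strand="+",
            exons=[exon1, exon2], cds=[exon1, exon2],
        )
        gene = GeneModel(gene_id="g1", chrom=chrom, start=10, end=64, strand="+",
                         transcripts=[tx])
        genome = {chrom: "ATGTGGGGATAAATGTGGGGATAAATGTGGGGATAAATGTGGGGATAAATGTGGGGATAAATGTGGGGATAA"}
        return gene, genome, intron

    def test_intron_edge_is_splice_site(self, toy):
        gene, genome, intron = toy
        for pos0 in (intron[0], intron[0] + 1, intron[1] - 2, intron[1] - 1):
            ref = genome[gene.chrom][pos0]
            alt = "A" if ref != "A" else "G"
            call = call_consequence(snv(gene.chrom, pos0, ref, alt), [gene], genome)
            assert call.coding_consequence == "splice_site", pos0
            assert call.feature_class == "intron"

    def test_deep_intron_is_non_coding(self, toy):
        gene, genome, intron = toy
        pos0 = (intron[0] + intron[1]) // 2
        ref = genome[gene.chrom][pos0]
        call = call_consequence(
            snv(gene.chrom, pos0, ref, "A" if ref != "A" else "G"), [gene], genome
        )
        assert call.feature_class == "intron"
        assert call.coding_consequence == "non_coding"

    def test_utr_classes_on_generator_genes(self, multiomics):
        gene = multiomics.genes[0]
        tx = gene.transcripts[0]
        for utr, label in ((tx.utr5[0], "utr5"), (tx.utr3[0], "utr3")):
            pos0 = (utr.start + utr.end) // 2
            ref = multiomics.genome[gene.chrom][pos0]
            call = call_consequence(
                snv(gene.chrom, pos0, ref, "A" if ref != "A" else "G"),
                multiomics.genes, multiomics.genome,
            )
            assert call.feature_class == label
            assert call.coding_consequence == "non_coding"


class TestRetranslationOracle:
    def test_random_cds_snvs_agree_with_full_protein_retranslation(self, multiomics, rng):
        """The per-codon caller must agree with translating the whole mutated
        CDS and diffing proteins."""
        genome, genes = multiomics.genome, multiomics.genes
        checked = 0
        for gene in genes[:20]:
            tx = gene.transcripts[0]
            cds_pos = [p for iv in tx.cds for p in range(iv.start, iv.end)]
            if tx.strand == "-":
                cds_pos = cds_pos[::-1]
            for _ in range(5):
                offset = int(rng.integers(len(cds_pos)))
                pos0 = cds_pos[offset]
                ref = genome[gene.chrom][pos0]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                call = call_consequence(snv(gene.chrom, pos0, ref, alt), genes, genome)

                # oracle: mutate the chromosome, re-extract and translate the CDS
                mutated = (genome[gene.chrom][:pos0] + alt
                           + genome[gene.chrom][pos0 + 1:])
                def protein(chrom_seq):
                    cds = "".join(
                        chrom_seq[iv.start:iv.end] for iv in tx.cds
                    )
                    if tx.strand == "-":
                        cds = str(Seq(cds).reverse_complement())
                    return str(Seq(cds).translate())
                p_ref, p_alt = protein(genome[gene.chrom]), protein(mutated)
                diffs = [i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
                if not diffs:
                    assert call.coding_consequence == "synonymous"
                else:
                    (i,) = diffs
                    assert call.aa_pos == i + 1
                    assert (call.aa_ref, call.aa_alt) == (p_ref[i], p_alt[i])
                    expected = "nonsense" if p_alt[i] == "*" else "missense"
                    assert call.coding_consequence == expected
                checked += 1
        assert checked == 100


class TestBurden:
    def test_rate_arithmetic(self):
        burden = FeatureBurden("exon", 10, 1_000_000)
        assert burden.rate == pytest.approx(1e-5)

    def test_territories_partition_genome(self, multiomics):
        lengths = {c: len(s) for c, s in multiomics.genome.items() if c != "chrX"}
        terr = feature_territories(multiomics.genes, lengths)
        covered = sum(
            sum(len(iv) for iv in terr[c]) for c in ("exon", "intron", "intergenic")
        )
        assert covered == sum(lengths.values())

    def test_no_snvs_gives_zero_rates(self, multiomics):
        lengths = {c: len(s) for c, s in multiomics.genome.items() if c != "chrX"}
        result = burden_table([], multiomics.genes, lengths)
        assert all(b.rate == 0 for b in result.rates)

    def test_burden_counts_and_chromosome_table(self, multiomics):
        genome, genes = multiomics.genome, multiomics.genes
        lengths = {c: len(s) for c, s in genome.items() if c != "chrX"}
        gene = genes[0]
        tx = gene.transcripts[0]
        variants = []
        for iv, n in ((tx.cds[0], 3), (tx.utr5[0], 2), (tx.introns()[0], 1)):
            for i in range(n):
                pos0 = iv.start + 5 + i  # clear of splice windows
                ref = genome[gene.chrom][pos0]
                alt = "A" if ref != "A" else "G"
                variants.append(snv(gene.chrom, pos0, ref, alt))
        calls = [call_consequence(v, genes, genome) for v in variants]
        result = burden_table(calls, genes, lengths)
        counts = result.counts_by_class
        utr_label = "utr5" if gene.strand == "+" else "utr3"
        assert counts["exon"] == 3 and counts[utr_label] == 2 and counts["intron"] == 1
        # UTR SNVs merge into the exon class for rates
        exon_rate = next(b for b in result.rates if b.feature_class == "exon")
        assert exon_rate.snv_count == 5
        assert result.per_chromosome.loc[gene.chrom].sum() == 6


class TestCompareBurdens:
    def test_ratio_arithmetic(self):
        out = compare_burdens(
            [FeatureBurden("exon", 40, 1000)], [FeatureBurden("exon", 10, 1000)]
        )
        assert out.loc[0, "ratio"] == pytest.approx(4.0)

    def test_identical_burdens(self):
        a = [FeatureBurden("exon", 25, 1000)]
        out = compare_burdens(a, a)
        assert out.loc[0, "ratio"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_p_value_matches_brute_force_tail_sum(self):
        """Exact conditional test vs direct enumeration of the binomial tail
        at p0 = 0.5 (equal exposures)."""
        from scipy.stats import binom

        nA, nB = 40, 10
        out = compare_burdens(
            [FeatureBurden("exon", nA, 1000)], [FeatureBurden("exon", nB, 1000)]
        )
        n = nA + nB
        pmf = [binom.pmf(k, n, 0.5) for k in range(n + 1)]
        expected = sum(p for p in pmf if p <= pmf[nA] * (1 + 1e-9))
        assert out.loc[0, "p_value"] == pytest.approx(expected, rel=1e-6)

    def test_zero_counts_flagged_undefined(self):
        out = compare_burdens(
            [FeatureBurden("exon", 0, 1000)], [FeatureBurden("exon", 0, 1000)]
        )
        assert bool(out.loc[0, "undefined"]) and np.isnan(out.loc[0, "ratio"])

    def test_bh_adjustment_across_classes(self):
        a = [FeatureBurden("exon", 40, 1000), FeatureBurden("intron", 12, 1000)]
        b = [FeatureBurden("exon", 10, 1000), FeatureBurden("intron", 10, 1000)]
        out = compare_burdens(a, b).set_index("feature_class")
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()
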