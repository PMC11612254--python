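"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a paired whole-genome
plus single-cell multi-omics experiment on an isogenic stem-cell line:

* a paired VCF (early-passage reference sample vs late-passage test sample)
  with planted somatic SNVs and contaminants that each violate exactly one
  of the six high-confidence filter criteria;
* a toy annotated genome (genes with UTRs, multi-exon CDS, both strands);
* copy-ratio segments with a planted gain locus (a 20q11.21-like event);
* ATAC and RNA cell-by-feature count matrices in which genes inside the
  gain locus are amplified, and a subset is additionally epigenetically
  activated ("concordant" genes) in late-passage cells;
* a hotspot-mutation p-value table.

Noise model: read sampling is binomial given a Beta-distributed true VAF
with shifted-Poisson depths; counts are negative-binomial with a shared
dispersion. All randomness flows through one seeded NumPy generator, so a
fixed config yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .intervals import GenomicInterval
from .io import (
    CellMatrix,
    GeneModel,
    SampleCall,
    Transcript,
    VariantRecord,
)

CRITERIA = ("ref_vaf", "biallelic", "depth", "alt_depth", "germline_like", "sex_chrom")

_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Configuration and manifest
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All knobs for the synthetic experiment; defaults are the study
    conditions the pipeline is validated under."""

    seed: int = 0

    # genome / annotation
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_background_genes: int = 24

    # paired variant simulation
    ref_sample: str = "P1"
    test_sample: str = "P4"
    n_planted_somatic: int = 50
    contaminants_per_criterion: int = 10
    somatic_vaf_beta: tuple[float, float] = (10.0, 30.0)  # mean 0.25, subclonal
    depth_base: int = 20
    depth_extra_poisson: float = 15.0
    het_band: tuple[float, float] = (0.40, 0.60)

    # burden simulation (mutations per bp by feature class)
    mutation_rates: dict = field(
        default_factory=lambda: {"exon": 1e-5, "intron": 3e-5, "intergenic": 2e-5}
    )

    # copy-number / multi-omics
    conditions: tuple[str, ...] = ("P1", "P2", "P3", "P4")
    effect_conditions: tuple[str, ...] = ("P3", "P4")
    gain_chrom: str = "chr1"
    gain_start: int = 600_000
    gain_end: int = 900_000
    gain_log2: float = 0.9
    segment_noise_sd: float = 0.1  # per-bin SD; segment means average over bins
    cnv_bin_size: int = 1_000  # WGS-scale coverage bins
    n_neutral_segments: int = 20
    n_concordant_genes: int = 8
    n_copy_only_genes: int = 8
    n_cells_per_condition: int = 150
    locus_effect: float = 2.0  # epigenetic fold-change on concordant genes
    atac_mean: float = 8.0
    rna_mean: float = 10.0
    nb_dispersion: float = 0.3
    n_background_peaks: int = 100
    n_decoy_tfs: int = 5

    # hotspot table
    n_hotspots: int = 20
    planted_hotspots: tuple = (("TP53", "R", 175, "H", 0.25),)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for name, rate in self.mutation_rates.items():
            if rate < 0:
                raise ValueError(f"mutation rate for {name} must be >= 0")
        if not (self.gain_start < self.gain_end <= self.chrom_length):
            raise ValueError("gain locus must lie within its chromosome")
        if self.gain_chrom not in self.chromosomes:
            raise ValueError(f"gain_chrom {self.gain_chrom} outside the simulated genome")
        if self.locus_effect <= 0:
            raise ValueError("locus_effect must be > 0")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def gain_locus(self) -> GenomicInterval:
        return GenomicInterval(self.gain_chrom, self.gain_start, self.gain_end)


@dataclass
class TruthManifest:
    """Planted ground truth; every generated record appears exactly once."""

    seed: int
    variants: pd.DataFrame | None = None  # record_id, chrom, pos, fate, true_vaf
    gain_segments: pd.DataFrame | None = None
    concordant_genes: list[str] = field(default_factory=list)
    copy_only_genes: list[str] = field(default_factory=list)
    background_genes: list[str] = field(default_factory=list)
    driver_tf: str = ""
    motif_peaks: dict[str, list[str]] = field(default_factory=dict)
    hotspots: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "seed": self.seed,
            "concordant_genes": self.concordant_genes,
            "copy_only_genes": self.copy_only_genes,
            "background_genes": self.background_genes,
            "driver_tf": self.driver_tf,
            "motif_peaks": self.motif_peaks,
        }
        (outdir / "manifest.json").write_text(json.dumps(meta, indent=2) + "\n")
        for name, df in (
            ("variants", self.variants),
            ("gain_segments", self.gain_segments),
            ("hotspots", self.hotspots),
        ):
            if df is not None:
                df.to_csv(outdir / f"manifest_{name}.tsv", sep="\t", index=False,
                          lineterminator="\n")


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------


def _gene_model(
    gene_id: str, chrom: str, tss: int, strand: str, n_cds_exons: int = 3
) -> GeneModel:
    """Deterministic toy gene: 100 bp 5'UTR, `n_cds_exons` x 120 bp CDS exons
    separated by 400 bp introns, 150 bp 3'UTR. Laid out left-to-right in
    genomic coordinates; strand only affects transcription orientation."""
    utr5_len, cds_len, intron_len, utr3_len = 100, 120, 400, 150
    pos = tss
    left_utr = GenomicInterval(chrom, pos, pos + utr5_len, strand)
    pos += utr5_len
    cds = []
    exons = []
    for i in range(n_cds_exons):
        iv = GenomicInterval(chrom, pos, pos + cds_len, strand)
        cds.append(iv)
        pos += cds_len
        if i < n_cds_exons - 1:
            pos += intron_len
    right_utr = GenomicInterval(chrom, pos, pos + utr3_len, strand)
    pos += utr3_len
    # exons: UTRs are part of terminal exons
    exons = [GenomicInterval(chrom, left_utr.start, cds[0].end, strand)]
    exons += cds[1:-1] if n_cds_exons > 2 else []
    if n_cds_exons > 1:
        exons.append(GenomicInterval(chrom, cds[-1].start, right_utr.end, strand))
    else:
        exons = [GenomicInterval(chrom, left_utr.start, right_utr.end, strand)]
    utr5, utr3 = (left_utr, right_utr) if strand != "-" else (right_utr, left_utr)
    tx = Transcript(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds,
        utr5=[utr5],
        utr3=[utr3],
    )
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=left_utr.start, end=right_utr.end,
        strand=strand, transcripts=[tx],
    )


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome sequence plus a deterministic gene layout.

    In-locus genes (concordant then copy-only) are placed inside the gain
    locus; background genes fill the rest of the genome. CDS lengths are
    multiples of 3 by construction.
    """
    rng = rng or np.random.default_rng(config.seed)
    genome = {
        chrom: "".join(rng.choice(_BASES, size=config.chrom_length))
        for chrom in config.chromosomes
    }
    # sex chromosome present only for contaminant placement (no genes)
    genome["chrX"] = "".join(rng.choice(_BASES, size=min(100_000, config.chrom_length)))

    genes: list[GeneModel] = []
    footprint = 100 + 3 * 120 + 2 * 400 + 150  # ~1410 bp per toy gene
    spacing = footprint + 2_000

    n_locus = config.n_concordant_genes + config.n_copy_only_genes
    locus_len = config.gain_end - config.gain_start
    if n_locus * spacing > locus_len:
        raise ValueError("gain locus too small for the requested in-locus genes")
    for i in range(n_locus):
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            _gene_model(
                f"LOCUS{i + 1:03d}", config.gain_chrom,
                config.gain_start + 1_000 + i * spacing, strand,
            )
        )
    # background genes round-robin over chromosomes, upstream of the locus
    per_chrom_limit = (config.gain_start - 10_000) // spacing
    placed = 0
    for i in range(config.n_background_genes):
        chrom = config.chromosomes[i % config.n_chromosomes]
        slot = i // config.n_chromosomes
        if chrom == config.gain_chrom and slot >= per_chrom_limit:
            continue
        strand = "+" if i % 2 == 0 else "-"
        genes.append(_gene_model(f"GENE{i + 1:03d}", chrom, 5_000 + slot * spacing, strand))
        placed += 1
    return genome, genes


# ---------------------------------------------------------------------------
# Paired variant simulation
# ---------------------------------------------------------------------------


def _nb_counts(rng: np.random.Generator, mean, dispersion: float, size) -> np.ndarray:
    """Negative binomial with mean `mean` and variance mean + dispersion*mean^2."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _draw_positions(
    rng: np.random.Generator, chroms: Sequence[str], length: int, n: int,
    used: set[tuple[str, int]],
) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    while len(out) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, length + 1))  # 1-based
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            out.append((chrom, pos))
    return out


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    return ref, alt


def simulate_variant_pair(
    config: SimulationConfig,
) -> tuple[list[VariantRecord], TruthManifest]:
    """Paired-sample variant calls with planted filter fates.

    Planted somatic records satisfy all six high-confidence criteria
    (reference VAF 0, biallelic SNV, depth >= 20, alt depth >= 3, VAF outside
    the heterozygous band, autosomal). Each contaminant violates exactly the
    one criterion named in its manifest fate. Observed alt depths are
    binomial reads of a Beta-distributed true VAF; constraint enforcement is
    by seeded rejection-resampling so fates are exact, not probabilistic.
    """
    rng = np.random.default_rng(config.seed)
    a, b = config.somatic_vaf_beta
    low, high = config.het_band
    used: set[tuple[str, int]] = set()
    records: list[VariantRecord] = []
    rows: list[dict] = []

    def depth_draw() -> int:
        return config.depth_base + int(rng.poisson(config.depth_extra_poisson))

    def passing_test_call() -> tuple[SampleCall, float]:
        for _ in range(10_000):
            true_vaf = float(rng.beta(a, b))
            depth = depth_draw()
            for _ in range(1_000):
                alt = int(rng.binomial(depth, true_vaf))
                vaf = alt / depth
                if alt >= 3 and not (low <= vaf <= high):
                    return SampleCall(depth, alt), true_vaf
        raise RuntimeError("could not realize a passing somatic call")  # pragma: no cover

    # planted somatic (pass) records
    for chrom, pos in _draw_positions(
        rng, config.chromosomes, config.chrom_length, config.n_planted_somatic, used
    ):
        ref, alt = _random_snv_alleles(rng)
        call, true_vaf = passing_test_call()
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alts=(alt,),
                calls={
                    config.ref_sample: SampleCall(depth_draw(), 0),
                    config.test_sample: call,
                },
            )
        )
        rows.append({"record_id": records[-1].record_id, "chrom": chrom, "pos": pos,
                     "fate": "pass", "true_vaf": true_vaf})

    # contaminants: one record class per criterion, each violating only it
    for criterion in CRITERIA:
        for chrom, pos in _draw_positions(
            rng,
            ["chrX"] if criterion == "sex_chrom" else config.chromosomes,
            min(100_000, config.chrom_length) if criterion == "sex_chrom"
            else config.chrom_length,
            config.contaminants_per_criterion,
            used,
        ):
            ref, alt = _random_snv_alleles(rng)
            alts: tuple[str, ...] = (alt,)
            call, true_vaf = passing_test_call()
            ref_call = SampleCall(depth_draw(), 0)
            if criterion == "ref_vaf":
                rd = depth_draw()
                ref_call = SampleCall(rd, max(1, int(rng.binomial(rd, 0.3))))
            elif criterion == "biallelic":
                second = str(rng.choice([x for x in _BASES if x not in {ref, alt}]))
                alts = (alt, second)
            elif criterion == "depth":
                # depth >= 8 keeps the minimum realizable VAF profile clear of
                # the het band, so only the depth criterion is violated
                depth = int(rng.integers(8, 20))
                for _ in range(1_000):
                    a_ = int(rng.binomial(depth, true_vaf))
                    if a_ >= 3 and not (low <= a_ / depth <= high):
                        call = SampleCall(depth, a_)
                        break
                else:  # pragma: no cover
                    call = SampleCall(depth, 3)
            elif criterion == "alt_depth":
                call = SampleCall(depth_draw(), int(rng.integers(1, 3)))
            elif criterion == "germline_like":
                for _ in range(10_000):
                    depth = depth_draw()
                    tv = float(np.clip(rng.normal(0.5, 0.03), 0.0, 1.0))
                    a_ = int(rng.binomial(depth, tv))
                    if a_ >= 3 and low <= a_ / depth <= high:
                        call, true_vaf = SampleCall(depth, a_), tv
                        break
            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alts=alts,
                    calls={config.ref_sample: ref_call, config.test_sample: call},
                )
            )
            rows.append({"record_id": records[-1].record_id, "chrom": chrom,
                         "pos": pos, "fate": criterion, "true_vaf": true_vaf})

    manifest = TruthManifest(seed=config.seed, variants=pd.DataFrame(rows))
    return records, manifest


def simulate_feature_snvs(
    config: SimulationConfig,
    genome: dict[str, str],
    genes: list[GeneModel],
    total_snvs: int | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Plant passing somatic SNVs by genomic feature class at configured rates.

    Counts per class are Poisson(rate x merged class length); positions are
    uniform within the class territory and reference alleles agree with the
    genome. When `total_snvs` is given, the per-class rates are rescaled so
    the expected total matches it (relative rates preserved).
    """
    from .consequence import feature_territories

    rng = np.random.default_rng(config.seed + 1)
    genome_lengths = {c: len(s) for c, s in genome.items() if c != "chrX"}
    territories = feature_territories(genes, genome_lengths)
    # merged exon territory (CDS + UTR) for rate purposes
    rates = dict(config.mutation_rates)
    lengths = {
        cls: sum(len(iv) for iv in territories[cls]) for cls in rates
    }
    expected = sum(rates[c] * lengths[c] for c in rates)
    scale = (total_snvs / expected) if total_snvs else 1.0

    records: list[VariantRecord] = []
    rows: list[dict] = []
    used: set[tuple[str, int]] = set()
    for cls in sorted(rates):
        ivs = territories[cls]
        cum = np.cumsum([len(iv) for iv in ivs])
        n = int(rng.poisson(rates[cls] * lengths[cls] * scale))
        drawn = 0
        while drawn < n:
            offset = int(rng.integers(cum[-1]))
            k = int(np.searchsorted(cum, offset, side="right"))
            iv = ivs[k]
            pos0 = iv.start + offset - (cum[k - 1] if k else 0)
            key = (iv.chrom, pos0 + 1)
            if key in used:
                continue
            used.add(key)
            ref = genome[iv.chrom][pos0]
            alt = str(rng.choice([x for x in _BASES if x != ref]))
            depth = config.depth_base + int(rng.poisson(config.depth_extra_poisson))
            alt_depth = max(3, int(rng.binomial(depth, 0.25)))
            records.append(
                VariantRecord(
                    chrom=iv.chrom, pos=pos0 + 1, ref=ref, alts=(alt,),
                    calls={
                        config.ref_sample: SampleCall(depth, 0),
                        config.test_sample: SampleCall(depth, alt_depth),
                    },
                )
            )
            rows.append({"record_id": records[-1].record_id, "class": cls})
            drawn += 1
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Multi-omics simulation
# ---------------------------------------------------------------------------


@dataclass
class MultiomicsData:
    genome: dict[str, str]
    genes: list[GeneModel]
    segments: pd.DataFrame  # sample, chrom, start, end, log2_ratio
    atac: CellMatrix
    rna: CellMatrix
    cell_conditions: list[str]
    peak_to_gene: dict[str, str]  # promoter peak id -> gene id
    motif_peaks: dict[str, list[str]]
    manifest: TruthManifest


def simulate_multiomics(config: SimulationConfig) -> MultiomicsData:
    """Copy segments plus ATAC/RNA count matrices with a planted gain locus.

    Genes inside the gain locus carry the configured copy log2 ratio in the
    effect ("late") conditions. ATAC signal of every in-locus gene scales
    with DNA content (2**gain_log2); concordant genes get an additional
    epigenetic boost of `locus_effect` applied equally to accessibility and
    expression, while copy-only genes show no expression response. A driver
    TF's motif maps exactly onto the epigenetically boosted peaks.
    """
    rng = np.random.default_rng(config.seed + 2)
    genome, genes = simulate_genome(config, rng)

    locus_genes = [g.gene_id for g in genes if g.gene_id.startswith("LOCUS")]
    concordant = locus_genes[: config.n_concordant_genes]
    copy_only = locus_genes[config.n_concordant_genes:]
    background = [g.gene_id for g in genes if not g.gene_id.startswith("LOCUS")]
    if config.locus_effect == 1.0:
        concordant, copy_only = [], locus_genes

    # ---- segments ------------------------------------------------------
    seg_rows: list[dict] = []
    locus = config.gain_locus
    for cond in config.conditions:
        is_ref = cond == config.ref_sample
        in_effect = cond in config.effect_conditions
        for chrom in config.chromosomes:
            bounds = np.linspace(0, config.chrom_length, config.n_neutral_segments + 1)
            cuts = sorted({int(x) for x in bounds})
            if chrom == locus.chrom:
                cuts = sorted(set(cuts) | {locus.start, locus.end})
            for s, e in zip(cuts, cuts[1:]):
                inside = chrom == locus.chrom and s >= locus.start and e <= locus.end
                if is_ref:
                    log2 = 0.0
                else:
                    # a segment's log2 ratio is the mean over its coverage
                    # bins, so segment-level noise is per-bin SD / sqrt(bins)
                    n_bins = max(1, (e - s) // config.cnv_bin_size)
                    log2 = float(
                        rng.normal(0.0, config.segment_noise_sd / np.sqrt(n_bins))
                    )
                    if inside and in_effect:
                        log2 += config.gain_log2
                seg_rows.append(
                    {"sample": cond, "chrom": chrom, "start": s, "end": e,
                     "log2_ratio": log2}
                )
    segments = pd.DataFrame(seg_rows)

    # ---- cells ---------------------------------------------------------
    cell_conditions: list[str] = []
    barcodes: list[str] = []
    for cond in config.conditions:
        for i in range(config.n_cells_per_condition):
            cell_conditions.append(cond)
            barcodes.append(f"{cond}_cell{i + 1:04d}")
    n_cells = len(barcodes)
    cond_arr = np.array(cell_conditions)
    late = np.isin(cond_arr, config.effect_conditions)

    copy_fold = 2.0 ** config.gain_log2

    # ---- ATAC: one promoter peak per gene + background peaks -----------
    peak_ids: list[str] = []
    peak_coords: list[GenomicInterval] = []
    peak_to_gene: dict[str, str] = {}
    atac_means = np.full((len(genes) + config.n_background_peaks, n_cells),
                         config.atac_mean)
    for i, g in enumerate(genes):
        tss = g.start if g.strand != "-" else g.end
        start = max(0, tss - 250)
        iv = GenomicInterval(g.chrom, start, start + 500)
        pid = f"{g.chrom}:{iv.start}-{iv.end}"
        peak_ids.append(pid)
        peak_coords.append(iv)
        peak_to_gene[pid] = g.gene_id
        if g.gene_id in concordant:
            atac_means[i, late] *= copy_fold * config.locus_effect
        elif g.gene_id in copy_only:
            atac_means[i, late] *= copy_fold
    for j in range(config.n_background_peaks):
        # background peaks tile inward from the right chromosome end, clear of
        # the gene layout (left) and the gain locus
        chrom = config.chromosomes[j % config.n_chromosomes]
        start = config.chrom_length - 1_000 - (j // config.n_chromosomes + 1) * 600
        if start <= 0:
            raise ValueError("chromosome too short for the requested background peaks")
        iv = GenomicInterval(chrom, start, start + 500)
        peak_ids.append(f"bg_{j}:{chrom}:{iv.start}-{iv.end}")
        peak_coords.append(iv)
    atac_counts = _nb_counts(rng, atac_means, config.nb_dispersion, atac_means.shape)
    atac = CellMatrix(
        counts=sp.csr_matrix(atac_counts),
        feature_ids=peak_ids,
        barcodes=list(barcodes),
        feature_coords=list(peak_coords),
    )

    # ---- RNA: genes as features ----------------------------------------
    rna_means = np.full((len(genes), n_cells), config.rna_mean)
    for i, g in enumerate(genes):
        if g.gene_id in concordant:
            rna_means[i, late] *= copy_fold * config.locus_effect
    rna_counts = _nb_counts(rng, rna_means, config.nb_dispersion, rna_means.shape)
    rna = CellMatrix(
        counts=sp.csr_matrix(rna_counts),
        feature_ids=[g.gene_id for g in genes],
        barcodes=list(barcodes),
        feature_coords=[g.body for g in genes],
    )

    # ---- motif map: driver TF == epigenetically boosted peaks ----------
    boosted_peaks = [pid for pid, gid in peak_to_gene.items() if gid in concordant]
    other_peaks = [pid for pid in peak_ids if pid not in set(boosted_peaks)]
    motif_peaks: dict[str, list[str]] = {"TEAD_like": list(boosted_peaks)}
    size = max(1, len(boosted_peaks))
    for d in range(config.n_decoy_tfs):
        pick = rng.choice(len(other_peaks), size=min(size, len(other_peaks)),
                          replace=False)
        motif_peaks[f"DECOY{d + 1}"] = [other_peaks[int(i)] for i in sorted(pick)]

    gain_rows = segments[
        (segments["chrom"] == locus.chrom)
        & (segments["start"] >= locus.start)
        & (segments["end"] <= locus.end)
        & (segments["sample"].isin(config.effect_conditions))
    ]
    manifest = TruthManifest(
        seed=config.seed,
        gain_segments=gain_rows.reset_index(drop=True),
        concordant_genes=list(concordant),
        copy_only_genes=list(copy_only),
        background_genes=list(background),
        driver_tf="TEAD_like",
        motif_peaks=motif_peaks,
    )
    return MultiomicsData(
        genome=genome,
        genes=genes,
        segments=segments,
        atac=atac,
        rna=rna,
        cell_conditions=cell_conditions,
        peak_to_gene=peak_to_gene,
        motif_peaks=motif_peaks,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Hotspot table and random mutation profiles
# ---------------------------------------------------------------------------

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def simulate_hotspot_table(config: SimulationConfig) -> pd.DataFrame:
    """Hotspot-mutation p-value table (gene, aa_ref, aa_pos, aa_alt, p_value).

    Planted entries (matching planted missense variants) come first; the
    remainder are random residues with p-values uniform in (0, 1].
    """
    rng = np.random.default_rng(config.seed + 3)
    rows = [
        {"gene": g, "aa_ref": r, "aa_pos": int(p), "aa_alt": a, "p_value": float(pv)}
        for g, r, p, a, pv in config.planted_hotspots
    ]
    seen = {(r["gene"], r["aa_ref"], r["aa_pos"], r["aa_alt"]) for r in rows}
    while len(rows) < max(config.n_hotspots, len(rows)):
        gene = f"GENE{int(rng.integers(1, 500)):03d}"
        ref = AA20[int(rng.integers(20))]
        alt = AA20[int(rng.integers(20))]
        if alt == ref:
            continue
        pos = int(rng.integers(1, 600))
        key = (gene, ref, pos, alt)
        if key in seen:
            continue
        seen.add(key)
        p = float(1.0 - rng.random())  # uniform in (0, 1]
        rows.append({"gene": gene, "aa_ref": ref, "aa_pos": pos, "aa_alt": alt,
                     "p_value": p})
    return pd.DataFrame(rows, columns=["gene", "aa_ref", "aa_pos", "aa_alt", "p_value"])


def random_mutation_profiles(
    n_samples: int,
    seed: int,
    n_substitutions: tuple[int, int] = (1, 50),
    genes: Sequence[str] | None = None,
):
    """Random missense-substitution profiles for score stress-testing."""
    from .scoring import MutationProfile, Substitution

    rng = np.random.default_rng(seed)
    gene_pool = list(genes) if genes else [f"GENE{i:03d}" for i in range(1, 101)]
    lo, hi = n_substitutions
    profiles = []
    for s in range(n_samples):
        n = int(rng.integers(lo, hi + 1))
        subs = []
        for _ in range(n):
            ref = AA20[int(rng.integers(20))]
            alt = AA20[int(rng.integers(20))]
            while alt == ref:
                alt = AA20[int(rng.integers(20))]
            subs.append(
                Substitution(
                    gene=gene_pool[int(rng.integers(len(gene_pool)))],
                    ref_aa=ref,
                    position=int(rng.integers(1, 1000)),
                    alt_aa=alt,
                )
            )
        profiles.append(MutationProfile(sample_id=f"S{s + 1:04d}", substitutions=tuple(subs)))
    return profiles
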