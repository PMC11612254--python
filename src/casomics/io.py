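"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are enforced here and nowhere else:

* VCF positions are 1-based; :class:`VariantRecord.pos` keeps the 1-based
  value (as every VCF tool does) and exposes ``pos0`` for internal use.
* GFF3 is 1-based inclusive and BED is 0-based half-open; both are
  normalized to the package-wide 0-based half-open convention at parse time.
* SEG tables and MatrixMarket feature coordinates are read and written
  0-based half-open.

Writers emit deterministic column order and ``\\n`` line endings so that
equal inputs produce byte-identical files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

# ---------------------------------------------------------------------------
# Variant records
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SampleCall:
    """Per-sample depth evidence at one site.

    ``missing`` marks samples whose AD field was absent in the source VCF;
    such calls carry depth 0 / alt_depth 0 and are never silently imputed.
    """

    depth: int
    alt_depth: int
    missing: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.alt_depth <= self.depth):
            raise ValueError(
                f"require 0 <= alt_depth <= depth, got {self.alt_depth}/{self.depth}"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction; defined as 0 when depth is 0."""
        return self.alt_depth / self.depth if self.depth > 0 else 0.0


@dataclass(frozen=True)
class VariantRecord:
    """One variant site (possibly multi-allelic; never split)."""

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alts: tuple[str, ...]
    calls: dict[str, SampleCall]
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not self.alts:
            raise ValueError("at least one alt allele required")
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError(f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}")
        if not self.record_id:
            object.__setattr__(
                self, "record_id", f"{self.chrom}:{self.pos}:{self.ref}>{','.join(self.alts)}"
            )

    @property
    def pos0(self) -> int:
        """0-based position for internal interval arithmetic."""
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic_snv(self) -> bool:
        return (
            len(self.alts) == 1
            and self.ref in _BASES
            and self.alts[0] in _BASES
        )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_vcf(path: str | Path, samples: Sequence[str] | None = None) -> list[VariantRecord]:
    """Read a VCF 4.x file into :class:`VariantRecord` objects.

    Multi-allelic sites are preserved intact (one record per site). Depth is
    taken from FORMAT/DP when present, else from the AD sum; alt depth is the
    sum of AD entries beyond the reference. Samples with a missing AD field
    get depth 0 / alt 0 and are flagged ``missing``.

    Parameters
    ----------
    path : path to a VCF (optionally gzipped)
    samples : if given, restrict to (and require) these sample names.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    file_samples = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in file_samples]
        if missing:
            raise KeyError(
                f"sample(s) {missing} not present in {path}; available: {file_samples}"
            )
        keep = list(samples)
    else:
        keep = file_samples
    idx = [file_samples.index(s) for s in keep]

    records: list[VariantRecord] = []
    for lineno, v in enumerate(vcf, start=1):
        try:
            ad = v.format("AD")
            dp = v.format("DP")
            calls: dict[str, SampleCall] = {}
            for s, i in zip(keep, idx):
                if ad is None or np.any(np.asarray(ad[i]) < 0):
                    calls[s] = SampleCall(0, 0, missing=True)
                    continue
                row = np.asarray(ad[i], dtype=np.int64)
                alt_depth = int(row[1:].sum())
                if dp is not None and int(np.asarray(dp[i]).ravel()[0]) >= 0:
                    depth = int(np.asarray(dp[i]).ravel()[0])
                else:
                    depth = int(row.sum())
                depth = max(depth, int(row.sum()))  # AD can exceed a stale DP
                calls[s] = SampleCall(depth, alt_depth)
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alts=tuple(v.ALT),
                    calls=calls,
                    record_id=v.ID or "",
                )
            )
        except Exception as exc:  # noqa: BLE001 - annotate with record number
            raise ValueError(f"malformed VCF body record #{lineno} in {path}: {exc}") from exc
    vcf.close()
    return records


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    samples: Sequence[str],
    contigs: dict[str, int] | None = None,
) -> None:
    """Write records as a minimal deterministic VCF 4.2 with GT:DP:AD."""
    lines = ["##fileformat=VCFv4.2", "##source=casomics"]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for rec in records:
        cols = [
            rec.chrom,
            str(rec.pos),
            rec.record_id or ".",
            rec.ref,
            ",".join(rec.alts),
            ".",
            "PASS",
            ".",
            "GT:DP:AD",
        ]
        for s in samples:
            call = rec.calls[s]
            if call.missing:
                cols.append("./.:.:.")
                continue
            gt = "0/1" if call.alt_depth > 0 else "0/0"
            # ref depth first, then the alt depths; multi-allelic alt depth is
            # attributed to the first alt (the filter rejects such sites whole).
            ad = [call.depth - call.alt_depth, call.alt_depth]
            ad += [0] * (len(rec.alts) - 1)
            cols.append(f"{gt}:{call.depth}:{','.join(map(str, ad))}")
        lines.append("\t".join(cols))
    with _open_text(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.cds, self.cds[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping CDS segments in transcript {self.transcript_id}"
                )

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open gene body
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (``.gff``/``.gff3``) or BED (``.bed``).

    Dialect is auto-detected from the extension. GFF3's 1-based inclusive
    coordinates are converted to 0-based half-open here; BED already is.
    BED lines become single-exon, non-coding gene models.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return _read_gff3(path)
    if suffix == ".bed":
        return _read_bed(path)
    raise ValueError(f"cannot detect annotation dialect from extension: {path.name}")


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        model = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            start=g.start - 1,
            end=g.end,
            strand=g.strand if g.strand in {"+", "-"} else ".",
        )
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            tx = Transcript(
                transcript_id=t.id,
                gene_id=g.id,
                chrom=t.seqid,
                strand=t.strand if t.strand in {"+", "-"} else ".",
                exons=[
                    GenomicInterval(e.seqid, e.start - 1, e.end, t.strand)
                    for e in db.children(t, featuretype="exon")
                ],
                cds=[
                    GenomicInterval(c.seqid, c.start - 1, c.end, t.strand)
                    for c in db.children(t, featuretype="CDS")
                ],
                utr5=[
                    GenomicInterval(u.seqid, u.start - 1, u.end, t.strand)
                    for u in db.children(t, featuretype="five_prime_UTR")
                ],
                utr3=[
                    GenomicInterval(u.seqid, u.start - 1, u.end, t.strand)
                    for u in db.children(t, featuretype="three_prime_UTR")
                ],
            )
            model.transcripts.append(tx)
        genes.append(model)
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: expected >=3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) >= 4 else f"bed_{lineno}"
            strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
            iv = GenomicInterval(chrom, start, end, strand)
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    transcripts=[
                        Transcript(
                            transcript_id=f"{name}.t1",
                            gene_id=name,
                            chrom=chrom,
                            strand=strand,
                            exons=[iv],
                        )
                    ],
                )
            )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (deterministic ordering)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        lines.append(
            "\t".join(
                [g.chrom, "casomics", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        for tx in g.transcripts:
            lines.append(
                "\t".join(
                    [g.chrom, "casomics", "mRNA", str(g.start + 1), str(g.end), ".",
                     tx.strand, ".", f"ID={tx.transcript_id};Parent={g.gene_id}"]
                )
            )
            for ftype, ivs in (
                ("exon", tx.exons),
                ("five_prime_UTR", tx.utr5),
                ("CDS", tx.cds),
                ("three_prime_UTR", tx.utr3),
            ):
                for iv in ivs:
                    lines.append(
                        "\t".join(
                            [iv.chrom, "casomics", ftype, str(iv.start + 1), str(iv.end),
                             ".", tx.strand, "0" if ftype == "CDS" else ".",
                             f"Parent={tx.transcript_id}"]
                        )
                    )
    with _open_text(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Copy-ratio segments (SEG as TSV)
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG-style TSV (sample, chrom, start, end, log2_ratio).

    Coordinates are 0-based half-open in this dialect.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file {path} missing columns: {missing}")
    return df[SEG_COLUMNS]


def write_seg(df: pd.DataFrame, path: str | Path) -> None:
    df = df[SEG_COLUMNS].sort_values(["sample", "chrom", "start"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Cell-by-feature count matrices (MatrixMarket + TSV sidecars)
# ---------------------------------------------------------------------------


@dataclass
class CellMatrix:
    """Features x cells count matrix shared by the ATAC and RNA stages."""

    counts: sp.csr_matrix  # features x cells
    feature_ids: list[str]
    barcodes: list[str]
    feature_coords: list[GenomicInterval | None] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_feat, n_cell = self.counts.shape
        if n_feat != len(self.feature_ids):
            raise ValueError(
                f"{n_feat} matrix rows but {len(self.feature_ids)} feature ids"
            )
        if n_cell != len(self.barcodes):
            raise ValueError(f"{n_cell} matrix columns but {len(self.barcodes)} barcodes")
        if self.feature_coords is not None and len(self.feature_coords) != n_feat:
            raise ValueError("feature_coords length must match feature count")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError as exc:
            raise KeyError(f"feature {feature_id!r} not in matrix") from exc

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask)
        return CellMatrix(
            counts=self.counts[:, mask],
            feature_ids=list(self.feature_ids),
            barcodes=[b for b, m in zip(self.barcodes, mask) if m],
            feature_coords=self.feature_coords,
        )


def read_matrix(
    mtx_path: str | Path, features_path: str | Path, barcodes_path: str | Path
) -> CellMatrix:
    """Read a MatrixMarket sparse matrix with feature/barcode TSV sidecars.

    The features sidecar has one feature per line: ``feature_id`` alone or
    ``feature_id<TAB>chrom<TAB>start<TAB>end`` when coordinates are known.
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0].tolist()
    if counts.shape[0] != len(feats):
        raise ValueError(
            f"matrix has {counts.shape[0]} rows but features file has {len(feats)} lines"
        )
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[1]} columns but barcodes file has "
            f"{len(barcodes)} lines"
        )
    coords: list[GenomicInterval | None] | None = None
    if feats.shape[1] >= 4:
        coords = [
            GenomicInterval(row[1], int(row[2]), int(row[3]))
            if pd.notna(row[1])
            else None
            for row in feats.itertuples(index=False)
        ]
    return CellMatrix(
        counts=counts,
        feature_ids=feats[0].tolist(),
        barcodes=barcodes,
        feature_coords=coords,
    )


def write_matrix(
    matrix: CellMatrix,
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Inverse of :func:`read_matrix` (integer MatrixMarket + TSV sidecars)."""
    coo = sp.coo_matrix(matrix.counts)
    order = np.lexsort((coo.row, coo.col))  # deterministic MM ordering
    coo = sp.coo_matrix(
        (coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape
    )
    scipy.io.mmwrite(str(mtx_path), coo, field="integer")
    with _open_text(features_path, "wt") as fh:
        for i, fid in enumerate(matrix.feature_ids):
            if matrix.feature_coords is not None and matrix.feature_coords[i] is not None:
                iv = matrix.feature_coords[i]
                fh.write(f"{fid}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{fid}\n")
    with _open_text(barcodes_path, "wt") as fh:
        fh.write("\n".join(matrix.barcodes) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase sequence dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")
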