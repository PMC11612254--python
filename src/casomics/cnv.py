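"""Copy-number calls from copy-ratio segments.

Segments carry a log2 copy ratio of a test sample against an isogenic
reference. A segment is a gain when its log2 ratio exceeds the cutoff
(default 0.85, a deliberately stringent threshold for unambiguous events)
and a loss when it falls below the negated cutoff. Per-gene copy log2
fold-changes are length-weighted means of the segments overlapping the
gene body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval
from .io import GeneModel

DEFAULT_CUTOFF = 0.85


@dataclass(frozen=True)
class CopySegment:
    interval: GenomicInterval
    log2_ratio: float


@dataclass(frozen=True)
class CnvCall:
    segment: CopySegment
    state: str  # gain | loss | neutral


def segments_from_frame(df: pd.DataFrame, sample: str | None = None) -> list[CopySegment]:
    """Build segments from a SEG-style frame; one sample at a time.

    Intervals of a sample must be non-overlapping (per-sample segmentation
    invariant); violations raise.
    """
    if sample is not None:
        df = df[df["sample"] == sample]
        if df.empty:
            raise KeyError(f"sample {sample!r} not present in segment table")
    segs = [
        CopySegment(
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            log2_ratio=float(r.log2_ratio),
        )
        for r in df.itertuples(index=False)
    ]
    ordered = sorted(segs, key=lambda s: (s.interval.chrom, s.interval.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.interval.chrom == b.interval.chrom and b.interval.start < a.interval.end:
            raise ValueError(
                f"overlapping segments within one sample: {a.interval} / {b.interval}"
            )
    return segs


def call_cnv(
    segments: Sequence[CopySegment], cutoff: float = DEFAULT_CUTOFF
) -> list[CnvCall]:
    """Threshold segments into gain / loss / neutral at |log2 ratio| > cutoff."""
    calls = []
    for seg in segments:
        if math.isnan(seg.log2_ratio):
            raise ValueError(f"NaN log2 ratio in segment {seg.interval}")
        if seg.log2_ratio > cutoff:
            state = "gain"
        elif seg.log2_ratio < -cutoff:
            state = "loss"
        else:
            state = "neutral"
        calls.append(CnvCall(segment=seg, state=state))
    return calls


def gene_copy_log2fc(
    segments: Sequence[CopySegment], genes: Sequence[GeneModel]
) -> pd.Series:
    """Length-weighted mean segment log2 ratio over each gene body.

    Genes with no overlapping segment get NaN (flagged missing rather than
    imputed). Splitting a segment into adjacent equal-ratio halves leaves
    every gene value unchanged.
    """
    values = {}
    for gene in genes:
        body = gene.body
        weight = 0
        acc = 0.0
        for seg in segments:
            ov = body.overlap_length(seg.interval)
            if ov > 0:
                weight += ov
                acc += ov * seg.log2_ratio
        values[gene.gene_id] = acc / weight if weight else float("nan")
    return pd.Series(values, name="copy_log2fc")


def calls_to_frame(calls: Sequence[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": c.segment.interval.chrom, "start": c.segment.interval.start,
             "end": c.segment.interval.end, "log2_ratio": c.segment.log2_ratio,
             "state": c.state}
            for c in calls
        ],
        columns=["chrom", "start", "end", "log2_ratio", "state"],
    )
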