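"""High-confidence somatic SNV filtering for paired samples.

A test sample (late-passage culture) is compared against a reference sample
(early-passage culture from the same line). A call is kept as a
high-confidence somatic SNV only when all six criteria hold:

1. reference-sample VAF at or below ``ref_sample_max_vaf`` (default 0 —
   literally no alternate reads in the reference),
2. biallelic SNV: exactly one alternate allele, single-base ref and alt,
3. test-sample mapped depth >= ``min_depth`` (default 20 reads),
4. test-sample alternate read depth >= ``min_alt_depth`` (default 3 reads),
5. not germline-like heterozygous: the test-sample VAF is outside the
   ``het_band`` (default [0.40, 0.60]); when a population-site list is
   supplied, only banded VAFs at known sites are rejected,
6. not on a sex chromosome (X/Y excluded: hemizygous calls there cannot be
   interpreted with diploid het/hom logic).

Criteria are evaluated in the order (ref_vaf, biallelic, depth, alt_depth,
germline_like, sex_chrom) for the ``first_failed`` label, but every
criterion is always evaluated so ``all_failed`` is complete.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import VariantRecord

CRITERIA = ("ref_vaf", "biallelic", "depth", "alt_depth", "germline_like", "sex_chrom")

DEFAULT_EXCLUDED_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})

#: The six pyrimidine-reference substitution classes; purine-reference SNVs
#: are complemented into these.
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 20
    min_alt_depth: int = 3
    ref_sample_max_vaf: float = 0.0
    het_band: tuple[float, float] = (0.40, 0.60)
    excluded_chroms: frozenset[str] = DEFAULT_EXCLUDED_CHROMS
    require_biallelic_snv: bool = True
    #: optional set of (chrom, pos) known population variant sites; when
    #: given, criterion 5 additionally requires membership in this set.
    population_sites: frozenset[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        low, high = self.het_band
        if not (0 <= low < high <= 1):
            raise ValueError(f"het_band must satisfy 0 <= low < high <= 1, got {self.het_band}")
        if self.min_depth < 0 or self.min_alt_depth < 0 or self.ref_sample_max_vaf < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class FilterVerdict:
    record_id: str
    passed: bool
    first_failed: str  # criterion name, or "none"
    all_failed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.passed != (len(self.all_failed) == 0):
            raise ValueError("pass flag inconsistent with all_failed set")


def _failed_criteria(
    rec: VariantRecord, test_sample: str, ref_sample: str, cfg: FilterConfig
) -> list[str]:
    """Return failed criteria in evaluation order (empty = pass)."""
    for s in (test_sample, ref_sample):
        if s not in rec.calls:
            raise KeyError(f"sample {s!r} not present in record {rec.record_id}")
    test = rec.calls[test_sample]
    ref = rec.calls[ref_sample]

    failed = []
    if ref.vaf > cfg.ref_sample_max_vaf:
        failed.append("ref_vaf")
    if cfg.require_biallelic_snv and not rec.is_biallelic_snv:
        failed.append("biallelic")
    if test.depth < cfg.min_depth:
        failed.append("depth")
    if test.alt_depth < cfg.min_alt_depth:
        failed.append("alt_depth")
    low, high = cfg.het_band
    germline_like = low <= test.vaf <= high
    if cfg.population_sites is not None:
        germline_like = germline_like and (rec.chrom, rec.pos) in cfg.population_sites
    if germline_like:
        failed.append("germline_like")
    if rec.chrom in cfg.excluded_chroms:
        failed.append("sex_chrom")
    return failed


def apply_filters(
    records: Iterable[VariantRecord],
    test_sample: str,
    ref_sample: str,
    config: FilterConfig | None = None,
) -> tuple[list[FilterVerdict], list[VariantRecord]]:
    """Apply the six somatic criteria; return verdicts and the passing subset."""
    cfg = config or FilterConfig()
    verdicts: list[FilterVerdict] = []
    passing: list[VariantRecord] = []
    for rec in records:
        failed = _failed_criteria(rec, test_sample, ref_sample, cfg)
        verdicts.append(
            FilterVerdict(
                record_id=rec.record_id,
                passed=not failed,
                first_failed=failed[0] if failed else "none",
                all_failed=frozenset(failed),
            )
        )
        if not failed:
            passing.append(rec)
    return verdicts, passing


def substitution_spectrum(records: Sequence[VariantRecord]) -> dict[str, int]:
    """Count SNVs in the six collapsed substitution classes.

    Purine-reference substitutions (ref G or A) are complemented into the
    pyrimidine-reference classes, e.g. G>A is counted as C>T. Counts sum to
    the number of input records.
    """
    counts: Counter[str] = Counter()
    for rec in records:
        if not rec.is_biallelic_snv:
            raise ValueError(
                f"substitution spectrum requires biallelic SNVs, got {rec.record_id}"
            )
        ref, alt = rec.ref, rec.alts[0]
        if ref in {"G", "A"}:
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    return {cls: counts.get(cls, 0) for cls in SPECTRUM_CLASSES}


def verdicts_to_rows(verdicts: Sequence[FilterVerdict]) -> list[dict]:
    """Tabular form for TSV export."""
    return [
        {
            "record_id": v.record_id,
            "pass": v.passed,
            "first_failed": v.first_failed,
            "all_failed": ",".join(sorted(v.all_failed)) or ".",
        }
        for v in verdicts
    ]
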