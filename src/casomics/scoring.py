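"""Tumorigenic-impact scoring of missense substitution profiles.

The score combines two signals per sample:

* **B score** — rarity of the amino-acid exchanges. Each substitution whose
  BLOSUM100 entry s(Ref, Alt) is negative contributes -s; exchanges with
  nonnegative log-odds (those that occur freely among highly similar
  proteins) contribute nothing::

      B = -sum_i min(s(Ref_i, Alt_i), 0)

* **H score** — membership in a published cancer-hotspot list with p-values.
  Each substitution exactly matching a hotspot entry contributes
  -log2(p)::

      H = -sum_k log2(p_k)   over matched substitutions k

* **combined score** — tanh(B + H), a standardized impact in [0, 1]
  (0 = no rare exchanges and no hotspot hits; the score saturates toward 1
  as evidence accumulates).

Restricting to a gene set (e.g. a TP53-interaction network for a "T score",
or COSMIC Tier 1 for a "C score") intersects the profile with the set before
summing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import substitution_matrices

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

_HGVS_SHORT = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


@dataclass(frozen=True)
class Substitution:
    gene: str
    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in CANONICAL_AA:
                raise ValueError(
                    f"non-canonical amino acid {aa!r} in "
                    f"{self.gene}:{self.ref_aa}{self.position}{self.alt_aa}"
                )
        if self.position < 1:
            raise ValueError("amino-acid position must be >= 1")

    @property
    def aa_change(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


def parse_aa_change(text: str) -> tuple[str, int, str]:
    """Parse HGVS-p short form, e.g. 'R175H' -> ('R', 175, 'H')."""
    m = _HGVS_SHORT.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse amino-acid change {text!r}")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class MutationProfile:
    sample_id: str
    substitutions: tuple[Substitution, ...]

    def restrict(self, gene_set: Iterable[str] | None) -> "MutationProfile":
        if gene_set is None:
            return self
        genes = set(gene_set)
        return MutationProfile(
            sample_id=self.sample_id,
            substitutions=tuple(s for s in self.substitutions if s.gene in genes),
        )


class SubstitutionMatrix:
    """A symmetric amino-acid substitution matrix (default BLOSUM100).

    Only the 20 canonical amino acids are scoreable; ambiguous codes
    (B, Z, X) and stop (*) are rejected — stop gains are nonsense variants
    and never reach missense scoring.
    """

    def __init__(self, array, name: str = "BLOSUM100"):
        self.name = name
        self._array = array
        alphabet = set(str(array.alphabet))
        if not CANONICAL_AA <= alphabet:
            raise ValueError("matrix does not cover the 20 canonical amino acids")
        for a in CANONICAL_AA:
            for b in CANONICAL_AA:
                if array[a, b] != array[b, a]:
                    raise ValueError(f"matrix not symmetric at ({a},{b})")

    def score(self, ref_aa: str, alt_aa: str) -> float:
        if ref_aa not in CANONICAL_AA or alt_aa not in CANONICAL_AA:
            raise ValueError(
                f"cannot score non-canonical substitution {ref_aa}->{alt_aa}"
            )
        return float(self._array[ref_aa, alt_aa])


def load_blosum100() -> SubstitutionMatrix:
    """Load the packaged BLOSUM100 matrix (NCBI matblas text, 1/3-bit units)."""
    ref = resources.files("casomics").joinpath("data/BLOSUM100.txt")
    with ref.open("rt") as fh:
        array = substitution_matrices.read(fh)
    return SubstitutionMatrix(array, name="BLOSUM100")


class HotspotTable:
    """Cancer-hotspot substitutions with per-entry p-values in (0, 1].

    Matching is exact on (gene, ref AA, position, alt AA) by default; a
    position-only mode matches on (gene, position) and uses the smallest
    p-value among entries at that position.
    """

    COLUMNS = ["gene", "aa_ref", "aa_pos", "aa_alt", "p_value"]

    def __init__(self, entries: Mapping[tuple[str, str, int, str], float]):
        self.entries: dict[tuple[str, str, int, str], float] = {}
        for key, p in entries.items():
            if not 0 < p <= 1:
                raise ValueError(f"hotspot p-value must be in (0, 1], got {p} for {key}")
            if key in self.entries:
                raise ValueError(f"duplicate hotspot entry {key}")
            self.entries[key] = float(p)
        self._by_position: dict[tuple[str, int], float] = {}
        for (gene, _ref, pos, _alt), p in self.entries.items():
            k = (gene, pos)
            self._by_position[k] = min(p, self._by_position.get(k, 1.0))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HotspotTable":
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"hotspot table missing columns {missing}")
        return cls(
            {
                (r.gene, r.aa_ref, int(r.aa_pos), r.aa_alt): float(r.p_value)
                for r in df.itertuples(index=False)
            }
        )

    @classmethod
    def read_tsv(cls, path) -> "HotspotTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def lookup(self, sub: Substitution, match_on: str = "exact") -> float | None:
        if match_on == "exact":
            return self.entries.get((sub.gene, sub.ref_aa, sub.position, sub.alt_aa))
        if match_on == "position":
            return self._by_position.get((sub.gene, sub.position))
        raise ValueError(f"unknown match mode {match_on!r}")


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def b_score(
    profile: MutationProfile,
    matrix: SubstitutionMatrix,
    gene_set: Iterable[str] | None = None,
) -> float:
    """Sum of -s over substitutions with negative matrix score s.

    Repeated identical substitutions each contribute (sums run over
    occurrences). Always >= 0; an empty (or fully restricted-away) profile
    scores 0.
    """
    total = 0.0
    for sub in profile.restrict(gene_set).substitutions:
        s = matrix.score(sub.ref_aa, sub.alt_aa)
        if s < 0:
            total -= s
    return total


def h_score(
    profile: MutationProfile,
    hotspots: HotspotTable,
    gene_set: Iterable[str] | None = None,
    match_on: str = "exact",
) -> float:
    """Sum of -log2(p) over substitutions matching a hotspot entry."""
    total = 0.0
    for sub in profile.restrict(gene_set).substitutions:
        p = hotspots.lookup(sub, match_on=match_on)
        if p is not None:
            total -= math.log2(p)
    return total


def combined_score(b: float, h: float) -> float:
    """tanh(B + H): a standardized impact score ranging from 0 to 1.

    Both inputs must be nonnegative (they are sums of nonnegative
    contributions by construction). The score is 0 only when B = H = 0 and
    saturates toward 1; in double precision tanh reaches exactly 1.0 once
    B + H exceeds ~19.
    """
    if b < 0 or h < 0:
        raise ValueError(f"B and H scores must be >= 0, got ({b}, {h})")
    return math.tanh(b + h)


def score_samples(
    profiles: Sequence[MutationProfile],
    matrix: SubstitutionMatrix,
    hotspots: HotspotTable,
    gene_sets: Mapping[str, Iterable[str]],
    match_on: str = "exact",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every sample against every named gene set.

    Returns a (sample x gene_set) score table and a per-substitution
    contribution ledger, both deterministically ordered.
    """
    for name, genes in gene_sets.items():
        if not name:
            raise ValueError("gene set name must be non-empty")
        if not set(genes):
            raise ValueError(f"gene set {name!r} is empty")
    score_rows = []
    ledger_rows = []
    for profile in profiles:
        for set_name in sorted(gene_sets):
            genes = set(gene_sets[set_name])
            restricted = profile.restrict(genes)
            b = b_score(restricted, matrix)
            h = h_score(restricted, hotspots, match_on=match_on)
            score_rows.append(
                {"sample": profile.sample_id, "gene_set": set_name,
                 "b_score": b, "h_score": h, "combined": combined_score(b, h)}
            )
            for sub in restricted.substitutions:
                s = matrix.score(sub.ref_aa, sub.alt_aa)
                p = hotspots.lookup(sub, match_on=match_on)
                ledger_rows.append(
                    {"sample": profile.sample_id, "gene_set": set_name,
                     "gene": sub.gene, "aa_change": sub.aa_change,
                     "blosum_score": s,
                     "b_contribution": -s if s < 0 else 0.0,
                     "hotspot_p": p if p is not None else float("nan"),
                     "h_contribution": -math.log2(p) if p is not None else 0.0}
                )
    scores = pd.DataFrame(
        score_rows, columns=["sample", "gene_set", "b_score", "h_score", "combined"]
    )
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["sample", "gene_set", "gene", "aa_change", "blosum_score",
                 "b_contribution", "hotspot_p", "h_contribution"],
    )
    return scores, ledger


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------


def read_profiles(path) -> list[MutationProfile]:
    """Read profiles from TSV columns (sample, gene, aa_change)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "gene", "aa_change"):
        if col not in df.columns:
            raise ValueError(f"profile table missing column {col!r}")
    profiles = []
    for sample, group in df.groupby("sample", sort=True):
        subs = []
        for r in group.itertuples(index=False):
            ref, pos, alt = parse_aa_change(r.aa_change)
            subs.append(Substitution(gene=r.gene, ref_aa=ref, position=pos, alt_aa=alt))
        profiles.append(MutationProfile(sample_id=str(sample), substitutions=tuple(subs)))
    return profiles


def read_gene_set(path) -> set[str]:
    """One gene symbol per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
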