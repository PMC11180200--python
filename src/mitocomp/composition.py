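"""Base composition, A+T / G+C content, and strand-asymmetry skews.

Skews follow the standard definitions

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed on the H-strand (reference) sequence. For regional composition the
same convention applies to light-strand genes unless ``coding_strand=True``,
which re-complements them for codon-oriented work. Percent contents are
computed over unambiguous bases only; a zero denominator yields NaN rather
than an exception, so that pooled summaries over sparse regions degrade
gracefully.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .io_formats import CoordinateError, GeneClass, GeneFeature, GeneTable, reverse_complement

__all__ = [
    "BaseCounts",
    "SkewResult",
    "RegionComposition",
    "count_bases",
    "compute_skew",
    "region_composition",
]

_AMBIGUOUS = frozenset("NRYSWKMBDHVU")


@dataclass(frozen=True)
class BaseCounts:
    """Exact base tally of one (gap-stripped) sequence."""

    a: int
    c: int
    g: int
    t: int
    ambiguous: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.c, self.g, self.t, self.ambiguous) < 0:
            raise ValueError("base counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t + self.ambiguous

    @property
    def unambiguous_total(self) -> int:
        return self.a + self.c + self.g + self.t

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(
            self.a + other.a, self.c + other.c, self.g + other.g,
            self.t + other.t, self.ambiguous + other.ambiguous,
        )


@dataclass(frozen=True)
class SkewResult:
    at_skew: float
    gc_skew: float
    at_content: float  # percent of unambiguous bases
    gc_content: float


def count_bases(seq: str) -> BaseCounts:
    """Tally A/C/G/T; IUPAC ambiguity codes pool into ``ambiguous``; gaps are dropped."""
    stripped = seq.upper().replace("-", "")
    if not stripped:
        raise ValueError("cannot count bases of an empty sequence")
    tally = Counter(stripped)
    ambiguous = sum(n for base, n in tally.items() if base in _AMBIGUOUS)
    return BaseCounts(
        a=tally.get("A", 0), c=tally.get("C", 0),
        g=tally.get("G", 0), t=tally.get("T", 0),
        ambiguous=ambiguous,
    )


def compute_skew(counts: BaseCounts) -> SkewResult:
    at = counts.a + counts.t
    gc = counts.g + counts.c
    total = counts.unambiguous_total
    return SkewResult(
        at_skew=(counts.a - counts.t) / at if at else math.nan,
        gc_skew=(counts.g - counts.c) / gc if gc else math.nan,
        at_content=100.0 * at / total if total else math.nan,
        gc_content=100.0 * gc / total if total else math.nan,
    )


@dataclass(frozen=True)
class RegionComposition:
    """Per-region skews plus the pooled (concatenated-region) result."""

    regions: dict[str, SkewResult]
    counts: dict[str, BaseCounts]
    pooled: SkewResult
    pooled_counts: BaseCounts


def _region_key(feature: GeneFeature, seen: Counter) -> str:
    seen[feature.name] += 1
    n = seen[feature.name]
    return feature.name if n == 1 else f"{feature.name}#{n}"


def region_composition(
    seq: str,
    table: GeneTable,
    selector: str | GeneClass | Iterable[str] = "genome",
    coding_strand: bool = False,
) -> RegionComposition:
    """Composition of selected regions of a genome.

    ``selector`` is ``"genome"`` (whole sequence as a single region), a
    :class:`GeneClass`, or an iterable of gene names. With
    ``coding_strand=True`` light-strand features are reverse-complemented
    before counting (skews then describe the coding strand).
    """
    if len(seq) < table.genome_length:
        raise CoordinateError(
            f"sequence length {len(seq)} shorter than annotated genome length "
            f"{table.genome_length}"
        )
    if isinstance(selector, str) and selector == "genome":
        counts = count_bases(seq)
        skew = compute_skew(counts)
        return RegionComposition(
            regions={"genome": skew}, counts={"genome": counts},
            pooled=skew, pooled_counts=counts,
        )
    if isinstance(selector, GeneClass):
        feats = table.select(gene_class=selector)
    else:
        feats = table.select(names=selector)
    if not feats:
        raise ValueError(f"selector {selector!r} matched no features")

    regions: dict[str, SkewResult] = {}
    counts: dict[str, BaseCounts] = {}
    pooled = BaseCounts(0, 0, 0, 0, 0)
    seen: Counter = Counter()
    for f in feats:
        sub = f.slice(seq)
        if coding_strand and f.strand.value == "L":
            sub = reverse_complement(sub)
        bc = count_bases(sub)
        key = _region_key(f, seen)
        counts[key] = bc
        regions[key] = compute_skew(bc)
        pooled = pooled + bc
    return RegionComposition(
        regions=regions, counts=counts,
        pooled=compute_skew(pooled), pooled_counts=pooled,
    )
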