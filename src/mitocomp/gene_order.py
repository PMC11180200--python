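"""Mitochondrial gene-order comparison.

Gene orders are compared against a reference (by default the canonical
vertebrate/teleost arrangement) at two levels:

* **content** — a multiset comparison yields duplicated genes (extra copies
  in the query) and lost genes;
* **adjacency** — on the genes that are single-copy in both genomes, the
  circular, strand-aware adjacency sets are compared. An adjacency present
  in the query but absent from the reference is a *breakpoint*; a gene whose
  (predecessor, successor) context changed is *moved*.

Strand-awareness means the adjacency ``(a on H) -> (b on H)`` differs from
its reverse-complement reading: a strand flip is a real rearrangement.
Multi-copy genes are excluded from breakpoint counting (their adjacency
identity is ill-defined) and reported only as duplications.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .io_formats import GeneTable, Strand

__all__ = [
    "OrderedGene",
    "GeneOrderString",
    "GeneOrderDiff",
    "canonical_teleost_order",
    "diff_orders",
]


@dataclass(frozen=True)
class OrderedGene:
    name: str
    strand: Strand


@dataclass(frozen=True)
class GeneOrderString:
    """The genomic order of (gene, strand) entries for one species."""

    species_id: str
    entries: tuple[OrderedGene, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"{self.species_id}: empty gene order")

    @classmethod
    def from_gene_table(cls, table: GeneTable) -> "GeneOrderString":
        return cls(
            species_id=table.species_id,
            entries=tuple(OrderedGene(f.name, f.strand) for f in table.features),
        )

    def copy_counts(self) -> Counter:
        return Counter(g.name for g in self.entries)

    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.entries)


def canonical_teleost_order() -> GeneOrderString:
    """The canonical 37-gene + OL + CR vertebrate order with strand assignments."""
    from .fixtures import load_opama_gene_table

    table = load_opama_gene_table()
    return GeneOrderString(
        species_id="canonical_teleost",
        entries=tuple(OrderedGene(f.name, f.strand) for f in table.features),
    )


@dataclass(frozen=True)
class GeneOrderDiff:
    reference_id: str
    query_id: str
    duplicated: dict[str, int]   # gene -> extra copies in the query
    lost: tuple[str, ...]
    moved: tuple[str, ...]
    identical: bool
    breakpoint_count: int


def _restricted_circular_adjacencies(
    order: GeneOrderString, keep: set[str]
) -> tuple[set[tuple[OrderedGene, OrderedGene]], dict[str, tuple[OrderedGene, OrderedGene]]]:
    """Directed circular adjacency set over the kept genes, plus each gene's context."""
    kept = [g for g in order.entries if g.name in keep]
    adjacencies: set[tuple[OrderedGene, OrderedGene]] = set()
    context: dict[str, tuple[OrderedGene, OrderedGene]] = {}
    n = len(kept)
    if n < 2:
        return adjacencies, context
    for i, g in enumerate(kept):
        succ = kept[(i + 1) % n]
        pred = kept[(i - 1) % n]
        adjacencies.add((g, succ))
        context[g.name] = (pred, succ)
    return adjacencies, context


def diff_orders(reference: GeneOrderString, query: GeneOrderString) -> GeneOrderDiff:
    """Content and adjacency differences of a query order versus a reference."""
    ref_counts = reference.copy_counts()
    q_counts = query.copy_counts()
    duplicated = {
        name: q_counts[name] - ref_counts.get(name, 0)
        for name in sorted(q_counts)
        if q_counts[name] > ref_counts.get(name, 0)
    }
    lost = tuple(
        name for name in sorted(ref_counts) if q_counts.get(name, 0) < ref_counts[name]
    )

    shared_single = {
        name
        for name in ref_counts
        if ref_counts[name] == 1 and q_counts.get(name, 0) == 1
    }
    ref_adj, ref_ctx = _restricted_circular_adjacencies(reference, shared_single)
    q_adj, q_ctx = _restricted_circular_adjacencies(query, shared_single)
    breakpoints = len(q_adj - ref_adj)
    moved = tuple(
        sorted(
            name
            for name in shared_single
            if name in ref_ctx and name in q_ctx and ref_ctx[name] != q_ctx[name]
        )
    )
    identical = not duplicated and not lost and not moved and breakpoints == 0
    return GeneOrderDiff(
        reference_id=reference.species_id,
        query_id=query.species_id,
        duplicated=duplicated,
        lost=lost,
        moved=moved,
        identical=identical,
        breakpoint_count=breakpoints,
    )
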