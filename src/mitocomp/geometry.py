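"""Gene-level geometry of an annotated mitogenome.

Given a :class:`~mitocomp.io_formats.GeneTable` this module reproduces the
classic per-genome accounting: gene lengths, intergenic spacers (IGS) and
overlaps between coordinate-consecutive features, the fraction of the genome
occupied by protein-coding genes, and start/stop-codon bookkeeping including
the incomplete stops (``T``/``TA``) completed to ``TAA`` by
post-transcriptional polyadenylation.

Adjacency is evaluated between consecutive features sorted by start
coordinate, regardless of strand or class — light-strand tRNAs and the
non-coding landmarks take part in the same gap/overlap ledger, which is the
convention used in published mitogenome feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .io_formats import GeneClass, GeneTable

__all__ = [
    "AdjacencyReport",
    "GeometrySummary",
    "StopStatus",
    "StopCodonCall",
    "COMPLETE_STOPS",
    "summarize_geometry",
    "classify_stop_codon",
]

#: Complete stop codons of the vertebrate mitochondrial code.
COMPLETE_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

#: Trailing residues accepted as polyadenylation-completed stops.
INCOMPLETE_STOPS = frozenset({"T", "TA"})


@dataclass(frozen=True)
class AdjacencyReport:
    """Gap or overlap between two coordinate-consecutive features.

    Exactly one of ``gap_bp``/``overlap_bp`` is positive; both are zero for
    abutting features (next start == previous end + 1).
    """

    gene_a: str
    gene_b: str
    gap_bp: int = 0
    overlap_bp: int = 0

    def __post_init__(self) -> None:
        if self.gap_bp < 0 or self.overlap_bp < 0:
            raise ValueError("gap/overlap sizes must be non-negative")
        if self.gap_bp and self.overlap_bp:
            raise ValueError("a junction cannot both gap and overlap")


@dataclass(frozen=True)
class GeometrySummary:
    genome_length: int
    gene_lengths: tuple[tuple[str, int], ...]
    total_pcg_length: int
    pcg_fraction: float  # percent of the genome
    igs_reports: tuple[AdjacencyReport, ...]
    overlap_reports: tuple[AdjacencyReport, ...]
    pcg_pcg_overlap_total: int
    pcg_pcg_overlap_pairs: tuple[AdjacencyReport, ...]
    n_genes: int  # features excluding the non-coding landmarks

    @property
    def pcg_pcg_participants(self) -> tuple[str, ...]:
        """Distinct PCGs taking part in PCG–PCG overlaps."""
        names: list[str] = []
        for rep in self.pcg_pcg_overlap_pairs:
            for g in (rep.gene_a, rep.gene_b):
                if g not in names:
                    names.append(g)
        return tuple(names)

    @property
    def pcg_min_length(self) -> int:
        return min(l for _, l in self._pcg_lengths)

    @property
    def pcg_max_length(self) -> int:
        return max(l for _, l in self._pcg_lengths)

    @property
    def _pcg_lengths(self) -> tuple[tuple[str, int], ...]:
        pcgs = {"nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
                "cox1", "cox2", "cox3", "atp6", "atp8", "cytb"}
        got = tuple((n, l) for n, l in self.gene_lengths if n in pcgs)
        return got if got else self.gene_lengths


def summarize_geometry(table: GeneTable) -> GeometrySummary:
    """Compute the per-genome geometry ledger from coordinates alone."""
    feats = table.features  # already sorted by start
    gene_lengths = tuple((f.name, f.length) for f in feats)
    pcgs = [f for f in feats if f.gene_class is GeneClass.PCG]
    total_pcg = sum(f.length for f in pcgs)
    fraction = 100.0 * total_pcg / table.genome_length if table.genome_length else float("nan")

    gaps: list[AdjacencyReport] = []
    overlaps: list[AdjacencyReport] = []
    pcg_pairs: list[AdjacencyReport] = []
    for a, b in zip(feats, feats[1:]):
        gap = b.start - a.end - 1
        if gap > 0:
            gaps.append(AdjacencyReport(a.name, b.name, gap_bp=gap))
        elif gap < 0:
            rep = AdjacencyReport(a.name, b.name, overlap_bp=-gap)
            overlaps.append(rep)
            if a.gene_class is GeneClass.PCG and b.gene_class is GeneClass.PCG:
                pcg_pairs.append(rep)

    return GeometrySummary(
        genome_length=table.genome_length,
        gene_lengths=gene_lengths,
        total_pcg_length=total_pcg,
        pcg_fraction=fraction,
        igs_reports=tuple(gaps),
        overlap_reports=tuple(overlaps),
        pcg_pcg_overlap_total=sum(r.overlap_bp for r in pcg_pairs),
        pcg_pcg_overlap_pairs=tuple(pcg_pairs),
        n_genes=sum(1 for f in feats if f.gene_class is not GeneClass.NC),
    )


class StopStatus(str, Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"
    NONE = "none"  # neither a stop nor a recognisable truncated stop


@dataclass(frozen=True)
class StopCodonCall:
    gene: str
    codon_observed: str  # length 1-3
    status: StopStatus
    completed_codon: str | None = None  # "TAA" for incomplete stops


def classify_stop_codon(gene_sequence: str, gene: str = "") -> StopCodonCall:
    """Classify the terminal codon of a coding-strand gene sequence.

    The trailing residues after the last full codon (``len mod 3``) decide the
    call: ``T`` or ``TA`` is an incomplete stop completed to ``TAA``; with no
    trailing residues the final full codon is tested against the complete-stop
    set. Anything else is flagged ``none`` for manual review.
    """
    seq = gene_sequence.upper().replace("-", "")
    if len(seq) < 4:
        raise ValueError(f"{gene or 'gene'}: sequence too short to classify ({len(seq)} nt)")
    trailing = len(seq) % 3
    if trailing:
        tail = seq[-trailing:]
        if tail in INCOMPLETE_STOPS:
            return StopCodonCall(gene, tail, StopStatus.INCOMPLETE, "TAA")
        return StopCodonCall(gene, tail, StopStatus.NONE)
    last = seq[-3:]
    if last in COMPLETE_STOPS:
        return StopCodonCall(gene, last, StopStatus.COMPLETE, last)
    return StopCodonCall(gene, last, StopStatus.NONE)
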