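"""Codon counting and relative synonymous codon usage (RSCU).

RSCU for codon *c* in a synonymous family *F* with total count ``n_F`` and
degeneracy ``k_F`` is ``count_c / (n_F / k_F)``: the observed usage divided
by the expectation under uniform usage within the family, so RSCU = 1 means
no bias and the family RSCU values always sum to ``k_F``.

The default genetic code is the vertebrate mitochondrial code (NCBI
translation table 2: stops TAA/TAG/AGA/AGG, TGA → Trp, ATA → Met; 60 sense
codons with six-fold leucine and serine families), obtained from Biopython's
codon tables. Stop codons never enter RSCU; codons containing ambiguous
bases are skipped and the per-unit skip count reported — a skip fraction
above 1% flags the unit as unreliable, mirroring the common practice of
dropping taxa with many ambiguous base pairs from codon-usage analyses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "GeneticCode",
    "VERTEBRATE_MITO",
    "CodonUsageError",
    "CodonUsageProfile",
    "extract_codons",
    "count_codons",
    "compute_rscu",
    "species_profile",
    "rscu_matrix",
    "cumulative_rscu",
    "SKIP_FLAG_FRACTION",
]

#: Units whose skipped-codon fraction exceeds this are flagged.
SKIP_FLAG_FRACTION = 0.01


class CodonUsageError(ValueError):
    """Invalid codon data (internal stop, negative counts, frame problems)."""


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to what codon counting needs."""

    table_id: int
    codon_to_aa: Mapping[str, str]  # sense codons only
    stop_codons: frozenset[str]
    sense_codons: tuple[str, ...]   # fixed order: grouped by amino acid
    families: Mapping[str, tuple[str, ...]]  # amino acid -> codons

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        table = _BioCodonTable.unambiguous_dna_by_id[table_id]
        forward = {codon: aa for codon, aa in table.forward_table.items()}
        stops = frozenset(table.stop_codons)
        families: dict[str, list[str]] = {}
        for codon, aa in forward.items():
            families.setdefault(aa, []).append(codon)
        fam = {aa: tuple(sorted(codons)) for aa, codons in families.items()}
        ordered = tuple(c for aa in sorted(fam) for c in fam[aa])
        return cls(
            table_id=table_id,
            codon_to_aa=forward,
            stop_codons=stops,
            sense_codons=ordered,
            families=fam,
        )

    def degeneracy(self, codon: str) -> int:
        return len(self.families[self.codon_to_aa[codon]])

    def is_sense(self, codon: str) -> bool:
        return codon in self.codon_to_aa


VERTEBRATE_MITO = GeneticCode.from_ncbi_id(2)


def extract_codons(
    gene_sequence: str,
    code: GeneticCode = VERTEBRATE_MITO,
    reading_frame: int = 1,
    drop_incomplete_stop: bool = True,
) -> list[str]:
    """Split a coding-strand CDS into codons for usage counting.

    Consecutive non-overlapping triplets from the requested frame; a trailing
    1–2 nt incomplete stop is dropped, and a complete terminal stop codon is
    excluded from the returned list. An internal stop raises
    :class:`CodonUsageError` naming the offset — almost always a frame or
    strand mistake.
    """
    seq = gene_sequence.upper()
    if "-" in seq:
        raise CodonUsageError("gapped sequence passed to extract_codons; ungap it first")
    if reading_frame not in (1, 2, 3):
        raise ValueError(f"reading_frame must be 1, 2 or 3, got {reading_frame}")
    seq = seq[reading_frame - 1 :]
    if len(seq) < 3:
        raise CodonUsageError("sequence shorter than one codon")
    n_full = len(seq) // 3
    trailing = len(seq) % 3
    if trailing and not drop_incomplete_stop:
        raise CodonUsageError(f"sequence length not a multiple of 3 ({trailing} nt left over)")
    codons = [seq[i * 3 : i * 3 + 3] for i in range(n_full)]
    for i, codon in enumerate(codons[:-1]):
        if codon in code.stop_codons:
            raise CodonUsageError(
                f"internal stop codon {codon} at nucleotide offset {i * 3 + 1} "
                "(check reading frame and strand)"
            )
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    return codons


def count_codons(
    codons: Iterable[str], code: GeneticCode = VERTEBRATE_MITO
) -> tuple[Counter, int]:
    """Tally sense codons; returns ``(counts, n_skipped)``.

    Codons containing anything but A/C/G/T are skipped, not imputed.
    """
    counts: Counter = Counter()
    skipped = 0
    for codon in codons:
        if code.is_sense(codon):
            counts[codon] += 1
        elif codon in code.stop_codons:
            raise CodonUsageError(f"stop codon {codon} cannot enter usage counts")
        else:
            skipped += 1
    return counts, skipped


@dataclass(frozen=True)
class CodonUsageProfile:
    """Codon counts and RSCU for one unit (a gene or a species pool)."""

    unit_id: str
    codon_counts: Mapping[str, int]   # keyed by sense codon
    rscu: Mapping[str, float]
    missing_families: frozenset[str]  # amino acids with zero observed codons
    n_skipped: int = 0


def compute_rscu(
    codon_counts: Mapping[str, int],
    code: GeneticCode = VERTEBRATE_MITO,
    unit_id: str = "",
    n_skipped: int = 0,
) -> CodonUsageProfile:
    """Family-wise RSCU from sense-codon counts.

    Families with zero total count get RSCU 0 for each member and the amino
    acid recorded in ``missing_families``.
    """
    for codon, n in codon_counts.items():
        if n < 0:
            raise CodonUsageError(f"negative count for codon {codon}")
        if codon not in code.codon_to_aa:
            raise CodonUsageError(f"{codon!r} is not a sense codon of table {code.table_id}")
    counts = {c: int(codon_counts.get(c, 0)) for c in code.sense_codons}
    rscu: dict[str, float] = {}
    missing: set[str] = set()
    for aa, codons in code.families.items():
        n_family = sum(counts[c] for c in codons)
        if n_family == 0:
            missing.add(aa)
            for c in codons:
                rscu[c] = 0.0
        else:
            expected = n_family / len(codons)
            for c in codons:
                rscu[c] = counts[c] / expected
    return CodonUsageProfile(
        unit_id=unit_id,
        codon_counts=counts,
        rscu=rscu,
        missing_families=frozenset(missing),
        n_skipped=n_skipped,
    )


def species_profile(
    unit_id: str,
    cds_sequences: Iterable[str],
    code: GeneticCode = VERTEBRATE_MITO,
) -> CodonUsageProfile:
    """Pool the codon counts of several coding sequences into one profile."""
    counts: Counter = Counter()
    skipped = 0
    for seq in cds_sequences:
        codons = extract_codons(seq, code=code)
        c, s = count_codons(codons, code=code)
        counts.update(c)
        skipped += s
    return compute_rscu(counts, code=code, unit_id=unit_id, n_skipped=skipped)


def rscu_matrix(
    profiles: Sequence[CodonUsageProfile],
    code: GeneticCode = VERTEBRATE_MITO,
) -> pd.DataFrame:
    """Species × codon RSCU matrix with a fixed codon column order.

    Columns follow ``code.sense_codons`` (grouped by amino acid). The frame
    carries two metadata columns-worth of attributes: ``df.attrs["skipped"]``
    maps unit id → skipped codon count and ``df.attrs["flagged"]`` lists units
    whose skip fraction exceeds :data:`SKIP_FLAG_FRACTION`.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for a cross-species matrix")
    ids = [p.unit_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit ids in profiles")
    data = {p.unit_id: [p.rscu[c] for c in code.sense_codons] for p in profiles}
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(code.sense_codons))
    skipped = {p.unit_id: p.n_skipped for p in profiles}
    totals = {p.unit_id: sum(p.codon_counts.values()) + p.n_skipped for p in profiles}
    flagged = [
        uid for uid in ids
        if totals[uid] and skipped[uid] / totals[uid] > SKIP_FLAG_FRACTION
    ]
    df.attrs["skipped"] = skipped
    df.attrs["flagged"] = flagged
    return df


def cumulative_rscu(matrix: pd.DataFrame) -> pd.Series:
    """Column sums of an RSCU matrix: the cumulative RSCU per codon."""
    return matrix.sum(axis=0)
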