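"""Degenerate-consensus motif scanning for control-region landmarks.

The control region of teleost mitogenomes carries a series of functional
landmarks — the extended termination-associated sequence (ETAS), the central
conserved blocks CSB-F/E/D, the conserved sequence blocks CSB-1/2/3, the
GTGGG-box typical of CSB-E, and an AT-rich 5' flank (TAATATA in sciaenids).
This module locates such landmarks by exhaustive sliding-window matching of
IUPAC consensus strings under a Hamming mismatch budget.

Only the two literal, sequence-explicit motifs ship as defaults (GTGGG-box
and the TAATATA 5' stretch); ETAS/CSB consensus strings vary by lineage and
are supplied by the user as patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "IUPAC_SETS",
    "MotifPattern",
    "MotifHit",
    "scan_motifs",
    "DEFAULT_PATTERNS",
    "reverse_complement_pattern",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHBDN")


@dataclass(frozen=True)
class MotifPattern:
    name: str
    consensus: str  # IUPAC string
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        consensus = self.consensus.upper()
        object.__setattr__(self, "consensus", consensus)
        if not consensus:
            raise ValueError(f"{self.name}: empty consensus")
        bad = set(consensus) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {sorted(bad)}")
        if not 0 <= self.max_mismatches < len(consensus):
            raise ValueError(
                f"{self.name}: max_mismatches must lie in [0, {len(consensus) - 1}]"
            )

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    start: int  # 1-based inclusive on the scanned sequence
    end: int
    mismatches: int
    matched: str


DEFAULT_PATTERNS: tuple[MotifPattern, ...] = (
    MotifPattern("GTGGG-box", "GTGGG", 0),
    MotifPattern("TAATATA-5prime", "TAATATA", 0),
)


def reverse_complement_pattern(pattern: MotifPattern) -> MotifPattern:
    rc = pattern.consensus.translate(_IUPAC_COMPLEMENT)[::-1]
    return MotifPattern(f"{pattern.name}(rc)", rc, pattern.max_mismatches)


def scan_motifs(
    cr_sequence: str,
    patterns: Sequence[MotifPattern] | Iterable[MotifPattern] = DEFAULT_PATTERNS,
) -> list[MotifHit]:
    """Scan an ungapped DNA string for every pattern at every offset.

    IUPAC degeneracy is honoured (a position matches iff the observed base
    belongs to the consensus character's degeneracy set); overlapping hits
    are all reported, sorted by start then pattern name. A pattern longer
    than the sequence simply yields no hits.
    """
    seq = cr_sequence.upper()
    if "-" in seq:
        raise ValueError("scan_motifs expects an ungapped sequence")
    hits: list[MotifHit] = []
    for pattern in patterns:
        m = len(pattern)
        budget = pattern.max_mismatches
        sets = [IUPAC_SETS[ch] for ch in pattern.consensus]
        for offset in range(len(seq) - m + 1):
            window = seq[offset : offset + m]
            mismatches = 0
            for ch, allowed in zip(window, sets):
                if ch not in allowed:
                    mismatches += 1
                    if mismatches > budget:
                        break
            else:
                hits.append(
                    MotifHit(
                        pattern=pattern.name,
                        start=offset + 1,
                        end=offset + m,
                        mismatches=mismatches,
                        matched=window,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.pattern))
    return hits
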