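"""Nei–Gojobori (1986) Ka/Ks estimation on codon-aligned coding sequences.

Site counting: each codon position contributes ``s_i = (# synonymous
one-step changes) / (# non-stop one-step changes)`` synonymous sites and
``1 - s_i`` nonsynonymous sites, so every codon carries exactly three sites
and mutations to stop codons are excluded from the denominator. Pairwise
sites are the average of the two sequences' per-codon sums.

Difference counting: codon pairs differing at k positions are resolved by
averaging the synonymous/nonsynonymous step classification over all k!
minimal substitution pathways with equal weights. Pathways passing through a
stop codon are dropped and the weights renormalised; in the rare case where
*every* pathway is blocked (possible under the mitochondrial code, e.g.
TGA ↔ AAA) the average is taken over all pathways with the stop exclusion
waived, so the pair still contributes rather than being silently lost.

Proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
``d = -(3/4) ln(1 - (4/3) p)``, giving Ks and Ka; the ratio Ka/Ks classifies
the selection regime (<1 purifying, >1 positive). The ratio is undefined
when Ks = 0, when a correction saturates (p >= 3/4), or when the pair shows
no differences at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import permutations

from .codon_usage import GeneticCode, VERTEBRATE_MITO
from .divergence import AlignmentBlock

__all__ = [
    "SelectionRegime",
    "KaKsResult",
    "ng86_sites",
    "pathway_differences",
    "ng86_pair",
    "family_kaks",
    "jukes_cantor",
]

_BASES = ("A", "C", "G", "T")


class SelectionRegime(str, Enum):
    PURIFYING = "purifying"
    NEUTRAL = "neutral"
    POSITIVE = "positive"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class KaKsResult:
    locus: str
    S: float           # synonymous sites (fractional)
    N: float           # nonsynonymous sites
    Sd: float          # pathway-averaged synonymous differences
    Nd: float          # pathway-averaged nonsynonymous differences
    pS: float
    pN: float
    Ks: float          # JC-corrected; NaN when saturated/undefined
    Ka: float
    ratio: float       # Ka/Ks; NaN when undefined
    regime: SelectionRegime
    n_codons_compared: int
    n_codons_skipped: int
    mean_pairwise_ratio: float = math.nan  # family level only
    n_undefined_pairs: int = 0
    method: str = "NG86"


# per-code caches keyed by table id
_SITES_CACHE: dict[tuple[int, str], tuple[float, float]] = {}
_DIFF_CACHE: dict[tuple[int, str, str], tuple[float, float]] = {}


def ng86_sites(codon: str, code: GeneticCode = VERTEBRATE_MITO) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one sense codon."""
    key = (code.table_id, codon)
    if key in _SITES_CACHE:
        return _SITES_CACHE[key]
    if not code.is_sense(codon):
        raise ValueError(f"{codon!r} is not a sense codon of table {code.table_id}")
    aa = code.codon_to_aa[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in code.stop_codons:
                continue
            non_stop += 1
            if code.codon_to_aa[mutant] == aa:
                syn += 1
        if non_stop:
            s_total += syn / non_stop
        # a position whose every change creates a stop contributes no sites
        # to either class beyond the nonsynonymous remainder handled below
    result = (s_total, 3.0 - s_total)
    _SITES_CACHE[key] = result
    return result


def _pathway_steps(c_from: str, c_to: str, order: tuple[int, ...]) -> list[tuple[str, str]]:
    """Successive (codon, codon) steps along one substitution ordering."""
    steps = []
    current = c_from
    for pos in order:
        nxt = current[:pos] + c_to[pos] + current[pos + 1 :]
        steps.append((current, nxt))
        current = nxt
    return steps


def pathway_differences(
    codon_a: str, codon_b: str, code: GeneticCode = VERTEBRATE_MITO
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair."""
    key = (code.table_id, codon_a, codon_b)
    if key in _DIFF_CACHE:
        return _DIFF_CACHE[key]
    diff_positions = tuple(i for i in range(3) if codon_a[i] != codon_b[i])
    if not diff_positions:
        result = (0.0, 0.0)
    else:
        valid: list[tuple[int, int]] = []
        blocked: list[tuple[int, int]] = []
        for order in permutations(diff_positions):
            steps = _pathway_steps(codon_a, codon_b, order)
            through_stop = any(b in code.stop_codons for _, b in steps[:-1])
            sd = nd = 0
            for u, v in steps:
                if u in code.stop_codons or v in code.stop_codons:
                    nd += 1  # only reachable on blocked pathways
                elif code.codon_to_aa[u] == code.codon_to_aa[v]:
                    sd += 1
                else:
                    nd += 1
            (blocked if through_stop else valid).append((sd, nd))
        pool = valid if valid else blocked
        sd_mean = sum(p[0] for p in pool) / len(pool)
        nd_mean = sum(p[1] for p in pool) / len(pool)
        result = (sd_mean, nd_mean)
    _DIFF_CACHE[key] = result
    return result


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN at or beyond saturation (p >= 3/4)."""
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return math.nan
    return -0.75 * math.log(arg)


def _split_codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _usable(codon: str, code: GeneticCode) -> bool:
    return code.is_sense(codon)


def ng86_pair(
    cds_a: str,
    cds_b: str,
    code: GeneticCode = VERTEBRATE_MITO,
    locus: str = "",
) -> KaKsResult:
    """NG86 Ka/Ks for a codon-aligned CDS pair.

    Codon pairs containing a gap, an ambiguity or a stop in either member
    are skipped with a count. Sites are the average over the two sequences.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"aligned CDSs differ in length: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError(f"alignment length {len(a)} is not a multiple of 3")
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    compared = skipped = 0
    for ca, cb in zip(_split_codons(a), _split_codons(b)):
        if not (_usable(ca, code) and _usable(cb, code)):
            skipped += 1
            continue
        sa, _ = ng86_sites(ca, code)
        sb, _ = ng86_sites(cb, code)
        S_a += sa
        S_b += sb
        sd, nd = pathway_differences(ca, cb, code)
        Sd += sd
        Nd += nd
        compared += 1
    if compared == 0:
        raise ValueError(f"{locus or 'pair'}: no comparable codons")
    S = (S_a + S_b) / 2.0
    N = 3.0 * compared - S
    return _finish(locus, S, N, Sd, Nd, compared, skipped)


def _finish(
    locus: str,
    S: float,
    N: float,
    Sd: float,
    Nd: float,
    compared: int,
    skipped: int,
    mean_pairwise_ratio: float = math.nan,
    n_undefined_pairs: int = 0,
) -> KaKsResult:
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    Ks = jukes_cantor(pS) if not math.isnan(pS) else math.nan
    Ka = jukes_cantor(pN) if not math.isnan(pN) else math.nan
    if Sd == 0.0 and Nd == 0.0:
        ratio = math.nan
        regime = SelectionRegime.UNDEFINED
    elif math.isnan(Ks) or math.isnan(Ka) or Ks == 0.0:
        ratio = math.nan
        regime = SelectionRegime.UNDEFINED
    else:
        ratio = Ka / Ks
        if ratio > 1.0:
            regime = SelectionRegime.POSITIVE
        elif ratio < 1.0:
            regime = SelectionRegime.PURIFYING
        else:
            regime = SelectionRegime.NEUTRAL
    return KaKsResult(
        locus=locus, S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        ratio=ratio, regime=regime,
        n_codons_compared=compared, n_codons_skipped=skipped,
        mean_pairwise_ratio=mean_pairwise_ratio,
        n_undefined_pairs=n_undefined_pairs,
    )


def family_kaks(
    block: AlignmentBlock, code: GeneticCode = VERTEBRATE_MITO
) -> KaKsResult:
    """Pooled NG86 estimate for a codon alignment of >= 2 sequences.

    The family ratio is formed from counts averaged over all unordered pairs
    (robust to individually undefined pairs); the mean of the defined
    pairwise ratios is reported alongside.
    """
    n = len(block.records)
    seqs = [r.residues for r in block.records]
    S_sum = N_sum = Sd_sum = Nd_sum = 0.0
    compared_sum = skipped_sum = 0
    ratios: list[float] = []
    undefined = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            res = ng86_pair(seqs[i], seqs[j], code=code, locus=block.locus)
            n_pairs += 1
            S_sum += res.S
            N_sum += res.N
            Sd_sum += res.Sd
            Nd_sum += res.Nd
            compared_sum += res.n_codons_compared
            skipped_sum += res.n_codons_skipped
            if math.isnan(res.ratio):
                undefined += 1
            else:
                ratios.append(res.ratio)
    mean_ratio = sum(ratios) / len(ratios) if ratios else math.nan
    return _finish(
        block.locus,
        S_sum / n_pairs,
        N_sum / n_pairs,
        Sd_sum / n_pairs,
        Nd_sum / n_pairs,
        round(compared_sum / n_pairs),
        skipped_sum,
        mean_pairwise_ratio=mean_ratio,
        n_undefined_pairs=undefined,
    )
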