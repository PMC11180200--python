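"""Alignment-based site classification and Kimura 2-parameter distances.

A column of an alignment block is *evaluated* iff no sequence has a gap or
ambiguity there (complete-column deletion); it is *conserved* iff all
residues are identical. This makes conserved% + variable% = 100 on the
evaluated sites.

The K2P distance between two aligned sequences uses pairwise deletion:
sites with a gap or ambiguity in either member of the pair are dropped for
that pair only. With transition proportion P and transversion proportion Q,

    d = -1/2 ln((1 - 2P - Q) * sqrt(1 - 2Q))

which is undefined (saturated) when either log argument is non-positive;
saturated pairs are flagged and excluded from family means, never clamped.

Family-level uncertainty comes from a seeded bootstrap over alignment
columns: the mean pairwise distance is recomputed on resampled columns and
the standard error is the standard deviation of the replicate means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceRecord

__all__ = [
    "AlignmentBlock",
    "SiteClassSummary",
    "PairwiseDistanceResult",
    "FamilyDistanceSummary",
    "classify_sites",
    "k2p_pair",
    "family_distance",
]

_UNAMBIGUOUS = frozenset("ACGT")
# transition partners under the purine/pyrimidine split
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class AlignmentBlock:
    """Equal-length gapped sequences for one locus across species."""

    locus: str
    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(f"{self.locus}: an alignment block needs >= 2 sequences")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"{self.locus}: unequal sequence lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.locus}: duplicate sequence ids")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def as_array(self) -> np.ndarray:
        """(n_sequences, n_sites) array of single characters."""
        return np.array([list(r.residues) for r in self.records])

    @classmethod
    def from_fasta(cls, path, locus: str | None = None) -> "AlignmentBlock":
        from .io_formats import read_fasta  # local import to avoid cycle at module load

        records = read_fasta(path)
        from pathlib import Path

        return cls(locus=locus or Path(path).stem, records=tuple(records))


@dataclass(frozen=True)
class SiteClassSummary:
    locus: str
    n_sites_total: int
    n_sites_evaluated: int
    n_conserved: int
    n_variable: int
    conserved_pct: float
    variable_pct: float


def classify_sites(block: AlignmentBlock) -> SiteClassSummary:
    """Conserved/variable partition of the gap- and ambiguity-free columns."""
    arr = block.as_array()
    is_unambiguous = np.isin(arr, list(_UNAMBIGUOUS))
    evaluated = is_unambiguous.all(axis=0)
    conserved = evaluated & (arr == arr[0]).all(axis=0)
    n_eval = int(evaluated.sum())
    n_cons = int(conserved.sum())
    n_var = n_eval - n_cons
    return SiteClassSummary(
        locus=block.locus,
        n_sites_total=block.length,
        n_sites_evaluated=n_eval,
        n_conserved=n_cons,
        n_variable=n_var,
        conserved_pct=100.0 * n_cons / n_eval if n_eval else math.nan,
        variable_pct=100.0 * n_var / n_eval if n_eval else math.nan,
    )


@dataclass(frozen=True)
class PairwiseDistanceResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # K2P distance; NaN when saturated
    n_compared: int
    defined: bool


def _site_categories(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-site category: -1 excluded, 0 identical, 1 transition, 2 transversion."""
    cat = np.full(a.shape, -1, dtype=np.int8)
    usable = np.isin(a, list(_UNAMBIGUOUS)) & np.isin(b, list(_UNAMBIGUOUS))
    same = usable & (a == b)
    cat[same] = 0
    diff = usable & ~same
    purine_a = np.isin(a, ["A", "G"])
    purine_b = np.isin(b, ["A", "G"])
    ts = diff & (purine_a == purine_b)
    cat[ts] = 1
    cat[diff & ~ts] = 2
    return cat


def _k2p_from_counts(n_same: int, n_ts: int, n_tv: int) -> PairwiseDistanceResult:
    n = n_same + n_ts + n_tv
    if n == 0:
        raise ValueError("no comparable (gap- and ambiguity-free) sites")
    p = n_ts / n
    q = n_tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return PairwiseDistanceResult(P=p, Q=q, d=math.nan, n_compared=n, defined=False)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return PairwiseDistanceResult(P=p, Q=q, d=d, n_compared=n, defined=True)


def k2p_pair(seq_a: str | SequenceRecord, seq_b: str | SequenceRecord) -> PairwiseDistanceResult:
    """Kimura 2-parameter distance for one aligned pair (pairwise deletion)."""
    sa = seq_a.residues if isinstance(seq_a, SequenceRecord) else seq_a.upper()
    sb = seq_b.residues if isinstance(seq_b, SequenceRecord) else seq_b.upper()
    if len(sa) != len(sb):
        raise ValueError(f"aligned sequences differ in length: {len(sa)} vs {len(sb)}")
    a = np.array(list(sa))
    b = np.array(list(sb))
    cat = _site_categories(a, b)
    return _k2p_from_counts(
        int((cat == 0).sum()), int((cat == 1).sum()), int((cat == 2).sum())
    )


@dataclass(frozen=True)
class FamilyDistanceSummary:
    locus: str
    mean_d: float
    se_d: float
    n_pairs: int
    n_undefined_pairs: int
    bootstrap_reps: int


def _pair_category_matrix(block: AlignmentBlock) -> np.ndarray:
    """(n_pairs, n_sites) category matrix over all unordered pairs."""
    arr = block.as_array()
    n = arr.shape[0]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(_site_categories(arr[i], arr[j]))
    return np.array(rows, dtype=np.int8)


def _pairwise_d(cats: np.ndarray) -> np.ndarray:
    """Vector of K2P distances (NaN when saturated or no sites) per category row."""
    n_same = (cats == 0).sum(axis=1).astype(float)
    n_ts = (cats == 1).sum(axis=1).astype(float)
    n_tv = (cats == 2).sum(axis=1).astype(float)
    n = n_same + n_ts + n_tv
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, n_ts / n, np.nan)
        q = np.where(n > 0, n_tv / n, np.nan)
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        d = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan)
    return d


def family_distance(
    block: AlignmentBlock,
    bootstrap_reps: int = 500,
    seed: int | None = None,
) -> FamilyDistanceSummary:
    """Mean pairwise K2P distance for a locus with a site-bootstrap SE.

    Saturated (undefined) pairs are excluded from the mean with their count
    reported. The bootstrap resamples alignment columns with replacement,
    using the same column sample for every pair within a replicate.
    """
    if len(block.records) < 3:
        raise ValueError(f"{block.locus}: family summaries need >= 3 sequences")
    cats = _pair_category_matrix(block)
    d_full = _pairwise_d(cats)
    n_undef = int(np.isnan(d_full).sum())
    defined = d_full[~np.isnan(d_full)]
    if defined.size == 0:
        raise ValueError(f"{block.locus}: every pairwise distance is undefined")
    mean_d = float(defined.mean())

    rng = np.random.default_rng(seed)
    n_sites = cats.shape[1]
    reps = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        idx = rng.integers(0, n_sites, n_sites)
        d_rep = _pairwise_d(cats[:, idx])
        good = d_rep[~np.isnan(d_rep)]
        reps[r] = good.mean() if good.size else np.nan
    good_reps = reps[~np.isnan(reps)]
    se = float(good_reps.std(ddof=1)) if good_reps.size > 1 else 0.0
    return FamilyDistanceSummary(
        locus=block.locus,
        mean_d=mean_d,
        se_d=se,
        n_pairs=cats.shape[0],
        n_undefined_pairs=n_undef,
        bootstrap_reps=bootstrap_reps,
    )
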