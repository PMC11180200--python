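"""Synthetic mitogenome-like data with known ground truth.

Three generators, all deterministic given a seed:

* :func:`simulate_genome` — an annotated genome following a configurable
  37-gene + OL + CR layout (by default the *O. pama* coordinates), with
  AC-biased base composition, an AT-rich control region carrying the
  TAATATA 5' flank and a GTGGG-box, and protein-coding genes that start
  with ATG, contain no internal stops on their coding strand, and end with
  configured complete or incomplete stop codons — including through the
  short PCG–PCG overlaps, where both reading frames must be satisfied at
  once.

* :func:`evolve_sequences` — sequence families diverged along a guide tree
  under a Kimura 2-parameter substitution process (transition/transversion
  rate ratio kappa); codon mode adds an accept/reject selection filter:
  amino-acid-changing events are accepted with probability omega and events
  creating stops are rejected outright. No indels, so the output is an
  alignment by construction. The codon filter is deliberately simpler than
  a full Goldman–Yang rate matrix; it is sufficient for regime-recovery
  tests.

* :func:`planted_rscu_matrix` — species × codon RSCU matrices with
  cluster-specific codon-preference shifts on top of the no-bias baseline
  (RSCU = 1 everywhere), preserving the family-sum normalisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .codon_usage import GeneticCode, VERTEBRATE_MITO
from .divergence import AlignmentBlock
from .io_formats import (
    GeneClass,
    GeneFeature,
    GeneTable,
    SequenceRecord,
    Strand,
)

__all__ = [
    "SimulationError",
    "GenomeSimSpec",
    "EvolveSimSpec",
    "simulate_genome",
    "evolve_sequences",
    "planted_rscu_matrix",
    "OPAMA_BASE_FREQS",
    "CR_BASE_FREQS",
    "DEFAULT_STOP_CODONS",
]


class SimulationError(RuntimeError):
    """The requested simulation is infeasible or failed to converge."""


_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Genome-wide base frequencies of the *O. pama* mitogenome (AC-biased).
OPAMA_BASE_FREQS = {
    "A": 4892 / 16513, "C": 4881 / 16513, "G": 2417 / 16513, "T": 4323 / 16513,
}

#: AT-rich control-region composition (~64% A+T, as in sciaenid CRs).
CR_BASE_FREQS = {"A": 0.35, "C": 0.23, "G": 0.13, "T": 0.29}

#: Stop-codon assignment of the 13 PCGs; "T"/"TA" are incomplete stops.
DEFAULT_STOP_CODONS = {
    "nad1": "TAG", "nad2": "TAA", "cox1": "AGA", "cox2": "T", "atp8": "TAA",
    "atp6": "TAA", "cox3": "TAA", "nad3": "T", "nad4l": "TAA", "nad4": "T",
    "nad5": "TAA", "nad6": "TAA", "cytb": "T",
}

_INCOMPLETE = ("T", "TA")


def _default_layout() -> tuple[tuple[str, Strand, GeneClass, int], ...]:
    from .fixtures import load_opama_gene_table

    table = load_opama_gene_table()
    return tuple((f.name, f.strand, f.gene_class, f.length) for f in table.features)


def _default_junctions() -> tuple[int, ...]:
    """Signed junction sizes of the default layout: +gap, -overlap, 0 abutting."""
    from .fixtures import load_opama_gene_table

    feats = load_opama_gene_table().features
    return tuple(b.start - a.end - 1 for a, b in zip(feats, feats[1:]))


@dataclass(frozen=True)
class GenomeSimSpec:
    """Recipe for one synthetic annotated mitogenome."""

    layout: tuple[tuple[str, Strand, GeneClass, int], ...]
    junctions: tuple[int, ...]  # signed: +gap, -overlap, 0 abutting
    base_freqs: dict[str, float] = field(default_factory=lambda: dict(OPAMA_BASE_FREQS))
    cr_base_freqs: dict[str, float] = field(default_factory=lambda: dict(CR_BASE_FREQS))
    stop_codons: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_STOP_CODONS))
    start_codon: str = "ATG"
    igs_range: tuple[int, int] = (1, 7)
    overlap_range: tuple[int, int] = (1, 10)
    species_id: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.junctions) != len(self.layout) - 1:
            raise SimulationError(
                f"{len(self.layout)} features need {len(self.layout) - 1} junctions, "
                f"got {len(self.junctions)}"
            )
        total = sum(self.base_freqs.get(b, 0.0) for b in _BASES)
        if abs(total - 1.0) > 1e-6:
            raise SimulationError(f"base frequencies sum to {total}, expected 1")
        for lo, hi in (self.igs_range, self.overlap_range):
            if not 0 <= lo <= hi <= 10:
                raise SimulationError("igs/overlap ranges must lie within [0, 10]")

    @classmethod
    def default(cls, species_id: str = "synthetic", seed: int | None = None) -> "GenomeSimSpec":
        """The canonical layout with the observed junction sizes."""
        return cls(
            layout=_default_layout(),
            junctions=_default_junctions(),
            species_id=species_id,
            seed=seed,
        )

    def build_table(self) -> GeneTable:
        """Coordinates implied by the layout and junction sizes."""
        features: list[GeneFeature] = []
        pos = 1
        for idx, (name, strand, gclass, length) in enumerate(self.layout):
            start = pos
            end = start + length - 1
            features.append(GeneFeature(name, start, end, strand, gclass))
            if idx < len(self.junctions):
                step = self.junctions[idx]
                if step < 0 and -step >= min(length, self.layout[idx + 1][3]):
                    raise SimulationError(
                        f"overlap {-step} bp at junction {name} exceeds a gene length"
                    )
                pos = end + 1 + step
        genome_length = max(f.end for f in features)
        return GeneTable(
            species_id=self.species_id,
            genome_length=genome_length,
            features=tuple(features),
        )


# --------------------------------------------------------------------------
# genome simulation
# --------------------------------------------------------------------------

def _sample_bases(rng: np.random.Generator, freqs: dict[str, float], n: int) -> list[str]:
    p = np.array([freqs[b] for b in _BASES], dtype=float)
    p /= p.sum()
    return [_BASES[i] for i in rng.choice(4, size=n, p=p)]


def _sample_sense_codon(
    rng: np.random.Generator, freqs: dict[str, float], code: GeneticCode
) -> str:
    while True:
        codon = "".join(_sample_bases(rng, freqs, 3))
        if code.is_sense(codon):
            return codon


def _tilt_for_stop_rejection(
    freqs: dict[str, float], code: GeneticCode, iters: int = 60
) -> dict[str, float]:
    """Proposal base frequencies whose post-stop-rejection marginal matches
    ``freqs``. Rejecting the A-rich stop codons (TAA/TAG/AGA/AGG) would
    otherwise depress A across the ~69% of the genome that is coding."""
    target = np.array([freqs[b] for b in _BASES], dtype=float)
    target /= target.sum()
    p = target.copy()
    idx = {b: i for i, b in enumerate(_BASES)}
    sense = [c for c in code.sense_codons]
    for _ in range(iters):
        marginal = np.zeros(4)
        total = 0.0
        for codon in sense:
            prob = p[idx[codon[0]]] * p[idx[codon[1]]] * p[idx[codon[2]]]
            total += prob
            for base in codon:
                marginal[idx[base]] += prob
        marginal /= 3.0 * total
        p *= target / np.maximum(marginal, 1e-12)
        p /= p.sum()
    return {b: float(p[i]) for b, i in idx.items()}


def _genome_index(feat: GeneFeature, cds_index: int) -> int:
    """0-based genome index of a CDS position, orientation-aware."""
    if feat.strand is Strand.H:
        return feat.start - 1 + cds_index
    return feat.end - 1 - cds_index


def _write_cds(genome: list[str], feat: GeneFeature, cds: str) -> None:
    for i, base in enumerate(cds):
        idx = _genome_index(feat, i)
        genome[idx] = base if feat.strand is Strand.H else _COMP[base]


def _read_cds(genome: list[str], feat: GeneFeature) -> str:
    out = []
    for i in range(feat.length):
        idx = _genome_index(feat, i)
        base = genome[idx]
        out.append(base if feat.strand is Strand.H else _COMP[base])
    return "".join(out)


def _build_pcg_cds(
    rng: np.random.Generator,
    feat: GeneFeature,
    stop: str,
    start_codon: str,
    freqs: dict[str, float],
    code: GeneticCode,
) -> str:
    n = feat.length
    if stop in _INCOMPLETE:
        if (n - len(stop)) % 3:
            raise SimulationError(
                f"{feat.name}: length {n} incompatible with incomplete stop {stop!r}"
            )
        n_codons = (n - len(stop)) // 3
        tail = stop
    else:
        if n % 3:
            raise SimulationError(f"{feat.name}: length {n} not a multiple of 3")
        if stop not in code.stop_codons:
            raise SimulationError(f"{feat.name}: {stop!r} is not a stop codon")
        n_codons = n // 3 - 1
        tail = stop
    if n_codons < 2:
        raise SimulationError(f"{feat.name}: too short for a start codon plus body")
    body = [_sample_sense_codon(rng, freqs, code) for _ in range(n_codons - 1)]
    return start_codon + "".join(body) + tail


def _pinned_positions(
    feats: list[GeneFeature],
    stop_codons: dict[str, str],
    start_codon: str,
) -> dict[int, str]:
    """Genome positions fixed by start/stop codons of the PCGs; conflicts raise."""
    pins: dict[int, str] = {}

    def pin(feat: GeneFeature, cds_index: int, base: str) -> None:
        idx = _genome_index(feat, cds_index)
        genome_base = base if feat.strand is Strand.H else _COMP[base]
        if pins.get(idx, genome_base) != genome_base:
            raise SimulationError(
                f"infeasible packing: position {idx + 1} pinned to both "
                f"{pins[idx]} and {genome_base}"
            )
        pins[idx] = genome_base

    for feat in feats:
        stop = stop_codons.get(feat.name, "TAA")
        for i, base in enumerate(start_codon):
            pin(feat, i, base)
        for i, base in enumerate(stop):
            pin(feat, feat.length - len(stop) + i, base)
    return pins


def _invalid_codons(
    genome: list[str],
    feat: GeneFeature,
    stop: str,
    start_codon: str,
    code: GeneticCode,
) -> list[int]:
    """Indices of codons violating the PCG contract (start/stop are pinned,
    so violations are internal stops created by overlap writes)."""
    cds = _read_cds(genome, feat)
    body = cds[: len(cds) - len(stop)] if stop in _INCOMPLETE else cds[:-3]
    bad = []
    if cds[:3] != start_codon:
        bad.append(0)
    for k in range(0, len(body) // 3):
        codon = body[3 * k : 3 * k + 3]
        if codon in code.stop_codons:
            bad.append(k)
    if stop not in _INCOMPLETE and cds[-3:] != stop:
        bad.append(len(cds) // 3 - 1)
    elif stop in _INCOMPLETE and not cds.endswith(stop):
        bad.append(len(body) // 3)
    return bad


def simulate_genome(
    spec: GenomeSimSpec | None = None,
    seed: int | None = None,
    code: GeneticCode = VERTEBRATE_MITO,
) -> tuple[SequenceRecord, GeneTable]:
    """Generate one annotated genome satisfying the spec.

    Overlapping PCGs constrain each other's sequence; start and stop codons
    are pinned as hard constraints and the remaining positions of any codon
    violating a reading-frame contract are re-drawn until every PCG is valid
    simultaneously. Infeasible pinnings (conflicting fixed bases) and
    non-converging configurations raise :class:`SimulationError`.
    """
    spec = spec or GenomeSimSpec.default()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    table = spec.build_table()
    pcgs = [f for f in table.features if f.gene_class is GeneClass.PCG]

    # the background absorbs the control region's AT excess so that the
    # genome-wide composition stays on target
    covered = np.zeros(table.genome_length, dtype=bool)
    cr_len = 0
    for feat in table.features:
        if feat.gene_class is GeneClass.PCG or feat.name == "CR":
            covered[feat.start - 1 : feat.end] = True
        if feat.name == "CR":
            cr_len += feat.length
    bg_len = int((~covered).sum())
    bg_freqs = dict(spec.base_freqs)
    if bg_len > 0 and cr_len > 0:
        adj = {
            b: spec.base_freqs[b]
            + (spec.base_freqs[b] - spec.cr_base_freqs[b]) * cr_len / bg_len
            for b in _BASES
        }
        if min(adj.values()) > 0.0:
            total = sum(adj.values())
            bg_freqs = {b: v / total for b, v in adj.items()}

    genome = _sample_bases(rng, bg_freqs, table.genome_length)

    # AT-rich control region(s) with the two literal landmarks
    for feat in table.select(names=["CR"]):
        cr = _sample_bases(rng, spec.cr_base_freqs, feat.length)
        genome[feat.start - 1 : feat.end] = cr
        if feat.length >= 7:
            genome[feat.start - 1 : feat.start + 6] = list("TAATATA")
        mid = feat.start - 1 + feat.length // 2
        if mid + 5 <= feat.end:
            genome[mid : mid + 5] = list("GTGGG")

    # coding regions: sense codons whose post-rejection marginal matches the
    # genome target; light-strand genes are written complemented, so their
    # sampling target is the complemented composition
    cds_freqs = {
        Strand.H: _tilt_for_stop_rejection(spec.base_freqs, code),
        Strand.L: _tilt_for_stop_rejection(
            {b: spec.base_freqs[_COMP[b]] for b in _BASES}, code
        ),
    }
    for feat in pcgs:
        stop = spec.stop_codons.get(feat.name, "TAA")
        cds = _build_pcg_cds(
            rng, feat, stop, spec.start_codon, cds_freqs[feat.strand], code
        )
        _write_cds(genome, feat, cds)

    pins = _pinned_positions(pcgs, spec.stop_codons, spec.start_codon)
    for idx, base in pins.items():
        genome[idx] = base

    # repair sweep: re-draw free positions of violating codons until stable
    for _ in range(10_000):
        dirty = False
        for feat in pcgs:
            stop = spec.stop_codons.get(feat.name, "TAA")
            for codon_idx in _invalid_codons(genome, feat, stop, spec.start_codon, code):
                free = [
                    _genome_index(feat, 3 * codon_idx + off)
                    for off in range(3)
                    if 3 * codon_idx + off < feat.length
                    and _genome_index(feat, 3 * codon_idx + off) not in pins
                ]
                if not free:
                    raise SimulationError(
                        f"{feat.name}: codon {codon_idx} fully pinned yet invalid"
                    )
                for idx in free:
                    genome[idx] = _sample_bases(rng, spec.base_freqs, 1)[0]
                dirty = True
        if not dirty:
            break
    else:
        raise SimulationError("PCG constraint repair did not converge")

    record = SequenceRecord(id=spec.species_id, residues="".join(genome))
    return record, table


# --------------------------------------------------------------------------
# sequence-family evolution
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolveSimSpec:
    """Guide tree plus substitution parameters for family simulation."""

    tree: str               # newick with leaf labels and branch lengths
    kappa: float = 2.0      # transition/transversion rate ratio
    omega: float = 1.0      # dN/dS acceptance probability (codon mode)
    locus: str = "locus"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.omega <= 0:
            raise ValueError("kappa and omega must be positive")


_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T
_CODE_OF = {b: i for i, b in enumerate(_BASES)}


def _k80_probs(t: float, kappa: float) -> tuple[float, float]:
    """(transition, per-target transversion) probabilities after time t."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_ts, p_tv


def _evolve_nucleotide(
    codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    if t == 0.0:
        return codes.copy()
    p_ts, p_tv = _k80_probs(t, kappa)
    u = rng.random(codes.size)
    pick = rng.integers(0, 2, codes.size)
    is_purine = (codes == 0) | (codes == 2)
    tv_target = np.where(is_purine, 1 + 2 * pick, 2 * pick)
    out = codes.copy()
    ts_mask = (u >= 1.0 - p_ts - 2.0 * p_tv) & (u < 1.0 - 2.0 * p_tv)
    tv_mask = u >= 1.0 - 2.0 * p_tv
    out[ts_mask] = _PARTNER[codes[ts_mask]]
    out[tv_mask] = tv_target[tv_mask]
    return out


def _evolve_codon(
    seq: list[str],
    t: float,
    kappa: float,
    omega: float,
    code: GeneticCode,
    rng: np.random.Generator,
    stats: dict,
) -> list[str]:
    out = list(seq)
    L = len(out)
    alpha = kappa / (kappa + 2.0)
    n_events = rng.poisson(t * L)
    for _ in range(n_events):
        pos = int(rng.integers(L))
        cur = out[pos]
        u = rng.random()
        cur_code = _CODE_OF[cur]
        if u < alpha:
            new = _BASES[_PARTNER[cur_code]]
        else:
            pick = 0 if u < alpha + (1.0 - alpha) / 2.0 else 1
            is_purine = cur in ("A", "G")
            new = _BASES[1 + 2 * pick] if is_purine else _BASES[2 * pick]
        c0 = 3 * (pos // 3)
        old_codon = "".join(out[c0 : c0 + 3])
        new_codon = old_codon[: pos - c0] + new + old_codon[pos - c0 + 1 :]
        if new_codon in code.stop_codons:
            stats["stop_rejections"] = stats.get("stop_rejections", 0) + 1
            continue
        # accept/reject keeps the nonsynonymous:synonymous flux ratio at omega
        # on both sides of 1 (probabilities cannot exceed 1, so for omega > 1
        # it is the synonymous events that are thinned instead)
        if code.codon_to_aa[new_codon] != code.codon_to_aa[old_codon]:
            p_accept = min(1.0, omega)
            kind = "nonsyn_rejections"
        else:
            p_accept = min(1.0, 1.0 / omega)
            kind = "syn_rejections"
        if rng.random() >= p_accept:
            stats[kind] = stats.get(kind, 0) + 1
            continue
        out[pos] = new
    return out


def evolve_sequences(
    root_seq: str,
    spec: EvolveSimSpec,
    mode: str = "nucleotide",
    seed: int | None = None,
    code: GeneticCode = VERTEBRATE_MITO,
    stats: dict | None = None,
) -> AlignmentBlock:
    """Evolve a root sequence along a guide tree; leaves form the alignment.

    In nucleotide mode branch lengths are expected substitutions per site
    under the K2P process. In codon mode they are expected *proposed*
    substitutions per site before the selection filter, which rejects
    stop-creating events and accepts amino-acid-changing events with
    probability omega.
    """
    root = root_seq.upper()
    if len(root) < 300:
        raise ValueError("root sequence must be at least 300 nt")
    if mode not in ("nucleotide", "codon"):
        raise ValueError(f"mode must be 'nucleotide' or 'codon', got {mode!r}")
    if mode == "codon":
        if len(root) % 3:
            raise ValueError("codon mode needs a root length divisible by 3")
        for k in range(len(root) // 3):
            codon = root[3 * k : 3 * k + 3]
            if not code.is_sense(codon):
                raise ValueError(f"root codon {codon!r} at position {3 * k + 1} is not sense")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    if stats is None:
        stats = {}

    tree = dendropy.Tree.get(
        data=spec.tree, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    seqs: dict[int, object] = {}
    if mode == "nucleotide":
        root_state: object = np.array([_CODE_OF[b] for b in root])
    else:
        root_state = list(root)
    seqs[id(tree.seed_node)] = root_state

    records = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent_state = seqs[id(node.parent_node)]
        if mode == "nucleotide":
            state = _evolve_nucleotide(parent_state, t, spec.kappa, rng)
        else:
            state = _evolve_codon(parent_state, t, spec.kappa, spec.omega, code, rng, stats)
        seqs[id(node)] = state
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"leaf{len(records) + 1}"
            if mode == "nucleotide":
                seq = "".join(_BASES[i] for i in state)
            else:
                seq = "".join(state)
            records.append(SequenceRecord(id=label.replace(" ", "_"), residues=seq))
    records.sort(key=lambda r: r.id)
    return AlignmentBlock(locus=spec.locus, records=tuple(records))


# --------------------------------------------------------------------------
# planted RSCU structure
# --------------------------------------------------------------------------

def planted_rscu_matrix(
    n_species: int,
    n_clusters: int,
    effect_size: float,
    seed: int | None = None,
    noise: float = 0.0,
    code: GeneticCode = VERTEBRATE_MITO,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Species × codon RSCU matrix with planted cluster structure.

    Each cluster prefers one randomly chosen codon per synonymous family:
    its RSCU rises by ``effect_size`` and the rest of the family drops to
    keep the family sum at the degeneracy. Per-species Gaussian noise
    (``noise`` standard deviation) is renormalised the same way. With
    ``effect_size == 0`` and ``noise == 0`` every row is exactly the
    no-bias baseline. Returns ``(matrix, cluster_labels)``.
    """
    if not n_species >= n_clusters >= 1:
        raise ValueError("need n_species >= n_clusters >= 1")
    if effect_size < 0 or noise < 0:
        raise ValueError("effect_size and noise must be non-negative")
    rng = np.random.default_rng(seed)
    families = [codons for codons in code.families.values()]

    cluster_profiles = []
    clipped = False
    for _ in range(n_clusters):
        profile: dict[str, float] = {}
        for codons in families:
            k = len(codons)
            preferred = codons[int(rng.integers(k))]
            for c in codons:
                profile[c] = 1.0 + effect_size if c == preferred else 1.0 - effect_size / (k - 1)
            if min(profile[c] for c in codons) < 0.0:
                clipped = True
                vals = np.clip([profile[c] for c in codons], 0.0, None)
                vals *= k / vals.sum()
                for c, v in zip(codons, vals):
                    profile[c] = float(v)
        cluster_profiles.append(profile)
    if clipped:
        warnings.warn("effect size produced negative RSCU; values clipped and renormalised")

    labels = np.array([i % n_clusters for i in range(n_species)])
    rows = []
    for i in range(n_species):
        base = cluster_profiles[labels[i]]
        row: dict[str, float] = {}
        for codons in families:
            k = len(codons)
            vals = np.array([base[c] for c in codons])
            if noise > 0.0:
                vals = np.clip(vals + rng.normal(0.0, noise, k), 0.0, None)
                total = vals.sum()
                vals = vals * (k / total) if total > 0 else np.full(k, 1.0)
            for c, v in zip(codons, vals):
                row[c] = float(v)
        rows.append([row[c] for c in code.sense_codons])
    df = pd.DataFrame(
        rows,
        index=[f"sp{i:02d}" for i in range(n_species)],
        columns=list(code.sense_codons),
    )
    return df, labels
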