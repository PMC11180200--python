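"""NG86 site/difference counting and Ka/Ks regime calls."""

import math
from itertools import permutations

import numpy as np
import pytest

from mitocomp.codon_usage import VERTEBRATE_MITO
from mitocomp.divergence import AlignmentBlock
from mitocomp.io_formats import SequenceRecord
from mitocomp.selection import (
    SelectionRegime,
    family_kaks,
    ng86_pair,
    ng86_sites,
    pathway_differences,
)
from mitocomp.synthetic_data import EvolveSimSpec, evolve_sequences

CODE = VERTEBRATE_MITO
SENSE = list(CODE.sense_codons)


def oracle_pathways(c1: str, c2: str):
    """Independent brute-force pathway average.

    Enumerates every ordering of the differing positions, walks the
    intermediate codons explicitly, and classifies each step by comparing
    translations; pathways visiting a stop are excluded unless all are,
    in which case the exclusion is waived (steps touching a stop count as
    nonsynonymous).
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    results_ok, results_blocked = [], []
    for order in permutations(diffs):
        codons = [c1]
        for pos in order:
            prev = codons[-1]
            codons.append(prev[:pos] + c2[pos] + prev[pos + 1 :])
        blocked = any(c in CODE.stop_codons for c in codons[1:-1])
        sd = nd = 0
        for u, v in zip(codons, codons[1:]):
            if u in CODE.stop_codons or v in CODE.stop_codons:
                nd += 1
            elif CODE.codon_to_aa[u] == CODE.codon_to_aa[v]:
                sd += 1
            else:
                nd += 1
        (results_blocked if blocked else results_ok).append((sd, nd))
    pool = results_ok or results_blocked
    return (
        sum(r[0] for r in pool) / len(pool),
        sum(r[1] for r in pool) / len(pool),
    )


class TestSites:
    def test_phenylalanine_example(self):
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_fourfold_third_position(self):
        s, n = ng86_sites("GTT")  # Val
        assert (s, n) == (1.0, 2.0)

    def test_sites_sum_to_three_for_every_sense_codon(self):
        for codon in SENSE:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            assert s >= 0.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestPathways:
    def test_full_sense_grid_matches_exhaustive_oracle(self):
        """Pathway averaging equals brute-force enumeration on all 60x60 pairs."""
        for c1 in SENSE:
            for c2 in SENSE:
                got = pathway_differences(c1, c2, CODE)
                want = oracle_pathways(c1, c2)
                assert got[0] == pytest.approx(want[0], abs=1e-12), (c1, c2)
                assert got[1] == pytest.approx(want[1], abs=1e-12), (c1, c2)

    def test_total_differences_equal_hamming_distance(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            c1, c2 = rng.choice(SENSE, 2)
            sd, nd = pathway_differences(c1, c2, CODE)
            assert sd + nd == pytest.approx(sum(a != b for a, b in zip(c1, c2)))

    def test_mito_specific_synonymy(self):
        """ATG->ATA is synonymous under code 2 (both Met) - a regression
        guard that the standard code is not in use."""
        assert pathway_differences("ATG", "ATA", CODE) == (1.0, 0.0)


class TestPairwise:
    def test_identical_pair_is_undefined(self):
        res = ng86_pair("ATGAAA", "ATGAAA")
        assert res.Sd == res.Nd == 0.0
        assert res.regime is SelectionRegime.UNDEFINED

    def test_met_codon_pair_counts(self):
        res = ng86_pair("ATGATG", "ATAATG")
        assert (res.Sd, res.Nd) == (1.0, 0.0)

    def test_symmetry_and_site_identity(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = "".join(rng.choice(SENSE, 30))
            b = "".join(rng.choice(SENSE, 30))
            r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
            assert (r1.S, r1.N, r1.Sd, r1.Nd) == (r2.S, r2.N, r2.Sd, r2.Nd)
            assert r1.S + r1.N == pytest.approx(3 * r1.n_codons_compared)

    def test_gap_codons_skipped(self):
        res = ng86_pair("ATG---AAA", "ATGAAAAAA")
        assert res.n_codons_compared == 2 and res.n_codons_skipped == 1

    def test_synonymous_only_divergence_is_purifying(self):
        """Fourfold third-position changes only: Nd = 0, regime purifying."""
        a = "GTT" * 30
        b = ("GTT" * 9 + "GTA") * 3  # 10% synonymous divergence, Val throughout
        res = ng86_pair(a, b)
        assert res.Nd == 0.0
        assert res.regime is SelectionRegime.PURIFYING

    def test_frame_violations_rejected(self):
        with pytest.raises(ValueError):
            ng86_pair("ATGA", "ATGA")
        with pytest.raises(ValueError):
            ng86_pair("ATG", "ATGAAA")


class TestFamily:
    def _family(self, omega, seed, n_codons=400):
        rng = np.random.default_rng(1000 + seed)
        root = "".join(rng.choice(SENSE, n_codons))
        spec = EvolveSimSpec(
            tree="(a:0.2,b:0.2,c:0.2,d:0.2);", kappa=2.0, omega=omega, locus="sim"
        )
        block = evolve_sequences(root, spec, mode="codon", seed=seed)
        return family_kaks(block)

    def test_identical_family_undefined(self):
        recs = tuple(
            SequenceRecord(id=f"s{i}", residues="ATGAAACCC") for i in range(3)
        )
        res = family_kaks(AlignmentBlock(locus="x", records=recs))
        assert res.regime is SelectionRegime.UNDEFINED

    def test_purifying_regime_recovered(self):
        res = self._family(omega=0.1, seed=1)
        assert res.regime is SelectionRegime.PURIFYING
        assert res.ratio < 0.5

    def test_positive_regime_recovered(self):
        res = self._family(omega=2.0, seed=2)
        assert res.regime is SelectionRegime.POSITIVE

    def test_mean_pairwise_ratio_reported(self):
        res = self._family(omega=0.1, seed=3)
        assert not math.isnan(res.mean_pairwise_ratio)
        assert res.n_undefined_pairs == 0
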