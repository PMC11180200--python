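"""Gene geometry: adjacency ledger, PCG accounting, stop-codon classes."""

import numpy as np
import pytest

from mitocomp.geometry import (
    StopStatus,
    classify_stop_codon,
    summarize_geometry,
)
from mitocomp.io_formats import GeneClass, GeneFeature, GeneTable, Strand


def _table(rows, length, species="toy"):
    feats = tuple(
        GeneFeature(n, s, e, Strand.H, GeneClass(c)) for n, s, e, c in rows
    )
    return GeneTable(species_id=species, genome_length=length, features=feats)


class TestAdjacency:
    def test_abutting_genes_have_no_gap_or_overlap(self):
        s = summarize_geometry(_table([("cox1", 1, 10, "PCG"), ("cox2", 11, 20, "PCG")], 20))
        assert not s.igs_reports and not s.overlap_reports

    def test_single_feature_table_yields_empty_ledgers(self):
        s = summarize_geometry(_table([("cox1", 1, 10, "PCG")], 10))
        assert not s.igs_reports and not s.overlap_reports

    def test_gap_and_overlap_sizes(self):
        s = summarize_geometry(
            _table(
                [("cox1", 1, 10, "PCG"), ("cox2", 14, 25, "PCG"), ("cox3", 20, 30, "PCG")],
                30,
            )
        )
        assert [(r.gene_a, r.gene_b, r.gap_bp) for r in s.igs_reports] == [
            ("cox1", "cox2", 3)
        ]
        assert [(r.gene_a, r.gene_b, r.overlap_bp) for r in s.overlap_reports] == [
            ("cox2", "cox3", 6)
        ]
        assert s.pcg_pcg_overlap_total == 6

    def test_randomized_tables_match_occupancy_oracle(self):
        """gap/overlap ledger equals a brute-force per-base occupancy count."""
        rng = np.random.default_rng(17)
        classes = ["PCG", "tRNA", "rRNA", "NC"]
        for _ in range(50):
            n = int(rng.integers(2, 15))
            rows, pos, prev_start = [], 1, 0
            for i in range(n):
                step = int(rng.integers(-8, 8))  # negative => overlap
                # keep starts and ends strictly increasing: nested features
                # are out of scope for the adjacency ledger
                start = max(1, prev_start + 1, pos + step)
                length = max(3, pos - start + 1) + int(rng.integers(0, 60))
                rows.append((f"g{i}", start, start + length - 1, classes[rng.integers(4)]))
                pos, prev_start = start + length, start
            genome_len = max(e for _, _, e, _ in rows) + int(rng.integers(0, 30))
            table = _table(rows, genome_len)
            s = summarize_geometry(table)
            # oracle: per-base set occupancy for each consecutive pair
            feats = table.features
            gaps, overlaps = [], []
            for a, b in zip(feats, feats[1:]):
                cov_a = set(range(a.start, a.end + 1))
                cov_b = set(range(b.start, b.end + 1))
                between = {
                    x
                    for x in range(min(cov_a), max(cov_b) + 1)
                    if min(cov_b) > x > max(cov_a)
                }
                shared = cov_a & cov_b
                if between - cov_a - cov_b:
                    gaps.append(len(between - cov_a - cov_b))
                if shared:
                    overlaps.append(len(shared))
            assert [r.gap_bp for r in s.igs_reports] == gaps
            assert [r.overlap_bp for r in s.overlap_reports] == overlaps

    def test_conservation_identity_on_random_nonoverlapping_tables(self):
        """sum(lengths) + gaps + flanks = genome length when nothing overlaps."""
        rng = np.random.default_rng(23)
        for _ in range(30):
            rows, pos = [], 1 + int(rng.integers(0, 10))
            for i in range(int(rng.integers(2, 12))):
                start = pos + int(rng.integers(0, 9))
                length = int(rng.integers(3, 50))
                rows.append((f"g{i}", start, start + length - 1, "PCG"))
                pos = start + length
            tail = int(rng.integers(0, 10))
            genome_len = rows[-1][2] + tail
            s = summarize_geometry(_table(rows, genome_len))
            total = sum(l for _, l in s.gene_lengths)
            gaps = sum(r.gap_bp for r in s.igs_reports)
            head = rows[0][1] - 1
            assert total + gaps + head + tail == genome_len

    def test_summary_invariant_under_row_order(self):
        rows = [("cox1", 5, 30, "PCG"), ("trnF", 1, 6, "tRNA"), ("CR", 40, 80, "NC")]
        a = summarize_geometry(_table(rows, 80))
        b = summarize_geometry(_table(list(reversed(rows)), 80))
        assert a == b


class TestOpamaGeometry:
    """The published feature-table arithmetic, reproduced from coordinates."""

    def test_pcg_totals(self, opama_geometry):
        assert opama_geometry.total_pcg_length == 11437
        assert opama_geometry.pcg_fraction == pytest.approx(69.26, abs=0.005)
        assert opama_geometry.pcg_min_length == 168   # atp8
        assert opama_geometry.pcg_max_length == 1839  # nad5

    def test_gap_and_overlap_census(self, opama_geometry):
        gaps = [r.gap_bp for r in opama_geometry.igs_reports]
        ovls = [r.overlap_bp for r in opama_geometry.overlap_reports]
        assert len(gaps) == 10 and min(gaps) == 1 and max(gaps) == 7
        assert len(ovls) == 9 and min(ovls) == 1 and max(ovls) == 10

    def test_pcg_pcg_overlaps(self, opama_geometry):
        pairs = {
            (r.gene_a, r.gene_b): r.overlap_bp
            for r in opama_geometry.pcg_pcg_overlap_pairs
        }
        assert pairs == {
            ("atp8", "atp6"): 10,
            ("atp6", "cox3"): 1,
            ("nad4l", "nad4"): 7,
            ("nad5", "nad6"): 4,
        }
        assert opama_geometry.pcg_pcg_overlap_total == 22
        # "seven PCGs": the count of participants, not of pairs
        assert len(opama_geometry.pcg_pcg_participants) == 7


class TestStopCodons:
    @pytest.mark.parametrize(
        "seq, status, observed, completed",
        [
            ("ATGAAATAA", StopStatus.COMPLETE, "TAA", "TAA"),
            ("ATGAAAAGA", StopStatus.COMPLETE, "AGA", "AGA"),  # the cox1 case
            ("ATGAAATAG", StopStatus.COMPLETE, "TAG", "TAG"),
            ("ATGGCCT", StopStatus.INCOMPLETE, "T", "TAA"),
            ("ATGGCCTA", StopStatus.INCOMPLETE, "TA", "TAA"),
            ("ATGGCCC", StopStatus.NONE, "C", None),
            ("ATGAAACCC", StopStatus.NONE, "CCC", None),
        ],
    )
    def test_classification(self, seq, status, observed, completed):
        call = classify_stop_codon(seq, "g")
        assert (call.status, call.codon_observed, call.completed_codon) == (
            status, observed, completed,
        )

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            classify_stop_codon("ATG")
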