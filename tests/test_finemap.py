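"""Corner-signature fine-mapping: argmax, windows, detection, refinement."""

import numpy as np
import pytest

from hicprox.contacts import RawContactMap, bin_read_pairs, expected_trans
from hicprox.errors import NoSignalError
from hicprox.finemap import (
    corner_detect,
    finemap_pair,
    max_trans_bin,
    refine_1kb,
    scan_genome,
    window_reads,
)
from hicprox.regions import BinScheme, GenomeAssembly
from hicprox.simulate import (
    SimConfig,
    simulate_background_reads,
    simulate_translocation_reads,
)

CHROM_LEN = 30_000_000
LENGTHS = {"chr1": CHROM_LEN, "chr2": CHROM_LEN}


def _scheme():
    return BinScheme(
        GenomeAssembly(("chr1", "chr2"), (CHROM_LEN, CHROM_LEN)), 1_000_000
    )


def expected_fine_bin(pos, sign, bin_size):
    """Bin holding the reads adjacent to a breakpoint: for a '-' direction
    the reads sit just below the breakpoint coordinate."""
    return pos // bin_size if sign == "+" else (pos - 1) // bin_size


class TestMaxTransBin:
    def test_single_nonzero_and_tie_rule(self, toy_scheme):
        cmap = RawContactMap(toy_scheme)
        cmap.add_count("chr1", 3, "chr2", 7, 5)
        assert max_trans_bin(cmap, ("chr1", "chr2")) == (3, 7)
        cmap.add_count("chr1", 5, "chr2", 1, 5)  # equal maximum
        assert max_trans_bin(cmap, ("chr1", "chr2")) == (3, 7)  # lexicographic

    def test_all_zero_raises(self, toy_scheme):
        with pytest.raises(NoSignalError):
            max_trans_bin(RawContactMap(toy_scheme), ("chr1", "chr2"))

    def test_normalized_and_raw_agree_on_planted_signal(self):
        scheme = _scheme()
        rng = np.random.default_rng(1)
        reads = simulate_translocation_reads(
            ("chr1", 10_500_000, "chr2", 20_500_000), "++", 2000, rng,
            chrom_lengths=LENGTHS,
        ) + simulate_background_reads(
            SimConfig(n_chroms=2, chrom_length=CHROM_LEN,
                      background_read_rate=2.0, rng_seed=2),
            scheme, rng,
        )
        cmap = bin_read_pairs(reads, scheme)
        raw = max_trans_bin(cmap, ("chr1", "chr2"))
        norm = max_trans_bin(
            cmap, ("chr1", "chr2"), expected=expected_trans(cmap)
        )
        assert raw == norm == (10, 20)


class TestWindowReads:
    def test_partition_and_centering(self):
        reads = [
            ("chr1", 10_500_000, "chr2", 20_500_000),  # window center
            ("chr1", 9_000_000, "chr2", 20_000_000),   # left edge inclusive
            ("chr1", 8_999_999, "chr2", 20_000_000),   # one end outside
            ("chr2", 21_999_999, "chr1", 11_999_999),  # swapped orientation, in
            ("chr1", 1_000_000, "chr2", 1_000_000),    # far away
        ]
        win, origin = window_reads(
            reads, ("chr1", "chr2"), (10, 20), chrom_lengths=LENGTHS
        )
        assert origin == (9_000_000, 19_000_000)
        assert len(win) == 3
        assert (11_999_999, 21_999_999) in win

    def test_window_clipped_at_chromosome_start(self):
        win, origin = window_reads(
            [("chr1", 0, "chr2", 0)], ("chr1", "chr2"), (0, 0),
            chrom_lengths=LENGTHS,
        )
        assert origin == (0, 0) and len(win) == 1


class TestCornerDetect:
    BOUNDS = ((9_000_000, 12_000_000), (19_000_000, 22_000_000))

    def _planted_window(self, orientation, n=2000, seed=3):
        rng = np.random.default_rng(seed)
        bp = ("chr1", 10_500_000, "chr2", 20_500_000)
        reads = simulate_translocation_reads(
            bp, orientation, n, rng, chrom_lengths=LENGTHS
        )
        win, _ = window_reads(
            reads, ("chr1", "chr2"), (10, 20), chrom_lengths=LENGTHS
        )
        return win, bp

    @pytest.mark.parametrize("orientation", ["++", "+-", "-+", "--"])
    def test_planted_orientation_and_corner_recovered(self, orientation):
        win, bp = self._planted_window(orientation)
        det = corner_detect(win, window_bounds=self.BOUNDS)
        assert det["called"] and det["orientation"] == orientation
        assert det["signature_score"] > 0.9
        expected = (
            expected_fine_bin(bp[1], orientation[0], 50_000),
            expected_fine_bin(bp[3], orientation[1], 50_000),
        )
        assert det["corner_bin"] == expected

    def test_uniform_window_produces_no_call(self):
        rng = np.random.default_rng(4)
        win = list(zip(
            rng.integers(9_000_000, 12_000_000, 3000),
            rng.integers(19_000_000, 22_000_000, 3000),
        ))
        det = corner_detect(win, window_bounds=self.BOUNDS)
        assert not det["called"]
        # quadrant enrichment over the uniform expectation stays near 0.25
        assert det["signature_score"] < 0.6

    def test_balanced_two_quadrant_pattern_rejected(self):
        # opposite quadrants each holding ~50%: no single-quadrant signature
        rng = np.random.default_rng(5)
        a = simulate_translocation_reads(
            ("chr1", 10_500_000, "chr2", 20_500_000), "++", 1000, rng,
            chrom_lengths=LENGTHS,
        )
        b = simulate_translocation_reads(
            ("chr1", 10_500_000, "chr2", 20_500_000), "--", 1000, rng,
            chrom_lengths=LENGTHS,
        )
        win, _ = window_reads(
            a + b, ("chr1", "chr2"), (10, 20), chrom_lengths=LENGTHS
        )
        det = corner_detect(win, window_bounds=self.BOUNDS)
        assert not det["called"]
        # the second cloud fills the diagonally opposite quadrant, so the
        # exclusivity requirement of an unbalanced call fails
        assert det["opposite_fraction"] > 0.2

    def test_insufficient_coverage_signalled(self):
        win, _ = self._planted_window("++", n=50)
        det = corner_detect(win, window_bounds=self.BOUNDS)
        assert det["status"] == "insufficient_coverage" and not det["called"]


class TestRefine:
    def test_argmax_bin_and_sparse_threshold(self):
        corner = (210, 410)  # 50-kb ordinals
        base = (210 * 50_000, 410 * 50_000)
        rng = np.random.default_rng(6)
        # 25 reads in one 1-kb bin, 5 scattered elsewhere in the corner bin
        target = (base[0] + 7_000, base[1] + 3_000)
        win = [(target[0] + int(r), target[1] + int(r2))
               for r, r2 in zip(rng.integers(0, 1000, 25), rng.integers(0, 1000, 25))]
        win += [(base[0] + int(x), base[1] + int(y))
                for x, y in zip(rng.integers(0, 50_000, 5), rng.integers(0, 50_000, 5))]
        refined, status = refine_1kb(win, corner)
        assert status == "refined"
        assert refined == (target[0] // 1000, target[1] // 1000)

    def test_below_threshold_is_sparse(self):
        corner = (210, 410)
        win = [(210 * 50_000 + 1, 410 * 50_000 + 1)] * 5
        refined, status = refine_1kb(win, corner)
        assert refined is None and status == "sparse"

    def test_exactly_min_reads_attempts_refinement(self):
        corner = (210, 410)
        win = [(210 * 50_000 + 500, 410 * 50_000 + 500)] * 20
        refined, status = refine_1kb(win, corner)
        assert status == "refined" and refined is not None


class TestScanGenome:
    def test_planted_translocation_flagged_exclusively(self):
        scheme = BinScheme(
            GenomeAssembly(("chr1", "chr2", "chr3"), (CHROM_LEN,) * 3),
            1_000_000,
        )
        rng = np.random.default_rng(7)
        reads = simulate_translocation_reads(
            ("chr1", 10_500_000, "chr3", 20_500_000), "++", 2000, rng,
            chrom_lengths={"chr1": CHROM_LEN, "chr3": CHROM_LEN},
        )
        bg = simulate_background_reads(
            SimConfig(n_chroms=3, chrom_length=CHROM_LEN,
                      background_read_rate=2.0, rng_seed=8),
            scheme, rng,
        )
        hits = scan_genome(bin_read_pairs(reads + bg, scheme))
        assert len(hits) == 1
        assert hits[0]["chrom_pair"] == ("chr1", "chr3")
        assert hits[0]["coarse_bin"] == (10, 20)

    def test_background_only_yields_no_flags(self):
        scheme = _scheme()
        flags = 0
        for seed in range(20):
            cfg = SimConfig(
                n_chroms=2, chrom_length=CHROM_LEN,
                background_read_rate=5.0, rng_seed=300 + seed,
            )
            rng = np.random.default_rng(300 + seed)
            cmap = bin_read_pairs(
                simulate_background_reads(cfg, scheme, rng), scheme
            )
            flags += len(scan_genome(cmap)) > 0
        assert flags <= 1  # >= 95% clean

    def test_empty_map_gives_empty_list(self, toy_scheme):
        assert scan_genome(RawContactMap(toy_scheme)) == []


class TestEndToEnd:
    def test_full_hierarchy_recovers_planted_breakpoint(self):
        scheme = _scheme()
        rng = np.random.default_rng(9)
        bp = ("chr1", 10_337_000, "chr2", 20_721_000)
        reads = simulate_translocation_reads(
            bp, "+-", 2000, rng, chrom_lengths=LENGTHS
        ) + simulate_background_reads(
            SimConfig(n_chroms=2, chrom_length=CHROM_LEN,
                      background_read_rate=2.0, rng_seed=10),
            scheme, rng,
        )
        cmap = bin_read_pairs(reads, scheme)
        call = finemap_pair(reads, cmap, ("chr1", "chr2"))
        assert call.status in ("called", "sparse_refinement")
        assert call.orientation == "+-"
        assert call.corner_bin_50kb == (
            expected_fine_bin(bp[1], "+", 50_000),
            expected_fine_bin(bp[3], "-", 50_000),
        )
        # containment invariants: corner within the 3-Mb window of the
        # coarse bin; refinement within the corner bin
        c1 = call.corner_bin_50kb[0] * 50_000
        assert abs(c1 - call.coarse_bin[0] * 1_000_000) <= 2_000_000
        if call.refined_bin_1kb is not None:
            assert call.refined_bin_1kb[0] * 1000 // 50_000 == call.corner_bin_50kb[0]
            assert call.refined_bin_1kb[1] * 1000 // 50_000 == call.corner_bin_50kb[1]
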