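"""Large-repeat detection, orientation calls and quadripartite statistics."""

import numpy as np
import pytest

from plastevol.io import PlastomeRecord, reverse_complement_record, rotate_record
from plastevol.structure import (
    RegionPartition,
    RepeatPair,
    classify_orientation,
    find_large_repeat,
    partition_regions,
    region_stats,
)


def _random_seq(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def planted_genome(orientation, seed=0, n=20000, rep_len=2000, a0=3000, b0=12000):
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, n))
    rep = _random_seq(rng, rep_len)
    second = rep if orientation == "direct" else _revcomp(rep)
    seq[a0 : a0 + rep_len] = rep
    seq[b0 : b0 + rep_len] = second
    return PlastomeRecord(id=f"planted-{orientation}", sequence="".join(seq), features=[])


class TestRepeatDetection:
    @pytest.mark.parametrize("orientation", ["inverted", "direct"])
    def test_planted_repeat_found_at_planted_coordinates(self, orientation):
        rec = planted_genome(orientation)
        rp = find_large_repeat(rec, min_len=1000)
        assert rp is not None
        assert rp.orientation == orientation
        assert abs(rp.copy_a[0] - 3000) <= 20 and abs(rp.copy_a[1] - 5000) <= 20
        assert abs(rp.copy_b[0] - 12000) <= 20 and abs(rp.copy_b[1] - 14000) <= 20
        assert rp.identity > 0.99

    def test_no_repeat_returns_none(self):
        rng = np.random.default_rng(1)
        rec = PlastomeRecord(id="plain", sequence=_random_seq(rng, 20000), features=[])
        assert find_large_repeat(rec, min_len=1000) is None

    def test_matches_exact_dp_oracle_boundaries(self):
        """Seed-and-extend agrees with a brute-force longest-common-run scan."""
        rec = planted_genome("inverted", seed=5, n=6000, rep_len=600, a0=1000, b0=4000)
        rp = find_large_repeat(rec, min_len=300)
        seq = rec.sequence
        rc = _revcomp(seq)
        n = len(seq)
        # oracle: longest exact run between seq and its reverse complement
        best = (0, 0, 0)
        for diff in range(-(n - 300), n - 300):
            run = 0
            for i in range(max(0, -diff), min(n, n - diff)):
                if seq[i] == rc[i + diff]:
                    run += 1
                    if run > best[0]:
                        best = (run, i - run + 1, i + diff - run + 1)
                else:
                    run = 0
        length, a_start, rc_start = best
        b_lo, b_hi = n - (rc_start + length), n - rc_start
        assert abs(rp.copy_a[0] - a_start) <= 20
        assert abs(rp.length - length) <= 40
        assert abs(rp.copy_b[0] - b_lo) <= 20

    def test_invariant_to_rotation_and_reverse_complement(self):
        rec = planted_genome("inverted", seed=2)
        base = find_large_repeat(rec, min_len=1000)
        rot = find_large_repeat(rotate_record(rec, 7000), min_len=1000)
        rc = find_large_repeat(reverse_complement_record(rec), min_len=1000)
        for other in (rot, rc):
            assert other.orientation == base.orientation
            assert abs(other.length - base.length) <= 40

    def test_short_sequence_rejected(self):
        rec = PlastomeRecord(id="short", sequence="ACGT" * 100, features=[])
        with pytest.raises(ValueError, match="too short"):
            find_large_repeat(rec, min_len=1000)


class TestOrientation:
    def test_classification(self):
        rp_ir = RepeatPair((0, 10), (20, 30), "inverted", 1.0)
        rp_dr = RepeatPair((0, 10), (20, 30), "direct", 1.0)
        assert classify_orientation(rp_ir) == "IR"
        assert classify_orientation(rp_dr) == "DR"

    def test_simulated_orientations_recovered(self, random_genomes):
        for records, truth in random_genomes:
            for tip, rec in records.items():
                rp = find_large_repeat(rec)
                assert classify_orientation(rp) == truth.orientation[tip], tip


class TestPartition:
    def test_arcs_assigned_by_length(self):
        rng = np.random.default_rng(3)
        rec = planted_genome("inverted", seed=3, n=20000, rep_len=2000, a0=1000, b0=13000)
        rp = find_large_repeat(rec, min_len=1000)
        part = partition_regions(rec, rp)
        assert part.lsc_length >= part.ssc_length
        assert part.lsc_length + part.ssc_length + 2 * rp.length == rec.length

    def test_tiling_invariant_on_simulated_genomes(self, random_genomes):
        for records, truth in random_genomes:
            for tip, rec in records.items():
                rp = find_large_repeat(rec)
                part = partition_regions(rec, rp)
                assert part.lsc_length + part.ssc_length + 2 * rp.length == rec.length

    def test_partition_matches_planted(self, random_genomes):
        records, truth = random_genomes[0]
        for tip, rec in records.items():
            rp = find_large_repeat(rec)
            planted = truth.partitions[tip].repeat
            assert abs(rp.copy_a[0] - planted.copy_a[0]) <= 20
            assert abs(rp.length - planted.length) <= 40

    def test_degenerate_partition_without_repeat(self):
        rng = np.random.default_rng(4)
        rec = PlastomeRecord(id="norep", sequence=_random_seq(rng, 20000), features=[])
        part = partition_regions(rec, None)
        assert not part.has_repeat
        assert part.lsc_length == rec.length and part.ssc_length == 0


class TestRegionStats:
    def test_all_gc_region(self):
        rec = planted_genome("inverted", seed=6)
        part = partition_regions(rec, find_large_repeat(rec, min_len=1000))
        stats = region_stats(rec, part)
        assert stats.total_length == rec.length
        # conservation: overall GC equals the length-weighted region mean
        weighted = (
            stats.gc_lsc * stats.lsc_length
            + stats.gc_ssc * stats.ssc_length
            + stats.gc_repeat * 2 * stats.repeat_length
        ) / stats.total_length
        assert abs(weighted - stats.gc_total) < 0.05

    def test_pure_gc_sequence(self):
        from plastevol.structure import _gc

        assert _gc("GCGC") == 100.0
        assert _gc("ATAT") == 0.0
        assert _gc("GCATNN") == 50.0  # N excluded from both sides

    def test_unique_gene_counts_exclude_second_copy(self, mini_clade):
        records, truth = mini_clade
        rec = records["T1"]
        rp = find_large_repeat(rec)
        part = partition_regions(rec, rp)
        stats = region_stats(rec, part)
        assert stats.n_rrna == 4  # duplicated in the repeat, counted once
        assert stats.n_genes == stats.n_protein + stats.n_rrna + stats.n_trna
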