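import numpy as np
import pytest

from ancestrylayers.datatypes import MISSING, MASK_IBD, DataFormatError, MaskedHaplotypeSet
from ancestrylayers.ibd_processing import (
    detect_ibd_exact,
    filter_cross_population,
    mask_ibd_segments,
    merge_ibd_blocks,
)
from conftest import make_haplotypes, make_ibd


def brute_force_runs(a, b, cm, min_len):
    """Oracle: scan every maximal identical run between two haplotypes."""
    runs, start = [], None
    for i in range(len(a) + 1):
        same = i < len(a) and a[i] == b[i]
        if same and start is None:
            start = i
        elif not same and start is not None:
            if cm[i - 1] - cm[start] >= min_len:
                runs.append((start, i - 1))
            start = None
    return runs


class TestDetect:
    def test_identical_haplotypes_single_full_segment(self):
        alleles = np.tile(np.array([[0], [1]] * 5, dtype=np.int8), (1, 2))
        hs = make_haplotypes(alleles)  # 10 sites, cm 1..10
        seg = detect_ibd_exact(hs, min_len_cm=1.0)
        # S1 hap1 == S1 hap2 over all 10 sites (9 cM span)
        assert len(seg) == 1
        row = seg.table.iloc[0]
        assert row["length_cm"] == pytest.approx(9.0)
        assert row["start"] == 100 and row["end"] == 1001

    def test_single_mismatch_splits_into_two_segments(self):
        a = np.zeros((11, 2), dtype=np.int8)
        a[5, 1] = 1
        hs = make_haplotypes(a)
        seg = detect_ibd_exact(hs, min_len_cm=2.0)
        lengths = sorted(seg.table["length_cm"])
        assert lengths == [pytest.approx(4.0), pytest.approx(4.0)]

    def test_matches_brute_force_on_random_haplotypes(self):
        rng = np.random.default_rng(6)
        alleles = rng.integers(0, 2, (1000, 6)).astype(np.int8)
        hs = make_haplotypes(alleles)
        seg = detect_ibd_exact(hs, min_len_cm=0.03)
        found = {(r.id1, r.hap1, r.id2, r.hap2, r.start, r.end)
                 for r in seg.table.itertuples(index=False)}
        expected = set()
        names = hs.haplotype_names()
        for x in range(6):
            for y in range(x + 1, 6):
                for i, j in brute_force_runs(alleles[:, x], alleles[:, y],
                                             hs.cm, 0.03):
                    sa, ha = names[x].rsplit("_", 1)
                    sb, hb = names[y].rsplit("_", 1)
                    key = tuple(sorted([(sa, int(ha)), (sb, int(hb))]))
                    expected.add((key[0][0], key[0][1], key[1][0], key[1][1],
                                  hs.positions[i], hs.positions[j] + 1))
        assert found == expected

    def test_missing_entries_rejected(self):
        a = np.zeros((5, 2), dtype=np.int8)
        a[0, 0] = MISSING
        with pytest.raises(DataFormatError, match="complete"):
            detect_ibd_exact(make_haplotypes(a))


def _two_block_setup(gap_sites, mismatches_in_gap=0):
    """Two identical haplotypes except a configurable central gap region."""
    n = 30
    a = np.zeros((n, 4), dtype=np.int8)
    # S1_1 and S2_1 identical on blocks [0..9] and [10+gap..n-1]
    gap_lo, gap_hi = 10, 10 + gap_sites
    for k in range(mismatches_in_gap):
        a[gap_lo + k, 2] = 1  # S2 differs inside the gap
    # positions spaced 0.1 cM apart
    positions = np.arange(1, n + 1) * 100
    cm = np.arange(n) * 0.1
    hs = make_haplotypes(a, positions=positions, cm=cm,
                         samples=["S1", "S2"], populations=["p1", "p2"])
    blocks = make_ibd([
        ("S1", 1, "S2", 1, "1", int(positions[0]), int(positions[9]) + 1, np.nan, 0.9),
        ("S1", 1, "S2", 1, "1", int(positions[gap_hi]), int(positions[n - 1]) + 1,
         np.nan, (n - 1 - gap_hi) * 0.1)])
    return hs, blocks


class TestMerge:
    def test_small_gap_no_mismatch_merges(self):
        hs, blocks = _two_block_setup(gap_sites=4)  # gap 0.4 cM
        merged = merge_ibd_blocks(blocks, hs, gap_max_cm=0.6, max_inconsistent=1)
        assert len(merged) == 1
        assert merged.table.loc[0, "start"] == 100
        assert merged.table.loc[0, "end"] == 3001

    def test_wide_gap_stays_split(self):
        hs, blocks = _two_block_setup(gap_sites=8)  # gap 0.8 cM
        merged = merge_ibd_blocks(blocks, hs, gap_max_cm=0.6, max_inconsistent=1)
        assert len(merged) == 2

    def test_two_inconsistencies_block_merge(self):
        hs, blocks = _two_block_setup(gap_sites=4, mismatches_in_gap=2)
        merged = merge_ibd_blocks(blocks, hs, gap_max_cm=0.6, max_inconsistent=1)
        assert len(merged) == 2
        one = merge_ibd_blocks(blocks, hs, gap_max_cm=0.6, max_inconsistent=2)
        assert len(one) == 1

    def test_merge_is_idempotent(self):
        hs, blocks = _two_block_setup(gap_sites=4)
        once = merge_ibd_blocks(blocks, hs)
        twice = merge_ibd_blocks(once, hs)
        assert once.table[["start", "end"]].equals(twice.table[["start", "end"]])

    def test_different_pairs_never_merged(self):
        hs, _ = _two_block_setup(gap_sites=2)
        blocks = make_ibd([
            ("S1", 1, "S2", 1, "1", 100, 900, np.nan, 0.8),
            ("S1", 2, "S2", 1, "1", 1000, 2000, np.nan, 1.0)])
        assert len(merge_ibd_blocks(blocks, hs)) == 2


class TestFilter:
    def _hs(self):
        return make_haplotypes(np.zeros((10, 4), dtype=np.int8),
                               samples=["S1", "S2"], populations=["p1", "p2"])

    def test_within_population_removed(self):
        hs = make_haplotypes(np.zeros((10, 4), dtype=np.int8),
                             samples=["S1", "S2"], populations=["p1", "p1"])
        seg = make_ibd([("S1", 1, "S2", 1, "1", 100, 900, np.nan, 5.0)])
        assert len(filter_cross_population(seg, hs)) == 0

    def test_short_cross_population_removed_strictly(self):
        seg = make_ibd([("S1", 1, "S2", 1, "1", 100, 900, np.nan, 0.9),
                        ("S1", 1, "S2", 2, "1", 100, 900, np.nan, 1.0),
                        ("S1", 2, "S2", 1, "1", 100, 900, np.nan, 1.5)])
        kept = filter_cross_population(seg, self._hs())
        assert list(kept.table["length_cm"]) == [1.5]  # 1.0 is not > 1.0

    def test_total_cm_conserved_per_record_vs_per_haplotype(self):
        rng = np.random.default_rng(8)
        rows = []
        for k in range(20):
            s, e = sorted(rng.integers(100, 1000, 2))
            rows.append((f"S{rng.integers(1, 3)}", rng.integers(1, 3),
                         f"T{rng.integers(1, 3)}", rng.integers(1, 3),
                         "1", int(s), int(e) + 1, np.nan, float(k + 1)))
        seg = make_ibd(rows)
        total = seg.total_cm()
        per_hap: dict = {}
        for r in seg.table.itertuples(index=False):
            per_hap[(r.id1, r.hap1)] = per_hap.get((r.id1, r.hap1), 0) + r.length_cm
            per_hap[(r.id2, r.hap2)] = per_hap.get((r.id2, r.hap2), 0) + r.length_cm
        assert sum(per_hap.values()) / 2 == pytest.approx(total)


class TestMaskIbd:
    def test_segment_masks_exactly_named_haplotypes(self):
        hs = make_haplotypes(np.ones((10, 4), dtype=np.int8),
                             samples=["S1", "S2"], populations=["p1", "p2"])
        mhs = MaskedHaplotypeSet.from_haplotypes(hs)
        seg = make_ibd([("S1", 1, "S2", 2, "1", 300, 701, np.nan, 4.0)])
        out = mask_ibd_segments(mhs, seg)
        # sites 3..7 (positions 300..700) on columns 0 (S1_1) and 3 (S2_2)
        assert (out.alleles[2:7, 0] == MISSING).all()
        assert (out.alleles[2:7, 3] == MISSING).all()
        assert (out.mask_reason[2:7, 0] == MASK_IBD).all()
        assert (out.alleles[:, 1] == 1).all() and (out.alleles[:, 2] == 1).all()
        assert int((out.alleles == MISSING).sum()) == 10

    def test_empty_segment_set_is_identity(self):
        hs = make_haplotypes(np.ones((5, 2), dtype=np.int8))
        mhs = MaskedHaplotypeSet.from_haplotypes(hs)
        out = mask_ibd_segments(mhs, make_ibd([]))
        np.testing.assert_array_equal(out.alleles, mhs.alleles)

    def test_unknown_haplotype_rejected(self):
        hs = make_haplotypes(np.ones((5, 2), dtype=np.int8))
        mhs = MaskedHaplotypeSet.from_haplotypes(hs)
        seg = make_ibd([("S9", 1, "S1", 1, "1", 100, 300, np.nan, 2.0)])
        with pytest.raises(DataFormatError, match="unknown sample"):
            mask_ibd_segments(mhs, seg)

    def test_masked_count_matches_true_segment_scan(self, small_cohort):
        cohort, _ = small_cohort
        hs = cohort.haplotypes
        kept = filter_cross_population(cohort.ibd, hs, 1.0)
        mhs = MaskedHaplotypeSet.from_haplotypes(hs)
        out = mask_ibd_segments(mhs, kept)
        expected = np.zeros(hs.alleles.shape, dtype=bool)
        for r in kept.table.itertuples(index=False):
            lo = np.searchsorted(hs.positions, r.start)
            hi = np.searchsorted(hs.positions, r.end)
            expected[lo:hi, hs.haplotype_column(r.id1, r.hap1)] = True
            expected[lo:hi, hs.haplotype_column(r.id2, r.hap2)] = True
        assert int((out.alleles == MISSING).sum()) == int(expected.sum())

    def test_no_surviving_cross_population_ibd_after_masking(self, small_cohort):
        # after masking, rerunning detection (missing treated as mismatch)
        # finds no cross-population segment >= 1 cM inside the masked regions
        cohort, _ = small_cohort
        hs = cohort.haplotypes
        kept = filter_cross_population(cohort.ibd, hs, 1.0)
        out = mask_ibd_segments(MaskedHaplotypeSet.from_haplotypes(hs), kept)
        for r in kept.table.itertuples(index=False):
            ca = hs.haplotype_column(r.id1, r.hap1)
            cb = hs.haplotype_column(r.id2, r.hap2)
            lo = np.searchsorted(hs.positions, r.start)
            hi = np.searchsorted(hs.positions, r.end)
            a, b = out.alleles[lo:hi, ca], out.alleles[lo:hi, cb]
            ok = (a != MISSING) & (b != MISSING) & (a == b)
            runs = np.flatnonzero(~ok)
            # every run of surviving identity inside the region spans < 1 cM
            cm = hs.cm[lo:hi]
            bounds = np.concatenate(([-1], runs, [len(ok)]))
            for k in range(len(bounds) - 1):
                i, j = bounds[k] + 1, bounds[k + 1] - 1
                if j > i:
                    assert cm[j] - cm[i] < 1.0
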