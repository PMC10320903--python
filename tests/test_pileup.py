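import numpy as np
import pytest

from regionstack import (
    PointConfig,
    SnippetStack,
    SortOrder,
    aggregate_1d,
    aggregate_2d,
    extract_1d,
    extract_2d,
    open_contacts,
    open_track,
    point_frames,
    sort_order_by_track,
    stacked_profiles,
)
from regionstack.pileup import PileupError, apply_sort_order, insulation_contrast

from conftest import make_regions, per_bp_mean_oracle, random_step_track


def point_set(assembly, anchors, chrom="chr1"):
    return make_regions(assembly, [(chrom, a - 1, a + 1) for a in anchors])


class TestExtract1D:
    def test_constant_track(self, assembly, write_text_track):
        track = open_track(write_text_track([("chr1", 0, 1_000_000, 3.0)]))
        rs = point_set(assembly, [100_000, 200_000, 300_000, 400_000, 500_000])
        stack = extract_1d(track, point_frames(rs, PointConfig(4000, 1000)))
        assert stack.values.shape == (5, 8)
        np.testing.assert_allclose(stack.values, 3.0)

    def test_out_of_bounds_bins_are_nan(self, assembly, write_text_track):
        track = open_track(write_text_track([("chr1", 0, 1_000_000, 3.0)]))
        rs = point_set(assembly, [2000])
        stack = extract_1d(track, point_frames(rs, PointConfig(5000, 1000)))
        row = stack.values[0]
        assert np.isnan(row[:3]).all() and np.allclose(row[3:], 3.0)

    def test_flip_on_minus_strand(self, assembly, write_text_track):
        import pandas as pd

        from regionstack import RegionSet

        track = open_track(write_text_track([("chr1", 99_000, 100_000, 7.0)]))
        track.set_chrom_lengths({"chr1": 1_000_000})
        df = pd.DataFrame([("chr1", 99_999, 100_001, "f", "+"),
                           ("chr1", 99_999, 100_001, "r", "-")],
                          columns=["chrom", "start", "end", "name", "strand"])
        rs = RegionSet(kind="point", records=df, assembly=assembly)
        frames = point_frames(rs, PointConfig(2000, 500))
        plain = extract_1d(track, frames)
        flipped = extract_1d(track, frames, flip_minus_strand=True)
        np.testing.assert_array_equal(flipped.values[0], plain.values[0])
        np.testing.assert_array_equal(flipped.values[1], plain.values[1][::-1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_bp_oracle(self, seed, assembly, write_text_track):
        rng = np.random.default_rng(seed)
        intervals = random_step_track(rng, 50_000)
        track = open_track(write_text_track(
            [("chr1", s, e, v) for s, e, v in intervals], f"t{seed}.txt"))
        track.set_chrom_lengths({"chr1": 1_000_000})
        anchors = rng.integers(2_000, 48_000, size=4)
        rs = point_set(assembly, sorted(set(int(a) for a in anchors)))
        frames = point_frames(rs, PointConfig(3000, 500))
        stack = extract_1d(track, frames)
        for frame, row in zip(frames, stack.values):
            expected = per_bp_mean_oracle(intervals, 1_000_000,
                                          frame.int_edges().astype(float))
            expected[frame.out_of_bounds] = np.nan
            np.testing.assert_allclose(row, expected, atol=1e-9)


class TestAggregate1D:
    def test_column_means(self):
        stack = SnippetStack(values=[[1.0, 2.0], [3.0, 4.0]], region_ids=[0, 1])
        np.testing.assert_allclose(aggregate_1d(stack), [2.0, 3.0])

    def test_nan_ignoring(self):
        stack = SnippetStack(values=[[1.0, np.nan], [3.0, 4.0]], region_ids=[0, 1])
        np.testing.assert_allclose(aggregate_1d(stack), [2.0, 4.0])

    def test_all_nan_bin_stays_nan(self):
        stack = SnippetStack(values=[[1.0, np.nan], [3.0, np.nan]], region_ids=[0, 1])
        out = aggregate_1d(stack)
        assert out[0] == 2.0 and np.isnan(out[1])

    def test_empty_stack_rejected(self):
        with pytest.raises(PileupError):
            aggregate_1d(SnippetStack(values=np.empty((0, 4)), region_ids=[]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(20, 7))
        values[rng.random(values.shape) < 0.3] = np.nan
        stack = SnippetStack(values=values, region_ids=np.arange(20))
        got = aggregate_1d(stack)
        for j in range(7):
            col = [v for v in values[:, j] if not np.isnan(v)]
            if col:
                assert got[j] == pytest.approx(np.mean(col), abs=1e-12)
            else:
                assert np.isnan(got[j])


class TestExtract2D:
    def test_identity_diagonal_store(self, assembly, write_text_contacts):
        n = 1000
        trip = [(i, i, 1.0) for i in range(n)]
        p = write_text_contacts(1000, {"chr1": 1_000_000}, trip)
        rs = point_set(assembly, [500_000])
        stack = extract_2d(open_contacts(p), point_frames(rs, PointConfig(5000, 1000)))
        snip = stack.values[0]
        np.testing.assert_allclose(np.diag(snip), 1.0)
        assert np.nansum(snip) == pytest.approx(10.0)

    def test_chromosome_start_gives_square_nan_block(self, assembly, write_text_contacts):
        p = write_text_contacts(1000, {"chr1": 1_000_000}, [(0, 0, 1.0)])
        rs = point_set(assembly, [2000])
        stack = extract_2d(open_contacts(p), point_frames(rs, PointConfig(5000, 1000)))
        snip = stack.values[0]
        assert np.isnan(snip[:3, :]).all() and np.isnan(snip[:, :3]).all()
        assert not np.isnan(snip[3:, 3:]).any()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_slice_oracle(self, seed, assembly, write_text_contacts):
        rng = np.random.default_rng(seed)
        binsize, nb = 1000, 50
        dense = np.zeros((nb, nb))
        trip = []
        for _ in range(60):
            i, j = sorted(rng.integers(0, nb, size=2))
            if dense[i, j]:
                continue
            v = float(rng.integers(1, 30))
            dense[i, j] = dense[j, i] = v
            trip.append((i, j, v))
        p = write_text_contacts(binsize, {"chr1": nb * binsize}, trip, f"c{seed}.txt")
        anchors = sorted(set(int(a) for a in rng.integers(5_000, 45_000, size=3)))
        rs = point_set(assembly, anchors)
        frames = point_frames(rs, PointConfig(4000, 1000))
        stack = extract_2d(open_contacts(p), frames)
        for frame, snip in zip(frames, stack.values):
            i0 = int(np.floor(frame.edges[0] / binsize + 0.5))
            expected = np.full((8, 8), np.nan)
            lo, hi = max(i0, 0), min(i0 + 8, nb)
            expected[lo - i0:hi - i0, lo - i0:hi - i0] = dense[lo:hi, lo:hi]
            expected[frame.out_of_bounds, :] = np.nan
            expected[:, frame.out_of_bounds] = np.nan
            np.testing.assert_allclose(snip, expected, atol=1e-12)

    def test_no_fine_enough_binsize_rejected(self, assembly, write_text_contacts):
        p = write_text_contacts(5000, {"chr1": 1_000_000}, [(0, 0, 1.0)])
        rs = point_set(assembly, [500_000])
        with pytest.raises(PileupError, match="binsize"):
            extract_2d(open_contacts(p), point_frames(rs, PointConfig(5000, 1000)))


class TestAggregate2D:
    def test_pixelwise_mean(self):
        stack = SnippetStack(values=[[[0.0, 2.0], [2.0, 0.0]],
                                     [[2.0, 0.0], [0.0, 2.0]]], region_ids=[0, 1])
        np.testing.assert_allclose(aggregate_2d(stack), [[1.0, 1.0], [1.0, 1.0]])

    def test_all_nan_snippet_excluded_per_pixel(self):
        stack = SnippetStack(values=[[[1.0, 1.0], [1.0, 1.0]],
                                     [[np.nan] * 2, [np.nan] * 2]], region_ids=[0, 1])
        np.testing.assert_allclose(aggregate_2d(stack), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(8, 5, 5))
        values[rng.random(values.shape) < 0.25] = np.nan
        stack = SnippetStack(values=values, region_ids=np.arange(8))
        got = aggregate_2d(stack)
        for j in range(5):
            for k in range(5):
                cell = [values[i, j, k] for i in range(8)
                        if not np.isnan(values[i, j, k])]
                if cell:
                    assert got[j, k] == pytest.approx(np.mean(cell), abs=1e-12)
                else:
                    assert np.isnan(got[j, k])

    def test_symmetric_store_gives_symmetric_average(self, assembly, write_text_contacts):
        rng = np.random.default_rng(11)
        nb = 200
        trip = [(i, j, float(rng.integers(1, 9)))
                for i in range(nb) for j in range(i, min(i + 10, nb))
                if rng.random() < 0.4]
        p = write_text_contacts(1000, {"chr1": 1_000_000}, trip)
        rs = point_set(assembly, [40_000, 80_000, 120_000])
        stack = extract_2d(open_contacts(p), point_frames(rs, PointConfig(10_000, 1000)))
        avg = aggregate_2d(stack)
        np.testing.assert_allclose(avg, avg.T, atol=1e-9)


class TestStackedProfiles:
    def _stack(self, n, bins=4, seed=0):
        rng = np.random.default_rng(seed)
        return SnippetStack(values=rng.normal(size=(n, bins)),
                            region_ids=np.arange(n))

    def test_under_cap_keeps_all_rows(self):
        matrix, order = stacked_profiles(self._stack(500), seed=1)
        assert matrix.shape[0] == 500
        assert len(order.region_ids) == 500

    def test_over_cap_subsamples_to_exactly_max_rows(self):
        matrix, order = stacked_profiles(self._stack(2500), seed=1)
        assert matrix.shape[0] == 1000
        assert len(set(order.region_ids.tolist())) == 1000

    def test_subsample_is_seeded(self):
        a, oa = stacked_profiles(self._stack(2500), seed=5)
        b, ob = stacked_profiles(self._stack(2500), seed=5)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(oa.region_ids, ob.region_ids)

    def test_sort_by_row_mean_descending(self):
        stack = SnippetStack(values=[[5.0, 5.0], [1.0, 1.0], [3.0, 3.0]],
                             region_ids=[0, 1, 2])
        order = sort_order_by_track(stack, "row_mean", descending=True)
        matrix, final = stacked_profiles(stack, order=order, seed=0)
        assert final.region_ids.tolist() == [0, 2, 1]
        np.testing.assert_allclose(matrix[:, 0], [5.0, 3.0, 1.0])

    def test_unknown_region_ids_rejected(self):
        stack = self._stack(10)
        bad = SortOrder(region_ids=np.arange(5, 20))
        with pytest.raises(PileupError, match="unknown region ids"):
            stacked_profiles(stack, order=bad, seed=0)

    def test_coupled_sorting_reorders_second_stack_consistently(self):
        rng = np.random.default_rng(2)
        a = SnippetStack(values=rng.normal(size=(50, 6)), region_ids=np.arange(50))
        b = SnippetStack(values=rng.normal(size=(50, 6)), region_ids=np.arange(50))
        order = sort_order_by_track(a, "row_mean")
        _, final = stacked_profiles(a, order=order, seed=0)
        b_sorted = apply_sort_order(b, final)
        np.testing.assert_array_equal(b_sorted.region_ids, final.region_ids)
        idx = [list(b.region_ids).index(r) for r in final.region_ids]
        np.testing.assert_array_equal(b_sorted.values, b.values[idx])


class TestSortOrder:
    def test_row_mean_descending(self):
        stack = SnippetStack(values=[[2.0, 2.0], [9.0, 9.0], [4.0, 4.0]],
                             region_ids=[0, 1, 2])
        order = sort_order_by_track(stack, "row_mean", descending=True)
        assert order.region_ids.tolist() == [1, 2, 0]

    def test_stable_ties_identity(self):
        stack = SnippetStack(values=np.ones((4, 3)), region_ids=[0, 1, 2, 3])
        order = sort_order_by_track(stack, "row_mean")
        assert order.region_ids.tolist() == [0, 1, 2, 3]

    def test_nan_rows_sort_last(self):
        stack = SnippetStack(values=[[np.nan, np.nan], [1.0, 1.0], [2.0, 2.0]],
                             region_ids=[0, 1, 2])
        order = sort_order_by_track(stack, "row_mean", descending=True)
        assert order.region_ids.tolist() == [2, 1, 0]

    def test_applying_order_twice_is_idempotent(self):
        rng = np.random.default_rng(7)
        stack = SnippetStack(values=rng.normal(size=(30, 5)),
                             region_ids=np.arange(30))
        order = sort_order_by_track(stack, "row_mean")
        once = apply_sort_order(stack, order)
        twice = apply_sort_order(once, order)
        np.testing.assert_array_equal(once.values, twice.values)


class TestAggregationInvariants:
    def test_aggregate_invariant_to_row_order(self):
        rng = np.random.default_rng(9)
        stack = SnippetStack(values=rng.normal(size=(40, 6)),
                             region_ids=np.arange(40))
        order = sort_order_by_track(stack, "row_mean")
        shuffled = apply_sort_order(stack, order)
        np.testing.assert_allclose(aggregate_1d(stack), aggregate_1d(shuffled),
                                   atol=1e-12)

    def test_planted_peak_recovered_at_center(self):
        from regionstack import SynthConfig, synth_genome, synth_regions, synth_track

        cfg = SynthConfig(seed=8, n_regions=80, mixture_fractions=(1.0,))
        asm, _ = synth_genome(cfg)
        regions, labels = synth_regions(cfg, asm)
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as d:
            path = synth_track(cfg, asm, regions, labels, subtype_effects=(1.0,),
                               out_path=Path(d) / "t.txt")
            track = open_track(path)
            stack = extract_1d(track, point_frames(regions, PointConfig(10_000, 1000)))
        profile = aggregate_1d(stack)
        n = len(profile)
        assert abs(int(np.argmax(profile)) - n // 2) <= 1

    def test_insulation_contrast_detects_planted_boundary(self, assembly,
                                                          write_text_contacts):
        # two-level block matrix: contacts crossing bin 50 are depleted
        nb, bs = 100, 1000
        trip = []
        for i in range(nb):
            for j in range(i, min(i + 12, nb)):
                v = 10.0 if (i < 50) == (j < 50) else 2.0
                trip.append((i, j, v))
        p = write_text_contacts(bs, {"chr1": 1_000_000}, trip)
        rs = point_set(assembly, [50_000])
        stack = extract_2d(open_contacts(p), point_frames(rs, PointConfig(10_000, 1000)))
        assert insulation_contrast(aggregate_2d(stack)) > 1.0
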