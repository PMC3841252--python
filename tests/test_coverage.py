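"""Coverage tracks, RPM quantification, occupancy calling and rank
normalization, each against an independent oracle."""

import numpy as np
import pytest

from smcpipe import (
    GenomicInterval,
    build_track,
    call_occupied_regions,
    rank_normalize,
    region_signal,
    track_to_bedgraph_records,
)

from conftest import make_track

SIZES = {"chr1": 10_000}


class TestBuildTrack:
    def test_no_reads(self):
        t = build_track([], SIZES, bin_size=100, extend_len=200)
        assert t.total_mapped == 0
        assert t.counts["chr1"].sum() == 0

    def test_extended_read_spans_two_bins(self):
        # 36 bp + read at 80: extends to [80, 280) -> bins 0,1,2 at 100 bp
        t = build_track(
            [GenomicInterval("chr1", 80, 116, "+")], SIZES, 100, 200
        )
        assert list(t.counts["chr1"][:4]) == [1, 1, 1, 0]
        # minus-strand read at the same spot extends leftward
        t = build_track(
            [GenomicInterval("chr1", 80, 116, "-")], SIZES, 100, 200
        )
        assert list(t.counts["chr1"][:4]) == [1, 1, 0, 0]

    def test_matches_perbase_accumulation(self):
        """Bin counts equal a brute-force per-base overlap count at bin edges."""
        rng = np.random.default_rng(21)
        reads = []
        for _ in range(100):
            s = int(rng.integers(0, 9_900))
            strand = "+-."[int(rng.integers(3))]
            reads.append(GenomicInterval("chr1", s, s + 36, strand))
        t = build_track(reads, SIZES, 100, 200)

        # oracle: per-base coverage of extended reads, then count reads
        # overlapping each bin by marking read ids
        hits = np.zeros((len(reads), 100), dtype=bool)
        for i, r in enumerate(reads):
            if r.strand == "+":
                s, e = r.start, r.start + 200
            elif r.strand == "-":
                s, e = r.end - 200, r.end
            else:
                mid = (r.start + r.end) // 2
                s, e = mid - 100, mid + 100
            s, e = max(0, s), min(10_000, e)
            hits[i, s // 100 : (e - 1) // 100 + 1] = True
        assert np.array_equal(t.counts["chr1"], hits.sum(axis=0))

    def test_read_conservation_bounds(self):
        rng = np.random.default_rng(22)
        reads = [
            GenomicInterval("chr1", int(s), int(s) + 36, "+")
            for s in rng.integers(0, 9_000, size=500)
        ]
        t = build_track(reads, SIZES, 50, 200)
        total = t.counts["chr1"].sum()
        assert total >= len(reads)
        assert total <= len(reads) * (np.ceil(200 / 50) + 1)

    def test_bad_params(self):
        with pytest.raises(ValueError):
            build_track([], SIZES, 0, 200)
        with pytest.raises(ValueError):
            build_track([GenomicInterval("chrZ", 0, 36)], SIZES, 50, 200)


class TestRegionSignal:
    def test_zero_coverage_region(self):
        t = make_track({"chr1": [0] * 50 + [5] * 50}, total_mapped=1000)
        region = GenomicInterval("chr1", 0, 1000)
        assert region_signal(t, region, "total_rpm") == 0
        assert region_signal(t, region, "density_rpm_per_bp") == 0

    def test_arithmetic(self):
        # 200 reads in a 1 kb region of a 2M-read track -> 100 RPM, 0.1 RPM/bp
        t = make_track(
            {"chr1": [20] * 10 + [0] * 90}, total_mapped=2_000_000
        )
        region = GenomicInterval("chr1", 0, 1000)
        assert region_signal(t, region, "total_rpm") == pytest.approx(100.0)
        assert region_signal(t, region, "density_rpm_per_bp") == pytest.approx(0.1)

    def test_prorata_partial_bins(self):
        t = make_track({"chr1": [10, 30]}, total_mapped=1_000_000)
        # half of bin 0 + half of bin 1 = 5 + 15 = 20 reads
        assert region_signal(
            t, GenomicInterval("chr1", 50, 150), "total_rpm"
        ) == pytest.approx(20.0)

    def test_density_additive_over_halves(self):
        rng = np.random.default_rng(23)
        t = make_track({"chr1": rng.integers(0, 50, 100).tolist()})
        full = GenomicInterval("chr1", 1000, 3000)
        left = GenomicInterval("chr1", 1000, 2000)
        right = GenomicInterval("chr1", 2000, 3000)
        total = region_signal(t, left) + region_signal(t, right)
        assert total / len(full) == pytest.approx(
            region_signal(t, full, "density_rpm_per_bp")
        )

    def test_partition_sums_to_mean_multiplicity(self):
        """Summed RPM over a genome partition is 1e6 x (bin-sum / reads)."""
        rng = np.random.default_rng(24)
        vec = rng.integers(0, 20, 100).tolist()
        t = make_track({"chr1": vec}, total_mapped=5_000)
        parts = [
            GenomicInterval("chr1", s, s + 2_500) for s in range(0, 10_000, 2_500)
        ]
        total = sum(region_signal(t, p) for p in parts)
        assert total == pytest.approx(1e6 * sum(vec) / 5_000)

    def test_zero_mapped_rejected(self):
        t = make_track({"chr1": [0] * 10}, total_mapped=0)
        with pytest.raises(ValueError):
            region_signal(t, GenomicInterval("chr1", 0, 100))


class TestCallOccupied:
    def test_identical_to_control_is_null(self):
        rng = np.random.default_rng(25)
        vec = rng.poisson(10, 2000).tolist()
        t = make_track({"chr1": vec}, bin_size=50, total_mapped=10_000)
        occ = call_occupied_regions(t, t, p_cutoff=1e-5, min_width=100, merge_gap=200)
        assert occ.regions == []

    def test_planted_enrichment_called_once(self):
        rng = np.random.default_rng(26)
        background = rng.poisson(10, 2000)
        treatment = background.copy()
        # 10x enrichment over 2 kb = bins 400..440 at bin_size 50
        treatment[400:440] = rng.poisson(100, 40)
        ctrl = make_track({"chr1": background.tolist()}, 50, 1_000_000)
        trt = make_track({"chr1": treatment.tolist()}, 50, 1_000_000)
        occ = call_occupied_regions(trt, ctrl, 1e-5, 100, 200)
        planted = GenomicInterval("chr1", 20_000, 22_000)
        hits = [r for r in occ.regions if r.overlaps(planted)]
        assert len(occ.regions) == 1 and len(hits) == 1

    def test_called_bases_monotone_in_cutoff(self):
        rng = np.random.default_rng(27)
        ctrl_vec = rng.poisson(8, 3000)
        trt_vec = rng.poisson(8 * np.exp(rng.normal(0, 0.4, 3000)))
        ctrl = make_track({"chr1": ctrl_vec.tolist()}, 50, 500_000)
        trt = make_track({"chr1": trt_vec.tolist()}, 50, 500_000)
        prev = None
        for cutoff in (1e-2, 1e-3, 1e-4, 1e-5, 1e-6):
            occ = call_occupied_regions(trt, ctrl, cutoff, 50, 100)
            bases = sum(len(r) for r in occ.regions)
            if prev is not None:
                assert bases <= prev
            prev = bases

    def test_mismatched_binning_rejected(self):
        a = make_track({"chr1": [1] * 100}, bin_size=50)
        b = make_track({"chr1": [1] * 50}, bin_size=100)
        with pytest.raises(ValueError):
            call_occupied_regions(a, b)


class TestRankNormalize:
    def _random_pair(self, seed, n=500, n_zero=150):
        """Continuous-valued tracks with equal nonzero support (the regime
        where multiset equality and idempotence hold exactly)."""
        rng = np.random.default_rng(seed)
        a = rng.lognormal(2.0, 0.6, n)
        b = rng.lognormal(2.5, 0.8, n)
        a[rng.choice(n, n_zero, replace=False)] = 0
        b[rng.choice(n, n_zero, replace=False)] = 0
        return (
            make_track({"chr1": a.tolist()}),
            make_track({"chr1": b.tolist()}),
        )

    def test_identical_tracks_unchanged(self):
        t = make_track({"chr1": [0, 3, 1, 4, 1, 5, 9, 2, 6, 0]})
        na, nb = rank_normalize(t, t)
        assert np.allclose(na.counts["chr1"], t.counts["chr1"])
        assert np.allclose(nb.counts["chr1"], t.counts["chr1"])

    def test_monotone_transform_invariance(self):
        """A strictly increasing transform of one track's counts changes
        none of its normalized values (fixed reference scale), and leaves
        the rank structure untouched under the default averaged scale."""
        a, b = self._random_pair(31)
        ref = np.sort(b.counts["chr1"][b.counts["chr1"] > 0])
        a2 = a.copy_with(
            {"chr1": np.where(a.counts["chr1"] > 0,
                              a.counts["chr1"] ** 2 + 1, 0.0)}
        )
        na1, _ = rank_normalize(a, b, reference=ref)
        na2, _ = rank_normalize(a2, b, reference=ref)
        assert np.allclose(na1.counts["chr1"], na2.counts["chr1"])
        # default averaged reference: output order statistics still agree
        da1, _ = rank_normalize(a, b)
        da2, _ = rank_normalize(a2, b)
        assert np.array_equal(
            np.argsort(da1.counts["chr1"], kind="stable"),
            np.argsort(da2.counts["chr1"], kind="stable"),
        )

    def test_output_multisets_identical(self):
        a, b = self._random_pair(32)
        na, nb = rank_normalize(a, b)
        va = np.sort(na.counts["chr1"][na.counts["chr1"] > 0])
        vb = np.sort(nb.counts["chr1"][nb.counts["chr1"] > 0])
        assert len(va) == len(vb)
        assert np.allclose(va, vb)

    def test_idempotent(self):
        a, b = self._random_pair(33)
        na, nb = rank_normalize(a, b)
        na2, nb2 = rank_normalize(na, nb)
        assert np.allclose(na.counts["chr1"], na2.counts["chr1"], atol=1e-9)
        assert np.allclose(nb.counts["chr1"], nb2.counts["chr1"], atol=1e-9)

    def test_all_zero_rejected(self):
        a = make_track({"chr1": [0] * 10})
        b = make_track({"chr1": [1] * 10})
        with pytest.raises(ValueError):
            rank_normalize(a, b)

    def test_export_floor_is_display_only(self):
        a = make_track({"chr1": [0.0, 0.05, 0.3, 0.5]})
        b = make_track({"chr1": [0.1, 0.0, 0.25, 0.45]})
        na, _ = rank_normalize(a, b)
        nz = na.counts["chr1"][na.counts["chr1"] > 0]
        assert nz.min() < 0.2  # analysis values stay unfloored
        recs = track_to_bedgraph_records(na, "raw", floor=0.2)
        assert recs and all(v >= 0.2 for _, v in recs)
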