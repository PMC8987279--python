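import numpy as np
import pandas as pd
import pytest

from _oracles import allpairs_overlaps
from sweepscan.core import GenomicInterval, SweepTruth
from sweepscan.sweep_scan import (
    make_windows, window_xpehh, empirical_threshold, flag_tail,
    consensus_regions, intersect_contrasts, count_high_daf, recovery_metrics,
    SweepRegion,
)


def _region(chrom, start, end, methods=("FST",), contrast="c1"):
    return SweepRegion(
        interval=GenomicInterval(chrom, start, end),
        methods_by_contrast={contrast: frozenset(methods)},
    )


class TestMakeWindows:
    def test_enumeration(self):
        grid = make_windows({"chr1": 1_000_000}, 100_000, 10_000)
        w = grid.windows["chr1"]
        assert len(w) == 100
        assert w[0].tolist() == [0, 100_000]
        assert w[-1].tolist() == [990_000, 1_000_000]  # clipped

    def test_step_equal_size_tiles(self):
        grid = make_windows({"chr1": 250_000}, 100_000, 100_000)
        w = grid.windows["chr1"]
        assert len(w) == int(np.ceil(250_000 / 100_000))
        assert w[-1].tolist() == [200_000, 250_000]

    def test_short_chromosome(self):
        grid = make_windows({"chr1": 25_000}, 100_000, 10_000)
        w = grid.windows["chr1"]
        assert len(w) == 3
        assert (w[:, 1] == 25_000).all()
        assert (w[:, 1] > w[:, 0]).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 100}, 0, 10)
        with pytest.raises(ValueError):
            make_windows({"chr1": 100}, 10, 20)


class TestWindowXpehh:
    def test_mean_and_max(self):
        scores = pd.DataFrame(
            {"chrom": "chr1", "pos": [10, 20], "norm": [1.0, 2.0]}
        )
        grid = make_windows({"chr1": 100}, 100, 100)
        assert window_xpehh(scores, grid, min_snps=2).loc[0, "xpehh"] == 1.5
        assert (
            window_xpehh(scores, grid, min_snps=2, summary="max").loc[0, "xpehh"]
            == 2.0
        )

    def test_min_snps_gate(self):
        scores = pd.DataFrame(
            {"chrom": "chr1", "pos": [10, 20, 30], "norm": [1.0, 2.0, 3.0]}
        )
        grid = make_windows({"chr1": 100}, 100, 100)
        assert np.isnan(window_xpehh(scores, grid, min_snps=10).loc[0, "xpehh"])

    def test_matches_groupby_recomputation(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(1_000_000, size=400, replace=False)) + 1
        norm = rng.normal(size=400)
        norm[rng.random(400) < 0.1] = np.nan
        scores = pd.DataFrame({"chrom": "chr1", "pos": pos, "norm": norm})
        grid = make_windows({"chr1": 1_000_000}, 100_000, 10_000)
        out = window_xpehh(scores, grid, min_snps=1)
        for i, row in out.iterrows():
            inside = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
            vals = norm[inside]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                assert np.isnan(row["xpehh"])
            else:
                assert row["xpehh"] == pytest.approx(vals.mean())


class TestEmpiricalThreshold:
    def test_interpolated_quantile_and_flags(self):
        values = np.arange(1.0, 101.0)
        cutoff = empirical_threshold(values, tail=0.05)
        assert cutoff == pytest.approx(95.05)
        flags, _ = flag_tail(values, tail=0.05)
        assert set(values[flags]) == {96, 97, 98, 99, 100}

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="equal"):
            cutoff = empirical_threshold(np.full(30, 7.0))
        assert cutoff == 7.0
        flags, _ = flag_tail(np.full(30, 7.0))
        assert flags.all()

    def test_too_few_scored_values(self):
        with pytest.raises(ValueError, match="20"):
            empirical_threshold(np.arange(10.0))

    def test_flag_fraction_bounded(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            values = rng.normal(size=rng.integers(50, 500))
            flags, _ = flag_tail(values, tail=0.05)
            assert flags.mean() <= 0.05 + 1.0 / len(values)

    def test_unscored_excluded(self):
        values = np.concatenate([np.arange(1.0, 101.0), [np.nan] * 50])
        flags, cutoff = flag_tail(values, tail=0.05)
        assert cutoff == pytest.approx(95.05)
        assert not flags[100:].any()


class TestConsensusRegions:
    def _grid(self):
        return make_windows({"chr1": 110_000}, 100_000, 10_000)

    def test_merge_and_method_union(self):
        grid = self._grid()
        n = len(grid.windows["chr1"])
        flags = {
            "FST": np.zeros(n, bool),
            "PI_RATIO": np.zeros(n, bool),
            "XPEHH": np.zeros(n, bool),
        }
        flags["FST"][[0, 1]] = True
        flags["XPEHH"][0] = True
        flags["PI_RATIO"][1] = True
        regions = consensus_regions(flags, grid, min_methods=2)
        assert len(regions) == 1
        assert regions[0].interval.start == 0
        assert regions[0].interval.end == 110_000
        assert regions[0].methods == {"FST", "PI_RATIO", "XPEHH"}
        assert regions[0].member_windows == [(0, 100_000), (10_000, 110_000)]

    def test_single_method_window_not_selected(self):
        grid = self._grid()
        n = len(grid.windows["chr1"])
        flags = {"FST": np.zeros(n, bool), "PI_RATIO": np.zeros(n, bool)}
        flags["FST"][0] = True
        assert consensus_regions(flags, grid, min_methods=2) == []

    def test_min_methods_three_is_subset_of_two(self):
        rng = np.random.default_rng(17)
        grid = make_windows({"chr1": 2_000_000}, 100_000, 10_000)
        n = len(grid.windows["chr1"])
        flags = {m: rng.random(n) < 0.1 for m in ("FST", "PI_RATIO", "XPEHH")}
        cover2 = _coverage(consensus_regions(flags, grid, min_methods=2))
        cover3 = _coverage(consensus_regions(flags, grid, min_methods=3))
        assert cover3 <= cover2

        # every bp covered at min_methods=3 is covered at min_methods=2
        r2 = consensus_regions(flags, grid, min_methods=2)
        for r in consensus_regions(flags, grid, min_methods=3):
            assert any(
                q.interval.start <= r.interval.start
                and q.interval.end >= r.interval.end
                for q in r2
            )

    def test_merged_regions_never_overlap(self):
        rng = np.random.default_rng(19)
        grid = make_windows({"chr1": 3_000_000}, 100_000, 10_000)
        n = len(grid.windows["chr1"])
        flags = {m: rng.random(n) < 0.15 for m in ("FST", "XPEHH")}
        regions = consensus_regions(flags, grid, min_methods=2)
        for a, b in zip(regions, regions[1:]):
            assert a.interval.end < b.interval.start  # merged, gap > 0
        for r in regions:
            assert r.interval.start == min(s for s, _ in r.member_windows)
            assert r.interval.end == max(e for _, e in r.member_windows)


def _coverage(regions):
    return sum(r.interval.length for r in regions)


class TestIntersectContrasts:
    def test_basic_intersection(self):
        a = [_region("chr1", 0, 100_000, contrast="c1")]
        b = [_region("chr1", 50_000, 150_000, methods=("XPEHH",), contrast="c2")]
        (out,) = intersect_contrasts(a, b)
        assert (out.interval.start, out.interval.end) == (50_000, 100_000)
        assert out.contrasts == {"c1", "c2"}
        assert out.methods_by_contrast["c1"] == {"FST"}
        assert out.methods_by_contrast["c2"] == {"XPEHH"}

    def test_disjoint_lists_empty(self):
        a = [_region("chr1", 0, 10_000)]
        b = [_region("chr1", 20_000, 30_000, contrast="c2")]
        assert intersect_contrasts(a, b) == []
        assert intersect_contrasts(a, []) == []

    def test_matches_quadratic_oracle_and_commutes(self):
        rng = np.random.default_rng(23)

        def random_regions(contrast):
            out = []
            cursor = 0
            for _ in range(30):
                cursor += int(rng.integers(1, 50_000))
                end = cursor + int(rng.integers(1, 80_000))
                out.append(_region("chr1", cursor, end, contrast=contrast))
                cursor = end
            return out

        a, b = random_regions("c1"), random_regions("c2")
        out = intersect_contrasts(a, b)
        oracle = allpairs_overlaps(
            [r.interval for r in a], [r.interval for r in b]
        )
        n_pairs = sum(len(v) for v in oracle.values())
        assert len(out) == n_pairs
        # commutative in coverage
        rev = intersect_contrasts(b, a)
        assert _coverage(out) == _coverage(rev)


class TestHighDaf:
    def _daf(self, positions, values):
        return pd.DataFrame({"chrom": "chr1", "pos": positions, "daf": values})

    def test_strict_cutoff_count(self):
        regions = [_region("chr1", 0, 1000)]
        daf = self._daf([10, 20, 30], [0.9, 0.81, 0.5])
        regions, summary = count_high_daf(regions, daf, cutoff=0.8)
        assert regions[0].n_high_daf == 2
        assert summary["n_genome_high_daf"] == 2

    def test_cutoff_one_counts_nothing(self):
        regions = [_region("chr1", 0, 1000)]
        daf = self._daf([10, 20], [1.0, 1.0])
        regions, _ = count_high_daf(regions, daf, cutoff=1.0)
        assert regions[0].n_high_daf == 0

    def test_enrichment_ratio_favors_regions(self):
        positions = np.arange(1, 1001)
        values = np.full(1000, 0.1)
        values[:100] = 0.9  # all high-dAF sites inside the region
        regions = [_region("chr1", 0, 100)]
        _, summary = count_high_daf(regions, self._daf(positions, values))
        assert summary["enrichment_ratio"] == pytest.approx(10.0)


class TestRecovery:
    def _truth(self, chrom, start, end):
        return SweepTruth(
            pop="target",
            interval=GenomicInterval(chrom, start, end, "target"),
            sweep_freq=0.95,
        )

    def test_exact_recovery(self):
        truth = [self._truth("chr1", 0, 100), self._truth("chr1", 500, 600)]
        regions = [_region("chr1", 0, 100), _region("chr1", 500, 600)]
        m = recovery_metrics(regions, truth, {"chr1": 1000})
        assert m["sensitivity"] == 1.0
        assert m["genome_fraction"] == pytest.approx(0.2)

    def test_empty_regions(self):
        truth = [self._truth("chr1", 0, 100)]
        m = recovery_metrics([], truth, {"chr1": 1000})
        assert m["sensitivity"] == 0.0

    def test_single_bp_overlap_counts(self):
        truth = [self._truth("chr1", 100, 200)]
        shifted = [_region("chr1", 150, 250)]
        m = recovery_metrics(shifted, truth, {"chr1": 1000})
        assert m["sensitivity"] == 1.0
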