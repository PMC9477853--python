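"""Interval algebra, TSS proximity, peak counts, and conservation averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maturekit.errors import InvalidArgumentError
from maturekit.intervals import (
    classify_tss_proximity,
    compare_peak_counts,
    exclude_regions,
    gain_loss,
    overlaps_any,
    peaks_near_genes,
    region_conservation,
    top_peaks,
)
from maturekit.synthetic import generate_peak_universe, generate_score_track


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, width_hi=500):
    starts = rng.integers(0, max_pos, size=n)
    widths = rng.integers(1, width_hi, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + widths,
            "name": [f"p{i}" for i in range(n)],
            "score": rng.uniform(0, 1000, size=n),
        }
    )


def brute_force_overlaps(peaks, other):
    out = []
    for a in peaks.itertuples(index=False):
        hit = any(
            a.chrom == b.chrom and a.start < b.end and b.start < a.end
            for b in other.itertuples(index=False)
        )
        out.append(hit)
    return np.array(out)


class TestTopPeaks:
    def test_whole_set_when_n_large(self, rng):
        peaks = random_peaks(rng, 10)
        with pytest.warns(UserWarning):
            out = top_peaks(peaks, 50)
        assert len(out) == 10

    def test_distinct_scores_take_largest(self, rng):
        peaks = random_peaks(rng, 30)
        peaks["score"] = np.arange(30, dtype=float)
        out = top_peaks(peaks, 5)
        assert set(out["score"]) == {25.0, 26.0, 27.0, 28.0, 29.0}

    def test_ties_broken_by_position_matches_full_sort(self, rng):
        for _ in range(100):
            peaks = random_peaks(rng, 20)
            peaks["score"] = rng.integers(0, 4, size=20).astype(float)  # many ties
            n = int(rng.integers(1, 20))
            got = top_peaks(peaks, n)
            expected = peaks.sort_values(
                ["score", "chrom", "start"], ascending=[False, True, True],
                kind="stable",
            ).head(n)
            assert sorted(got["name"]) == sorted(expected["name"])


class TestExcludeRegions:
    def test_empty_blacklist_identity(self, rng):
        peaks = random_peaks(rng, 15)
        out = exclude_regions(peaks, [])
        assert len(out) == 15

    def test_self_blacklist_empties(self, rng):
        peaks = random_peaks(rng, 15)
        assert exclude_regions(peaks, [peaks]).empty

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            peaks = random_peaks(rng, 25, max_pos=5000)
            black = random_peaks(rng, 10, max_pos=5000)
            got = exclude_regions(peaks, [black])
            expected = peaks[~brute_force_overlaps(peaks, black)]
            assert sorted(got["name"]) == sorted(expected["name"])

    def test_idempotent(self, rng):
        peaks = random_peaks(rng, 40, max_pos=20_000)
        black = random_peaks(rng, 10, max_pos=20_000)
        once = exclude_regions(peaks, [black])
        twice = exclude_regions(once, [black])
        pd.testing.assert_frame_equal(once, twice)


class TestGainLoss:
    def test_identical_sets_nothing_changes(self, rng):
        peaks = random_peaks(rng, 20)
        res = gain_loss(peaks, peaks, n=20)
        assert res.gained.empty and res.lost.empty
        assert res.pct_gained == 0.0 and res.pct_lost == 0.0

    def test_disjoint_sets_full_turnover(self):
        earlier = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 1000], "end": [100, 1100],
             "name": ["a", "b"], "score": [1.0, 2.0]}
        )
        later = pd.DataFrame(
            {"chrom": "chr1", "start": [5000, 7000], "end": [5100, 7100],
             "name": ["c", "d"], "score": [1.0, 2.0]}
        )
        res = gain_loss(earlier, later, n=2)
        assert res.pct_gained == 100.0 and res.pct_lost == 100.0

    def test_symmetry_under_swap(self, rng):
        earlier = random_peaks(rng, 30, max_pos=20_000)
        later = random_peaks(rng, 30, max_pos=20_000)
        fwd = gain_loss(earlier, later, n=30)
        rev = gain_loss(later, earlier, n=30)
        pd.testing.assert_frame_equal(fwd.gained, rev.lost)
        pd.testing.assert_frame_equal(fwd.lost, rev.gained)

    def test_recovers_generator_truth_exactly(self):
        tss = pd.DataFrame(
            {"gene_id": ["g0"], "chrom": ["chr1"], "tss": [500_000], "strand": ["+"]}
        )
        sets, truth = generate_peak_universe(
            {"chr1": 3_000_000}, ["t0", "t1"], 500, 0.2, 0.2, 0.0, tss, seed=6
        )
        res = gain_loss(sets["t0"], sets["t1"], n=500)
        assert sorted(res.gained["name"]) == sorted(truth.gained["t0->t1"])
        assert sorted(res.lost["name"]) == sorted(truth.lost["t0->t1"])
        assert res.pct_gained == pytest.approx(100 * 100 / 500)


class TestTssProximity:
    TSS = pd.DataFrame(
        {"gene_id": ["gA", "gB"], "chrom": ["chr1", "chr1"],
         "tss": [10_000, 50_000], "strand": ["+", "-"]}
    )

    def _peak(self, start, end, chrom="chr1"):
        return pd.DataFrame(
            {"chrom": [chrom], "start": [start], "end": [end],
             "name": ["p"], "score": [1.0]}
        )

    def test_midpoint_at_tss_is_proximal(self):
        out = classify_tss_proximity(self._peak(9_900, 10_100), self.TSS)
        assert bool(out["proximal"].iloc[0])
        assert out["tss_distance"].iloc[0] == 0

    def test_2kb_boundary_inclusive(self):
        # midpoint exactly 2000 bp away -> proximal
        out = classify_tss_proximity(self._peak(11_900, 12_100), self.TSS)
        assert bool(out["proximal"].iloc[0])
        # 2001 bp away -> distal
        out = classify_tss_proximity(self._peak(11_901, 12_101), self.TSS)
        assert not bool(out["proximal"].iloc[0])

    def test_chrom_without_tss_is_distal_with_warning(self):
        with pytest.warns(UserWarning):
            out = classify_tss_proximity(self._peak(0, 100, chrom="chrX"), self.TSS)
        assert not bool(out["proximal"].iloc[0])

    def test_matches_brute_force_nearest_scan(self, rng):
        tss = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20)],
                "chrom": rng.choice(["chr1", "chr2"], size=20),
                "tss": rng.integers(0, 100_000, size=20),
                "strand": "+",
            }
        )
        for _ in range(100):
            peaks = random_peaks(rng, 10)
            out = classify_tss_proximity(peaks, tss).set_index("name")
            for p in peaks.itertuples(index=False):
                mid = (p.start + p.end) // 2
                dists = [
                    abs(t.tss - mid)
                    for t in tss.itertuples(index=False)
                    if t.chrom == p.chrom
                ]
                expected = min(dists) if dists else np.inf
                assert out.loc[p.name, "tss_distance"] == expected


class TestPeaksNearGenes:
    TSS = pd.DataFrame(
        {"gene_id": ["gA", "gB"], "chrom": ["chr1", "chr2"],
         "tss": [10_000, 10_000], "strand": ["+", "+"]}
    )

    def test_no_peaks_all_zero(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "name", "score"])
        counts = peaks_near_genes(empty, ["gA", "gB"], self.TSS, 5000)
        assert (counts == 0).all()

    def test_single_peak_counted_once(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [9000], "end": [9200],
             "name": ["p"], "score": [1.0]}
        )
        counts = peaks_near_genes(peaks, ["gA", "gB"], self.TSS, 5000)
        assert counts["gA"] == 1 and counts["gB"] == 0

    def test_missing_gene_listed_in_error(self):
        peaks = random_peaks(np.random.default_rng(0), 5)
        with pytest.raises(InvalidArgumentError, match="gZ"):
            peaks_near_genes(peaks, ["gZ"], self.TSS, 5000)

    def test_matches_brute_force_count(self, rng):
        tss = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(15)],
                "chrom": rng.choice(["chr1", "chr2"], size=15),
                "tss": rng.integers(0, 80_000, size=15),
                "strand": "+",
            }
        )
        genes = list(tss["gene_id"])
        for _ in range(100):
            peaks = random_peaks(rng, 30)
            window = int(rng.integers(1000, 30_000))
            got = peaks_near_genes(peaks, genes, tss, window)
            for t in tss.itertuples(index=False):
                expected = sum(
                    p.chrom == t.chrom
                    and abs((p.start + p.end) // 2 - t.tss) <= window
                    for p in peaks.itertuples(index=False)
                )
                assert got[t.gene_id] == expected


class TestComparePeakCounts:
    def test_identical_vectors_p_one(self):
        res = compare_peak_counts([3, 1, 4, 1, 5], [3, 1, 4, 1, 5])
        assert res.p_value == pytest.approx(1.0)
        assert res.mean_difference == 0.0

    def test_clear_separation_small_p(self, rng):
        gained = rng.normal(10, 0.1, size=500)
        lost = rng.normal(2, 0.1, size=500)
        res = compare_peak_counts(gained, lost)
        assert res.p_value < 1e-100

    def test_matches_welch_closed_form(self, rng):
        for _ in range(100):
            a = rng.normal(5, 2, size=12)
            b = rng.normal(4, 3, size=12)
            res = compare_peak_counts(a, b)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
            p_hand = 2 * stats.t.sf(abs(t_hand), df)
            assert res.t_statistic == pytest.approx(t_hand, rel=1e-10)
            assert res.p_value == pytest.approx(p_hand, rel=1e-10)


class TestRegionConservation:
    SIZES = {"chr1": 200_000}

    def test_constant_track_equal_means(self, rng):
        track = generate_score_track(self.SIZES, seed=1, constant=0.5)
        regions = random_peaks(rng, 10, chroms=("chr1",), max_pos=150_000)
        res = region_conservation(regions, track, self.SIZES, background_n=50, seed=2)
        assert res.foreground_mean == pytest.approx(0.5)
        assert res.background_mean == pytest.approx(0.5)

    def test_region_means_match_per_base_expansion(self):
        track = generate_score_track({"chr1": 5000}, seed=4, mean_segment_length=80)
        per_base = np.zeros(5000)
        for row in track.segments("chr1").itertuples(index=False):
            per_base[row.start : row.end] = row.value
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 700, 1500, 3000, 4400],
             "end": [300, 1300, 2000, 4000, 5000],
             "name": list("abcde"), "score": 1.0}
        )
        res = region_conservation(regions, track, {"chr1": 5000}, background_n=10, seed=1)
        for row in regions.itertuples(index=False):
            assert res.region_means[row.name] == pytest.approx(
                per_base[row.start : row.end].mean()
            )

    def test_empty_regions_rejected(self):
        track = generate_score_track(self.SIZES, seed=1, constant=1.0)
        empty = pd.DataFrame(columns=["chrom", "start", "end", "name", "score"])
        with pytest.raises(InvalidArgumentError):
            region_conservation(empty, track, self.SIZES)


class TestOrderInvariance:
    def test_operations_invariant_to_input_order(self, rng):
        peaks = random_peaks(rng, 40, max_pos=30_000)
        shuffled = peaks.sample(frac=1, random_state=1).reset_index(drop=True)
        black = random_peaks(rng, 10, max_pos=30_000)
        pd.testing.assert_frame_equal(
            exclude_regions(peaks, [black]), exclude_regions(shuffled, [black])
        )
        pd.testing.assert_frame_equal(top_peaks(peaks, 7), top_peaks(shuffled, 7))
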