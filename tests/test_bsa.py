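"""Site filter, ED statistic, window scan, threshold and interval calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodpeach.bsa import (
    EDScan,
    ScanConfig,
    call_candidate_intervals,
    compute_threshold,
    euclidean_distance,
    filter_snps,
    pool_frequencies,
    site_ed,
    transform_ed,
    window_scan,
)


def _site(**kw):
    base = dict(chrom="chr1", pos=100, ref="A",
                A_mut=15, C_mut=0, G_mut=15, T_mut=0,
                A_wt=30, C_wt=0, G_wt=0, T_wt=0,
                qd=10.0, fs=5.0, mq=50.0, mq_rank_sum=0.0,
                read_pos_rank_sum=0.0, dp=60)
    base.update(kw)
    return base


class TestFilter:
    @pytest.mark.parametrize(
        "override, reason",
        [
            ({"qd": 1.5}, "QD"),
            ({"fs": 61.0}, "FS"),
            ({"mq": 39.0}, "MQ"),
            ({"mq_rank_sum": -13.0}, "MQRankSum"),
            ({"read_pos_rank_sum": -9.0}, "ReadPosRankSum"),
            ({"dp": 3}, "DP"),
        ],
    )
    def test_each_clause_rejects_with_its_name(self, override, reason):
        df = pd.DataFrame([_site(**override)])
        kept, rejected = filter_snps(df)
        assert len(kept) == 0
        assert reason in rejected["reason"].iloc[0]

    def test_clean_site_kept(self):
        kept, rejected = filter_snps(pd.DataFrame([_site()]))
        assert len(kept) == 1 and len(rejected) == 0

    def test_missing_annotations_pass_by_default(self):
        df = pd.DataFrame([_site(qd=np.nan, mq_rank_sum=np.nan)])
        kept, _ = filter_snps(df)
        assert len(kept) == 1

    def test_strict_mode_fails_missing(self):
        df = pd.DataFrame([_site(qd=np.nan)])
        kept, rejected = filter_snps(df, strict_missing=True)
        assert len(kept) == 0 and "QD" in rejected["reason"].iloc[0]

    def test_remove_reading_drops_high_depth(self):
        kept, rejected = filter_snps(pd.DataFrame([_site(dp=60)]), dp_is_remove=True)
        assert len(kept) == 0 and "DP" in rejected["reason"].iloc[0]

    def test_filter_partitions_input(self, rng):
        df = pd.DataFrame(
            [_site(pos=i, qd=q, dp=d)
             for i, (q, d) in enumerate(zip(rng.uniform(0, 5, 100),
                                            rng.integers(0, 10, 100)))]
        )
        kept, rejected = filter_snps(df)
        assert len(kept) + len(rejected) == len(df)
        assert set(kept["pos"]).isdisjoint(rejected["pos"])


class TestPoolFrequencies:
    def test_single_base(self):
        f_mut, _ = pool_frequencies(_site(A_mut=30, G_mut=0))
        assert f_mut.tolist() == [1, 0, 0, 0]

    def test_even_split(self):
        f_mut, _ = pool_frequencies(_site(A_mut=15, G_mut=15))
        assert f_mut.tolist() == [0.5, 0, 0.5, 0]

    def test_mixed_counts_to_4dp(self):
        f_mut, _ = pool_frequencies(_site(A_mut=20, C_mut=5, G_mut=5, T_mut=0))
        assert np.round(f_mut, 4).tolist() == [0.6667, 0.1667, 0.1667, 0.0]

    def test_zero_depth_pool_is_undefined(self):
        f_mut, f_wt = pool_frequencies(_site(A_wt=0))
        assert not np.isnan(f_mut).any()
        assert np.isnan(f_wt).all()


class TestEuclideanDistance:
    def test_identical_pools_zero(self):
        f = np.array([0.25, 0.25, 0.25, 0.25])
        assert euclidean_distance(f, f) == 0.0

    def test_opposite_fixed_bases_sqrt2(self):
        a = np.array([1.0, 0, 0, 0])
        g = np.array([0.0, 0, 1.0, 0])
        assert euclidean_distance(a, g) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_hand_arithmetic_example(self):
        m = np.array([0.75, 0, 0.25, 0])
        w = np.array([0.25, 0, 0.75, 0])
        assert euclidean_distance(m, w) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_malformed_vector_errors(self):
        with pytest.raises(ValueError):
            euclidean_distance(np.array([0.5, 0.5, 0.5, 0]), np.array([1, 0, 0, 0]))

    @given(st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
           st.lists(st.floats(0.01, 1), min_size=4, max_size=4))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_bounds_and_symmetry(self, a, b):
        fa = np.array(a) / np.sum(a)
        fb = np.array(b) / np.sum(b)
        ed = euclidean_distance(fa, fb)
        assert 0 <= ed <= np.sqrt(2) + 1e-12
        assert ed == pytest.approx(euclidean_distance(fb, fa), abs=1e-12)
        if np.allclose(fa, fb):
            assert ed == pytest.approx(0, abs=1e-12)


class TestTransform:
    @pytest.mark.parametrize("ed, k, expected",
                             [(1.0, 5, 1.0), (np.sqrt(2), 5, 2 ** 2.5), (0.0, 5, 0.0)])
    def test_closed_forms(self, ed, k, expected):
        assert transform_ed([ed], k)[0] == pytest.approx(expected, rel=1e-12)

    def test_preserves_argmax(self, rng):
        vals = rng.uniform(0, 1.4, 500)
        assert np.argmax(vals) == np.argmax(transform_ed(vals, 5))

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            transform_ed([0.5], 0.5)


def _scored(positions, values, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions, "ed_power": values})


class TestWindowScan:
    def test_window_count_250kb(self):
        w = window_scan(_scored([1], [0.0]), {"chr1": 250_000}, ScanConfig())
        assert len(w) == 25
        assert w["start"].iloc[0] == 1 and w["start"].iloc[-1] == 240_001
        assert (w["end"].iloc[-2:] == 250_000).all()  # truncated tail windows

    def test_window_count_100kb(self):
        w = window_scan(_scored([1], [0.0]), {"chr1": 100_000}, ScanConfig())
        assert len(w) == 10
        assert w["end"].iloc[0] == 100_000
        assert (w["end"] == 100_000).all()

    def test_single_site_covers_expected_windows(self):
        v = 0.123
        w = window_scan(_scored([50_000], [v]), {"chr1": 200_000}, ScanConfig())
        covering = w[(w["start"] <= 50_000) & (w["end"] >= 50_000)]
        assert (covering["stat"] == v).all()
        assert w.loc[~w.index.isin(covering.index), "stat"].isna().all()

    def test_unsorted_input_errors(self):
        with pytest.raises(ValueError, match="sorted"):
            window_scan(_scored([500, 100], [0.1, 0.2]), {"chr1": 1_000}, ScanConfig())

    def test_matches_brute_force_oracle(self, rng):
        n = 1000
        pos = np.sort(rng.choice(np.arange(1, 400_000), n, replace=False))
        vals = rng.uniform(0, 2, n)
        cfg = ScanConfig(window=50_000, step=7_000, min_snps_per_window=1)
        w = window_scan(_scored(pos, vals), {"chr1": 400_000}, cfg)
        for _, row in w.iterrows():
            inside = vals[(pos >= row["start"]) & (pos <= row["end"])]
            if len(inside) == 0:
                assert np.isnan(row["stat"])
            else:
                assert row["stat"] == pytest.approx(inside.mean(), rel=1e-12)
                assert row["n_snps"] == len(inside)


class TestThreshold:
    def test_constant_stats_nothing_above(self):
        w = pd.DataFrame({"chrom": "chr1", "start": [1, 11], "end": [10, 20],
                          "n_snps": 1, "stat": [2.5, 2.5]})
        thr, n = compute_threshold(w, ScanConfig())
        assert thr == 2.5 and n == 2
        assert len(call_candidate_intervals(w, thr, 10)) == 0

    def test_linear_interpolation_quantile(self):
        w = pd.DataFrame({"chrom": "chr1", "start": np.arange(100),
                          "end": np.arange(100), "n_snps": 1,
                          "stat": np.arange(1.0, 101.0)})
        thr, _ = compute_threshold(w, ScanConfig())
        assert thr == pytest.approx(95.05, abs=1e-9)

    def test_spike_exceeds_threshold(self, rng):
        stats = rng.uniform(0, 1, 100)
        stats[37] = 50.0
        w = pd.DataFrame({"chrom": "chr1", "start": np.arange(100),
                          "end": np.arange(100), "n_snps": 1, "stat": stats})
        thr, _ = compute_threshold(w, ScanConfig())
        assert stats[37] > thr

    def test_no_defined_windows_errors(self):
        w = pd.DataFrame({"chrom": [], "start": [], "end": [], "n_snps": [],
                          "stat": []})
        with pytest.raises(ValueError):
            compute_threshold(w, ScanConfig())


class TestCandidateIntervals:
    def _windows(self, stats, step=10_000, chrom="chr1"):
        starts = 1 + step * np.arange(len(stats))
        return pd.DataFrame({"chrom": chrom, "start": starts,
                             "end": starts + 99_999, "n_snps": 1,
                             "stat": stats})

    def test_adjacent_windows_merge_to_union(self):
        w = self._windows([1.0, 1.0, 0.0, 0.0])
        iv = call_candidate_intervals(w, 0.5, 10_000)
        assert len(iv) == 1
        assert iv["start"].iloc[0] == 1 and iv["end"].iloc[0] == 110_000

    def test_gap_splits_runs(self):
        iv = call_candidate_intervals(self._windows([1, 0, 1]), 0.5, 10_000)
        assert len(iv) == 2

    def test_peak_tie_takes_smaller_start(self):
        iv = call_candidate_intervals(self._windows([1, 1]), 0.5, 10_000)
        assert iv["peak_start"].iloc[0] == 1

    def test_chromosome_change_splits_runs(self):
        a = self._windows([1.0], chrom="chr1")
        b = self._windows([1.0], chrom="chr2")
        iv = call_candidate_intervals(pd.concat([a, b]), 0.5, 10_000)
        assert len(iv) == 2


def test_pipeline_recovers_causal_under_strong_map_contrast():
    """End-to-end wiring: with a dense genetic map (10 cM/Mb) the linked
    region decays fast enough for the top interval to land on the locus."""
    from bloodpeach.sim import SimConfig, simulate_bsa_experiment

    sim = simulate_bsa_experiment(SimConfig(seed=1, recomb_rate=10.0))
    res = EDScan(sim.sites, sim.chrom_lengths).fit()
    top = res.top_interval
    assert top is not None
    assert top["start"] <= sim.causal_pos <= top["end"]
    assert "candidate intervals" in res.summary()


def test_site_ed_drops_zero_depth_pools():
    df = pd.DataFrame([_site(), _site(pos=200, A_wt=0)])
    scored = site_ed(df)
    assert scored["pos"].tolist() == [100]
    assert scored["ed"].iloc[0] == pytest.approx(np.sqrt(0.5), abs=1e-12)
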