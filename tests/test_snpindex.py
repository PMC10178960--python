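"""SNP-index arithmetic, parental screening, and the sliding-window scan."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap.snpindex import (
    ScanConfig,
    compute_records,
    delta_snp_index,
    extract_candidate_interval,
    format_interval_mb,
    screen_parental_snps,
    sliding_window_scan,
    snp_index,
)
from bsamap.variant_io import WINDOW_COLUMNS

from conftest import make_site


class TestSnpIndex:
    @pytest.mark.parametrize(
        "maternal,paternal,expected",
        [(12, 0, 1.0), (0, 15, 0.0), (37, 63, 0.37)],
    )
    def test_read_fractions(self, maternal, paternal, expected):
        assert snp_index(maternal, paternal) == pytest.approx(expected)

    def test_zero_depth_is_missing_not_zero(self):
        assert math.isnan(snp_index(0, 0))

    @given(a=st.integers(0, 10_000), b=st.integers(0, 10_000))
    @settings(derandomize=True)
    def test_complement_sums_to_one(self, a, b):
        if a + b == 0:
            return
        assert snp_index(a, b) + snp_index(b, a) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "o,n,expected", [(1.00, 0.37, 0.63), (0.5, 0.5, 0.0), (0.2, 0.5, -0.3)]
    )
    def test_delta(self, o, n, expected):
        assert delta_snp_index(o, n) == pytest.approx(expected)

    def test_delta_missing_propagates(self):
        assert math.isnan(delta_snp_index(math.nan, 0.3))
        assert math.isnan(delta_snp_index(0.3, math.nan))


class TestParentalScreen:
    CFG = ScanConfig()

    def test_parent_distinguishing_site_kept(self):
        site = make_site(MO=(1, 9), PN=(12, 0), O=(2, 10), N=(5, 5))
        assert screen_parental_snps([site], self.CFG) == [site]

    def test_impure_maternal_bulk_dropped(self):
        site = make_site(MO=(4, 6), PN=(12, 0), O=(2, 10), N=(5, 5))
        assert screen_parental_snps([site], self.CFG) == []

    def test_maternal_allele_in_paternal_bulk_dropped(self):
        site = make_site(MO=(0, 10), PN=(8, 4), O=(2, 10), N=(5, 5))
        assert screen_parental_snps([site], self.CFG) == []

    def test_low_depth_dropped(self):
        site = make_site(MO=(0, 10), PN=(12, 0), O=(1, 2), N=(5, 5))
        assert screen_parental_snps([site], self.CFG) == []

    def test_incomplete_site_excluded_from_intersection(self):
        site = make_site(MO=(0, 10), PN=(12, 0), O=(2, 10))
        assert screen_parental_snps([site], self.CFG) == []


def brute_force_windows(records, chrom_lengths, config):
    """Independent oracle: re-scan every SNP for every window."""
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 1
        while start <= length:
            end = min(start + config.window_size - 1, length)
            members = records[
                (records["chrom"] == chrom)
                & (records["pos"] >= start)
                & (records["pos"] <= end)
            ]
            row = {"chrom": chrom, "start": start, "end": end, "n_snps": len(members)}
            for col, out in (("index_O", "mean_index_O"), ("index_N", "mean_index_N"),
                             ("delta", "mean_delta")):
                vals = members[col].dropna()
                low = len(members) < config.min_snps_per_window
                row[out] = float(vals.mean()) if len(vals) and not low else np.nan
            rows.append(row)
            start += config.step
    return pd.DataFrame(rows)[WINDOW_COLUMNS]


class TestSlidingWindow:
    def test_two_snps_alone_in_window(self):
        records = pd.DataFrame(
            {
                "chrom": ["c", "c"], "pos": [100, 200],
                "index_O": [0.9, 0.9], "index_N": [0.7, 0.5],
                "delta": [0.2, 0.4],
            }
        )
        cfg = ScanConfig(window_size=1_000, step=1_000)
        win = sliding_window_scan(records, {"c": 1_000}, cfg)
        assert len(win) == 1
        assert win.loc[0, "mean_delta"] == pytest.approx(0.3)
        assert win.loc[0, "n_snps"] == 2

    def test_empty_window_is_missing_not_zero(self):
        records = pd.DataFrame(
            {"chrom": ["c"], "pos": [100], "index_O": [1.0], "index_N": [0.3],
             "delta": [0.7]}
        )
        cfg = ScanConfig(window_size=1_000, step=1_000)
        win = sliding_window_scan(records, {"c": 3_000}, cfg)
        assert win.loc[0, "mean_delta"] == pytest.approx(0.7)  # single SNP = identity
        assert win["mean_delta"].iloc[1:].isna().all()

    def test_unsorted_input_rejected(self):
        records = pd.DataFrame(
            {"chrom": ["c", "c"], "pos": [200, 100], "index_O": [1.0, 1.0],
             "index_N": [0.3, 0.3], "delta": [0.7, 0.7]}
        )
        with pytest.raises(ValueError, match="sorted"):
            sliding_window_scan(records, {"c": 1_000}, ScanConfig(window_size=1000, step=1000))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        records = pd.DataFrame(
            {
                "chrom": rng.choice(["c1", "c2"], size=n),
                "pos": rng.integers(1, 2_000_000, size=n),
                "index_O": rng.uniform(0, 1, size=n),
                "index_N": rng.uniform(0, 1, size=n),
            }
        )
        records["delta"] = records["index_O"] - records["index_N"]
        records.loc[rng.integers(0, n, size=10), ["index_N", "delta"]] = np.nan
        records = records.sort_values(["chrom", "pos"]).reset_index(drop=True)
        lengths = {"c1": 2_000_000, "c2": 1_500_000}
        cfg = ScanConfig(window_size=250_000, step=50_000, min_snps_per_window=2)
        fast = sliding_window_scan(records, lengths, cfg)
        slow = brute_force_windows(records, lengths, cfg)
        pd.testing.assert_frame_equal(
            fast.reset_index(drop=True), slow.reset_index(drop=True),
            check_dtype=False,
        )

    def test_invariant_to_input_order_after_sorting(self, small_records):
        lengths = {"chr1": 25_000_000, "chr2": 25_000_000}
        cfg = ScanConfig()
        a = sliding_window_scan(small_records, lengths, cfg)
        shuffled = (
            small_records.sample(frac=1, random_state=0)
            .sort_values(["chrom", "pos"])
            .reset_index(drop=True)
        )
        b = sliding_window_scan(shuffled, lengths, cfg)
        pd.testing.assert_frame_equal(a, b)


def _grid_windows(chrom, length, deltas_by_start, window=1_000_000, step=10_000):
    starts = np.arange(1, length + 1, step)
    ends = np.minimum(starts + window - 1, length)
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "n_snps": 5,
         "mean_index_O": 0.5, "mean_index_N": 0.5}
    )
    df["mean_delta"] = [deltas_by_start(s) for s in starts]
    return df


def _flat_band(windows, upper99=0.2, upper95=0.15):
    return pd.DataFrame(
        {"chrom": windows["chrom"], "start": windows["start"],
         "lower99": -upper99, "lower95": -upper95,
         "upper95": upper95, "upper99": upper99, "n_sims": 10_000}
    )


class TestCandidateInterval:
    def test_supra_run_reported_as_union_span(self):
        # supra windows starting 5.26-6.41 Mb with 1 Mb windows span 5.26-7.41 Mb
        win = _grid_windows(
            "chr3", 12_000_000,
            lambda s: 0.63 if 5_260_001 <= s <= 6_410_001 else 0.05,
        )
        band = _flat_band(win)
        intervals = extract_candidate_interval(win, band, level=99)
        assert len(intervals) == 1
        chrom, start, end = intervals[0]
        assert (end - start + 1) == 2_150_000
        assert format_interval_mb(intervals[0]) == "chr3:5.26-7.41 Mb"

    def test_all_below_threshold_gives_empty_list(self):
        win = _grid_windows("c", 3_000_000, lambda s: 0.01)
        assert extract_candidate_interval(win, _flat_band(win), level=99) == []

    def test_disjoint_runs_split_into_two_intervals(self):
        win = _grid_windows(
            "c", 10_000_000,
            lambda s: 0.5 if s in (1, 5_000_001) else 0.0,
        )
        intervals = extract_candidate_interval(win, _flat_band(win), level=99)
        assert len(intervals) == 2

    def test_level_95_is_at_least_as_wide(self):
        win = _grid_windows(
            "c", 10_000_000,
            lambda s: 0.18 if 3_000_001 <= s <= 4_000_001 else 0.0,
        )
        band = _flat_band(win, upper99=0.2, upper95=0.15)
        assert extract_candidate_interval(win, band, level=99) == []
        assert len(extract_candidate_interval(win, band, level=95)) == 1

    def test_grid_mismatch_rejected(self):
        win = _grid_windows("c", 2_000_000, lambda s: 0.0)
        band = _flat_band(win)
        band["start"] = band["start"] + 7
        with pytest.raises(ValueError, match="align"):
            extract_candidate_interval(win, band, level=99)


class TestComputeRecords:
    def test_indices_and_delta_from_counts(self):
        site = make_site(MO=(0, 50), PN=(50, 0), O=(0, 40), N=(26, 14))
        rec = compute_records([site])
        row = rec.iloc[0]
        assert row["index_MO"] == 1.0 and row["index_PN"] == 0.0
        assert row["index_O"] == 1.0
        assert row["index_N"] == pytest.approx(0.35)
        assert row["delta"] == pytest.approx(0.65)
        assert row["depth_N"] == 40
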