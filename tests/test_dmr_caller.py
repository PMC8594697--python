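"""Window enumeration, levels, the two-group test, calling and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methylgraft import dmr_caller, synthetic_data
from methylgraft.dmr_caller import (DmrCallParams, DmrSummary, MethylomeSet,
                                    round_half_away)

from conftest import methylome_from_levels


class TestGlobalLevels:
    def make_set(self, meth, total, condition="OG", n_rep=2):
        samples = {}
        for r in range(n_rep):
            samples[f"s{r}"] = pd.DataFrame({
                "chrom": "chr1", "pos": np.arange(1, len(meth) + 1),
                "strand": "+", "context": "CHH",
                "n_meth": np.asarray(meth, np.int64),
                "n_total": np.asarray(total, np.int64)})
        return MethylomeSet(condition, samples)

    def test_all_unmethylated_is_zero_percent(self):
        ms = self.make_set([0] * 5, [10] * 5)
        levels, _ = dmr_caller.global_methylation_levels([ms])
        assert levels.query("context == 'CHH'")["level"].eq(0.0).all()

    def test_single_site_half_methylated(self):
        ms = self.make_set([5], [10])
        levels, _ = dmr_caller.global_methylation_levels([ms])
        assert levels.query("context == 'CHH'")["level"].iloc[0] == pytest.approx(50.0)

    def test_no_qualifying_site_is_nan_not_zero(self):
        ms = self.make_set([1], [2])  # below min coverage 3
        levels, _ = dmr_caller.global_methylation_levels([ms], min_site_coverage=3)
        assert levels["level"].isna().all()

    def test_binomial_sampling_recovers_true_level(self):
        # 500 CHH sites at a true 10% level, coverage 14: estimate within 3 pp
        rng = np.random.default_rng(7)
        total = np.full(500, 14)
        meth = rng.binomial(total, 0.10)
        ms = self.make_set(meth, total)
        levels, _ = dmr_caller.global_methylation_levels([ms])
        est = levels.query("context == 'CHH'")["level"].iloc[0]
        assert abs(est - 10.0) < 3.0


class TestEnumerateWindows:
    def test_length_450_gives_five_windows(self):
        w = dmr_caller.enumerate_windows({"c": 450})
        assert list(map(tuple, w[["start", "end"]].to_numpy())) == [
            (0, 200), (100, 300), (200, 400), (300, 450), (400, 450)]

    def test_length_200_gives_two_windows(self):
        w = dmr_caller.enumerate_windows({"c": 200})
        assert list(map(tuple, w[["start", "end"]].to_numpy())) == [(0, 200), (100, 200)]

    @given(st.integers(min_value=1, max_value=1000))
    @settings(max_examples=200, derandomize=True)
    def test_interior_bases_covered_exactly_twice(self, length):
        w = dmr_caller.enumerate_windows({"c": length})
        cover = np.zeros(length, int)
        for row in w.itertuples():
            cover[row.start:row.end] += 1
        # every base in [window_size, length) lies in window_size/step = 2 windows
        interior = cover[200:]
        assert (interior == 2).all() if len(interior) else True
        assert (cover >= 1).all()

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            dmr_caller.enumerate_windows({"c": 0})


class TestWindowLevel:
    def make_calls(self, pos, meth, total, context="CHH"):
        return pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                             "context": context,
                             "n_meth": np.asarray(meth, np.int64),
                             "n_total": np.asarray(total, np.int64)})

    def test_fully_methylated_sites(self):
        calls = self.make_calls([10, 20, 30, 40], [10] * 4, [10] * 4)
        level, n = dmr_caller.window_replicate_level(calls, ("chr1", 0, 200), "CHH")
        assert (level, n) == (100.0, 4)

    def test_low_coverage_site_excluded(self):
        calls = self.make_calls([10, 20, 30, 40, 50],
                                [2, 0, 0, 0, 0], [2, 10, 10, 10, 10])
        level, n = dmr_caller.window_replicate_level(calls, ("chr1", 0, 200), "CHH")
        assert n == 4  # the 2x site does not count
        assert level == pytest.approx(0.0)

    def test_mean_of_site_ratios(self):
        calls = self.make_calls([10, 20, 30, 40], [2, 8, 5, 5], [10] * 4)
        level, _ = dmr_caller.window_replicate_level(calls, ("chr1", 0, 200), "CHH")
        assert level == pytest.approx(50.0)

    def test_underpopulated_window_is_undefined(self):
        calls = self.make_calls([10, 20, 30], [1, 1, 1], [10] * 3)
        level, n = dmr_caller.window_replicate_level(calls, ("chr1", 0, 200), "CHH")
        assert n == 3 and math.isnan(level)

    def test_levels_match_brute_force_recomputation(self, calls_frame):
        # oracle: per-site recomputation with explicit loops on a <=10 kb instance
        params = DmrCallParams()
        sub = calls_frame[calls_frame.chrom == "chr1"]
        for start in range(0, 10_000, 100):
            window = ("chr1", start, min(start + 200, 10_000))
            for ctx in ("CG", "CHG", "CHH"):
                got, n = dmr_caller.window_replicate_level(sub, window, ctx, params)
                ratios = [r.n_meth / r.n_total for r in sub.itertuples()
                          if window[1] < r.pos <= window[2] and r.context == ctx
                          and r.n_total >= params.min_site_coverage]
                assert n == len(ratios)
                if len(ratios) >= params.min_sites_per_window:
                    assert got == pytest.approx(100 * np.mean(ratios))
                else:
                    assert math.isnan(got)


class TestTestWindow:
    def test_identical_groups(self):
        p, delta, sa, sb = dmr_caller.test_window([10, 12, 11], [10, 12, 11])
        assert delta == 0.0
        assert sa == sb == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_welch(self):
        a, b = np.array([10., 12., 11.]), np.array([30., 32., 31.])
        p, delta, *_ = dmr_caller.test_window(a, b, stat="welch")
        assert delta == pytest.approx(20.0)
        # independent hand computation of the Welch statistic and p-value
        se = math.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t = (b.mean() - a.mean()) / se
        df = (a.var(ddof=1) / 3 + b.var(ddof=1) / 3) ** 2 / (
            (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
        p_hand = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_zero_variance_groups(self):
        p, delta, sa, sb = dmr_caller.test_window([5, 5, 5], [5, 5, 5])
        assert sa == sb == 0.0 and p == 1.0
        p2, *_ = dmr_caller.test_window([5, 5, 5], [9, 9, 9])
        assert p2 == 0.0

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            dmr_caller.test_window([5], [5, 6])


class TestCallDmrs:
    def test_copy_of_reference_yields_no_dmrs(self, tiny_sim):
        ref = tiny_sim["ref"]
        clone = MethylomeSet("SD", {f"c{i}": df.copy() for i, df in
                                    enumerate(ref.samples.values())})
        dmrs = dmr_caller.call_dmrs(ref, clone)
        assert len(dmrs) == 0

    def test_direction_sign_coherence(self, tiny_sim):
        dmrs = dmr_caller.call_dmrs(tiny_sim["ref"], tiny_sim["test"])
        assert len(dmrs) > 0
        hypo = dmrs.direction == "hypo"
        assert (dmrs.delta_mc[hypo] < 0).all()
        assert (dmrs.delta_mc[~hypo] > 0).all()

    def test_swap_symmetry(self, tiny_sim):
        fwd = dmr_caller.call_dmrs(tiny_sim["ref"], tiny_sim["test"])
        rev = dmr_caller.call_dmrs(tiny_sim["test"], tiny_sim["ref"])
        key = ["chrom", "start", "context"]
        merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        assert len(merged) == len(fwd) == len(rev)
        assert np.allclose(merged.delta_mc_f, -merged.delta_mc_r)
        assert np.allclose(merged.p_value_f, merged.p_value_r)
        assert ((merged.direction_f == "hypo") == (merged.direction_r == "hyper")).all()

    def test_threshold_monotonicity(self, tiny_sim):
        base = dmr_caller.call_dmrs(tiny_sim["ref"], tiny_sim["test"])
        stricter_p = dmr_caller.call_dmrs(
            tiny_sim["ref"], tiny_sim["test"],
            params=DmrCallParams(p_threshold=0.001))
        stricter_sda = dmr_caller.call_dmrs(
            tiny_sim["ref"], tiny_sim["test"],
            params=DmrCallParams(sda_threshold={"CG": 2, "CHG": 2, "CHH": 2}))
        assert len(stricter_p) <= len(base)
        assert len(stricter_sda) <= len(base)

    def test_sda_filter_excludes_noisy_windows(self):
        # one group is internally inconsistent: high SDA must veto the call
        ref = methylome_from_levels({"a": 10, "b": 10, "c": 10})
        test = methylome_from_levels({"a": 40, "b": 60, "c": 80}, condition="SD")
        loose = dmr_caller.call_dmrs(
            ref, test, params=DmrCallParams(
                p_threshold=0.05, min_sites_per_window=4,
                sda_threshold={"CG": 1e9, "CHG": 1e9, "CHH": 1e9}))
        tight = dmr_caller.call_dmrs(
            ref, test, params=DmrCallParams(
                p_threshold=0.05, sda_threshold={"CG": 5, "CHG": 5, "CHH": 5}))
        assert len(loose) >= 1
        assert len(tight) == 0

    def test_fisher_variant_runs(self):
        ref = methylome_from_levels({"a": 10, "b": 10})
        test = methylome_from_levels({"a": 90, "b": 90}, condition="SD")
        dmrs = dmr_caller.call_dmrs(ref, test,
                                    params=DmrCallParams(stat="fisher"))
        assert len(dmrs) >= 1
        assert (dmrs.direction == "hyper").all()


class TestSummary:
    # the study's printed per-context counts (hypo, hyper) per comparison
    SD_COUNTS = {"CHH": (93_784, 4_998), "CHG": (22, 157), "CG": (78, 398)}
    YG_COUNTS = {"CHH": (27_945, 14_749), "CHG": (19, 370), "CG": (68, 850)}

    def test_printed_share_structure(self):
        s = DmrSummary.from_counts(
            {c: {"hypo": h, "hyper": y} for c, (h, y) in self.SD_COUNTS.items()})
        assert round_half_away(s.direction_share("hypo"), 1) == 94.4
        assert round_half_away(s.context_share("CHH"), 1) == 99.3
        assert round_half_away(s.direction_share("hypo", ["CHH"]), 1) == 94.9

    def test_counts_conserved(self, tiny_sim):
        dmrs = dmr_caller.call_dmrs(tiny_sim["ref"], tiny_sim["test"])
        s = dmr_caller.summarize_dmrs(dmrs)
        assert s.total == len(dmrs)
        assert s.as_frame().query("context == 'all'")["total"].iloc[0] == len(dmrs)

    def test_empty_set_shares_undefined(self):
        s = dmr_caller.summarize_dmrs(pd.DataFrame(
            columns=["context", "direction"]))
        assert s.total == 0
        assert math.isnan(s.direction_share("hypo"))
        assert math.isnan(s.context_share("CHH"))

    @pytest.mark.parametrize("x,nd,expected", [
        (0.5, 0, 1.0), (-0.5, 0, -1.0), (2.5, 0, 3.0),
        (94.35, 1, 94.4), (84.735, 1, 84.7),
    ])
    def test_round_half_away(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestDensity:
    def test_no_dmrs_gives_empty_track(self):
        track = dmr_caller.dmr_density(pd.DataFrame(columns=["chrom", "start", "context"]),
                                       {"chr1": 100_000})
        assert len(track) == 0

    def test_counts_in_first_bin(self):
        dmrs = pd.DataFrame({"chrom": "chr1",
                             "start": [0, 100, 20_000, 49_900, 60_000],
                             "context": "CHH"})
        track = dmr_caller.dmr_density(dmrs, {"chr1": 100_000})
        first = track[(track.bin_start == 0)]
        assert first["count"].iloc[0] == 4
        assert track[(track.bin_start == 50_000)]["count"].iloc[0] == 1

    def test_bin_counts_conserve_totals(self, tiny_sim):
        dmrs = dmr_caller.call_dmrs(tiny_sim["ref"], tiny_sim["test"])
        track = dmr_caller.dmr_density(dmrs, {"chr1": tiny_sim["spec"].chrom_length})
        for ctx, grp in track.groupby("context"):
            assert grp["count"].sum() == (dmrs.context == ctx).sum()


def test_merge_dmrs_collapses_overlapping_runs():
    dmrs = pd.DataFrame({
        "chrom": "chr1", "start": [0, 100, 400], "end": [200, 300, 600],
        "context": "CHH", "delta_mc": [-10., -12., -8.],
        "p_value": [1e-3, 1e-4, 1e-3], "direction": "hypo"})
    merged = dmr_caller.merge_dmrs(dmrs)
    assert list(map(tuple, merged[["start", "end"]].to_numpy())) == [(0, 300), (400, 600)]
    assert merged.delta_mc.iloc[0] == -12.0
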