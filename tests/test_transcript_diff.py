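"""DET selection, BIN classification, enrichment, contrasts and 2^-ddCt."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from methylgraft import transcript_diff as td


def det_table(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "kind", "ratio", "p_value"])


class TestSelectDets:
    def test_threshold_is_inclusive(self):
        sel = td.select_dets(det_table([("a", "gene", 1.0, 0.009),
                                        ("b", "gene", 1.0, 0.011)]))
        assert sel["all"].transcript_id.tolist() == ["a"]

    def test_empty_table(self):
        sel = td.select_dets(det_table([]))
        assert len(sel["all"]) == 0 and len(sel["gene"]) == 0 and len(sel["TE"]) == 0

    def test_matches_direct_filter_oracle(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(0, 1e-4, 100), rng.uniform(0, 1, 10_000)])
        kinds = rng.choice(["gene", "TE"], len(p))
        tab = det_table([(f"t{i}", kinds[i], 0.5, p[i]) for i in range(len(p))])
        sel = td.select_dets(tab, alpha=0.01)
        assert len(sel["all"]) == int((p <= 0.01).sum())
        assert len(sel["gene"]) + len(sel["TE"]) == len(sel["all"])

    def test_idempotent_and_monotone_in_alpha(self):
        rng = np.random.default_rng(4)
        tab = det_table([(f"t{i}", "gene", 0.0, rng.random()) for i in range(500)])
        sel1 = td.select_dets(tab, alpha=0.05)["all"]
        sel2 = td.select_dets(sel1, alpha=0.05)["all"]
        pd.testing.assert_frame_equal(sel1, sel2)
        assert len(td.select_dets(tab, alpha=0.01)["all"]) <= len(sel1)


class TestBins:
    MAP = pd.DataFrame({
        "bincode": ["1", "1.1", "15", "24"],
        "name": ["Photosynthesis", "PSII", "RNA biosynthesis", "Solute transport"],
        "identifier": ["a", "a", "b", "c"],
    })

    def test_most_specific_bin_wins(self):
        assigned = td.assign_bins(["a"], self.MAP)
        assert assigned.bincode.tolist() == ["1.1"]

    def test_unassigned_excluded(self):
        tab = det_table([("a", "gene", 1, 0.001), ("zz", "gene", 1, 0.001)])
        res = td.classify_bins(tab, self.MAP)
        assert res["count"].sum() == 1

    def test_single_bin_is_hundred_percent(self):
        tab = det_table([("b", "gene", 1, 0.001)])
        res = td.classify_bins(tab, self.MAP)
        assert res.pct.tolist() == [100.0]

    def test_small_classes_collapse_into_other(self):
        # 25 transcripts in one bin, 1 in another (4%): the 4% class collapses
        rows = [(f"x{i}", "gene", 1, 0.001) for i in range(24)] + \
               [("b", "gene", 1, 0.001)]
        big_map = pd.DataFrame({
            "bincode": ["9"] * 24 + ["15"],
            "name": ["Big"] * 24 + ["RNA biosynthesis"],
            "identifier": [f"x{i}" for i in range(24)] + ["b"]})
        res = td.classify_bins(det_table(rows), big_map, collapse_below=5.0)
        assert set(res.name) == {"Big", "Other class"}
        assert res[res.name == "Other class"].pct.iloc[0] == pytest.approx(4.0)

    def test_percentages_match_independent_tally(self):
        rng = np.random.default_rng(11)
        ids = [f"t{i}" for i in range(200)]
        codes = rng.choice(["1", "15", "24"], 200)
        bmap = pd.DataFrame({"bincode": codes, "name": codes, "identifier": ids})
        tab = det_table([(i, "gene", 1, 0.001) for i in ids])
        res = td.classify_bins(tab, bmap)
        tally = pd.Series(codes).value_counts()
        for row in res.itertuples():
            assert row.count == tally[row.bincode]
            assert row.pct == pytest.approx(100 * tally[row.bincode] / 200)
        assert res.pct.sum() == pytest.approx(100.0)


def hypergeom_tail(k, N, K, n):
    """Exhaustive sum of the upper hypergeometric tail P(X >= k)."""
    return sum(comb(K, i, exact=True) * comb(N - K, n - i, exact=True)
               for i in range(k, min(K, n) + 1)) / comb(N, n, exact=True)


def brute_force_bh(p):
    """Textbook Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestEnrichment:
    def bin_map_for(self, ids, codes):
        return pd.DataFrame({"bincode": codes, "name": codes, "identifier": ids})

    def test_dets_equal_background_gives_p_one(self):
        ids = [f"t{i}" for i in range(20)]
        bmap = self.bin_map_for(ids, ["1"] * 10 + ["2"] * 10)
        res = td.enrichment(pd.Series(ids), pd.Series(ids), bmap)
        assert np.allclose(res.p_value, 1.0)

    def test_matches_exhaustive_tail_enumeration(self):
        # k=5 of n=10 DETs in a bin holding K=10 of N=100 transcripts
        ids = [f"t{i}" for i in range(100)]
        codes = ["1"] * 10 + ["2"] * 90
        bmap = self.bin_map_for(ids, codes)
        dets = ids[:5] + ids[10:15]  # 5 in bin 1, 5 in bin 2
        res = td.enrichment(pd.Series(dets), pd.Series(ids), bmap)
        row = res[res.bincode == "1"].iloc[0]
        assert (row.k, row.n, row.K, row.N) == (5, 10, 10, 100)
        assert row.p_value == pytest.approx(hypergeom_tail(5, 100, 10, 10), rel=1e-12)

    def test_single_bin_q_equals_p(self):
        ids = [f"t{i}" for i in range(30)]
        bmap = self.bin_map_for(ids, ["7"] * 30)
        res = td.enrichment(pd.Series(ids[:4]), pd.Series(ids), bmap)
        assert len(res) == 1
        assert res.q_value.iloc[0] == pytest.approx(res.p_value.iloc[0])

    def test_inconsistent_map_raises(self):
        bmap = pd.DataFrame({"bincode": ["1", "2"], "name": ["a", "b"],
                             "identifier": ["x", "y"]})
        with pytest.raises(ValueError, match="background"):
            td.enrichment(pd.Series(["x"]), pd.Series(["y"]), bmap)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_bh_matches_brute_force(self, pvals):
        from statsmodels.stats.multitest import multipletests
        got = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(got, brute_force_bh(pvals), atol=1e-12)


class TestCompareContrasts:
    def test_disjoint_sets(self):
        cmp = td.compare_contrasts(det_table([("a", "gene", 1, 0)]),
                                   det_table([("b", "gene", 1, 0)]))
        assert cmp["common"] == set()
        assert cmp["specific_1"] == {"a"}

    def test_concordant_and_opposite_counts(self):
        cmp = td.compare_contrasts(
            det_table([("a", "gene", 1.0, 0), ("b", "gene", -1.0, 0)]),
            det_table([("a", "gene", 0.5, 0), ("b", "gene", 2.0, 0)]))
        assert len(cmp["common"]) == 2
        assert cmp["concordant_up"] == 1
        assert cmp["opposite"] == 1

    def test_partition_property(self):
        rng = np.random.default_rng(13)
        ids1 = rng.choice(2000, 300, replace=False)
        ids2 = rng.choice(2000, 400, replace=False)
        t1 = det_table([(f"t{i}", "gene", float(rng.normal()), 0) for i in ids1])
        t2 = det_table([(f"t{i}", "gene", float(rng.normal()), 0) for i in ids2])
        cmp = td.compare_contrasts(t1, t2)
        assert len(cmp["specific_1"]) + len(cmp["common"]) == len(t1)
        assert len(cmp["specific_2"]) + len(cmp["common"]) == len(t2)
        assert cmp["concordant_up"] + cmp["concordant_down"] + cmp["opposite"] \
            == len(cmp["common"])


class TestDdct:
    REFS = {"ACTIN": 18.0, "GAPDH": 19.0, "TUBULIN": 20.0}

    def test_calibrator_maps_to_one(self):
        m = [td.QpcrMeasurement("cal", 22.0, dict(self.REFS))]
        assert td.ddct_quantify(m, "cal")["cal"] == pytest.approx(1.0)

    def test_one_cycle_doubling(self):
        m = [td.QpcrMeasurement("cal", 22.0, dict(self.REFS)),
             td.QpcrMeasurement("s", 21.0, dict(self.REFS))]
        assert td.ddct_quantify(m, "cal")["s"] == pytest.approx(2.0)

    def test_normalization_factor_is_geometric_mean(self):
        # reference quantities 1, 2, 4 -> NF = 2; unchanged target -> 1/2
        refs_s = {"ACTIN": 18.0, "GAPDH": 18.0, "TUBULIN": 18.0}
        m = [td.QpcrMeasurement("cal", 22.0, dict(refs_s)),
             td.QpcrMeasurement("s", 22.0,
                                {"ACTIN": 18.0, "GAPDH": 17.0, "TUBULIN": 16.0})]
        assert td.ddct_quantify(m, "cal")["s"] == pytest.approx(0.5)

    def test_global_ct_shift_cancels(self):
        m = [td.QpcrMeasurement("cal", 22.0, dict(self.REFS)),
             td.QpcrMeasurement("s", 21.0, dict(self.REFS)),
             td.QpcrMeasurement("s_shift", 21.0 + 3.0,
                                {g: c + 3.0 for g, c in self.REFS.items()})]
        out = td.ddct_quantify(m, "cal")
        assert out["s_shift"] == pytest.approx(out["s"])

    def test_missing_reference_ct_raises(self):
        m = [td.QpcrMeasurement("cal", 22.0, dict(self.REFS)),
             td.QpcrMeasurement("s", 21.0, {"ACTIN": 18.0})]
        with pytest.raises(ValueError, match="lacks reference"):
            td.ddct_quantify(m, "cal")

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            td.QpcrMeasurement("x", 20.0, {"ACTIN": 18.0}, efficiency=2.5)
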