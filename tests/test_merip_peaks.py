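"""Window enrichment test, peak merging and differential methylation."""

import math

import numpy as np
import pandas as pd
import pytest

from lncm6a import merip_peaks as mp
from lncm6a.syn_data import SimulationConfig, simulate

from conftest import make_annotation


def binomial_tail_oracle(x, n, p0):
    """P(X >= x) by direct pmf summation."""
    return sum(math.comb(n, j) * p0**j * (1 - p0) ** (n - j)
               for j in range(x, n + 1))


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)
                / math.comb(n, r1))

    p_obs = pmf(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


class TestWindowTest:
    def test_zero_ip_gives_one(self):
        assert mp.window_test(0, 17, 1000, 1000) == 1.0

    def test_five_vs_zero_closed_form(self):
        assert math.isclose(mp.window_test(5, 0, 1000, 1000), 1 / 32)

    def test_empty_window_gives_one(self):
        assert mp.window_test(0, 0, 10, 10) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mp.window_test(-1, 3, 10, 10)

    def test_matches_enumeration_exhaustively(self):
        # every (x_ip, x_in) split of every window total n <= 50
        N_ip, N_in = 1_000, 2_000
        p0 = N_ip / (N_ip + N_in)
        for n in range(0, 51):
            x = np.arange(n + 1)
            got = mp.window_test(x, n - x, N_ip, N_in)
            want = [binomial_tail_oracle(int(xi), n, p0) for xi in x]
            assert np.allclose(got, want, rtol=1e-10)


def toy_wcm(ip_gm, in_gm, ip_d4=None, in_d4=None):
    """Single-transcript window matrix with one replicate per condition."""
    n = len(ip_gm)
    ann = make_annotation([("G1", "chr1", "+", [(0, 50 * (n + 1))])])
    windows = mp.make_windows(ann)
    assert len(windows) == n
    ip_d4 = ip_gm if ip_d4 is None else ip_d4
    in_d4 = in_gm if in_d4 is None else in_d4
    counts = pd.DataFrame({"GM_IP_1": ip_gm, "GM_input_1": in_gm,
                           "D4_IP_1": ip_d4, "D4_input_1": in_d4},
                          index=windows.index)
    libs = pd.DataFrame({
        "condition": ["GM", "GM", "D4", "D4"],
        "role": ["IP", "input", "IP", "input"],
        "replicate": [1, 1, 1, 1],
    }, index=pd.Index(["GM_IP_1", "GM_input_1", "D4_IP_1", "D4_input_1"],
                      name="library"))
    return mp.WindowCountMatrix(windows, counts, libs), ann


class TestCallPeaks:
    def test_adjacent_significant_windows_merge(self):
        ip = [5] * 20
        ip[4] = ip[5] = 500
        wcm, _ = toy_wcm(ip, [5] * 20)
        peaks = mp.call_peaks(wcm, "GM")
        assert len(peaks) == 1
        pk = peaks[0]
        # windows 4: sp [200,300) and 5: sp [250,350) merge to [200,350)
        assert (pk.sp_start, pk.sp_end) == (200, 350)
        assert (pk.interval.start, pk.interval.end) == (200, 350)
        assert pk.fdr <= 0.05

    def test_gap_beyond_step_stays_separate(self):
        ip = [5] * 20
        ip[2] = ip[10] = 500
        wcm, _ = toy_wcm(ip, [5] * 20)
        peaks = mp.call_peaks(wcm, "GM")
        assert len(peaks) == 2

    def test_empty_matrix_empty_result(self):
        ann = make_annotation([("G1", "chr1", "+", [(0, 1000)])])
        windows = mp.make_windows(ann).iloc[:0]
        wcm = mp.WindowCountMatrix(
            windows, pd.DataFrame(index=windows.index,
                                  columns=["GM_IP_1", "GM_input_1"]).fillna(0),
            pd.DataFrame({"condition": ["GM", "GM"], "role": ["IP", "input"],
                          "replicate": [1, 1]},
                         index=pd.Index(["GM_IP_1", "GM_input_1"],
                                        name="library")))
        assert mp.call_peaks(wcm, "GM") == []

    def test_null_simulation_calls_almost_nothing(self):
        total_windows = total_peaks = 0
        for seed in range(10):
            res = simulate(SimulationConfig(
                seed=seed, n_lnc=12, n_coding=24, chrom_length=300_000,
                peak_enrichment_fold=1.0, frac_de=0.0),
                with_sequence=False)
            for cond in ("GM", "D4"):
                total_peaks += len(mp.call_peaks(res.window_counts, cond))
                total_windows += len(res.window_counts.windows)
        assert total_peaks <= math.ceil(total_windows / 10_000)

    def test_planted_peaks_recovered(self, default_sim, default_peaks):
        union = default_peaks["union"]
        recovered = 0
        for pk in default_sim.truth_peaks.itertuples():
            hit = any(u.gene_id == pk.gene_id
                      and u.interval.start < pk.end
                      and u.interval.end > pk.start for u in union)
            recovered += hit
        assert recovered / len(default_sim.truth_peaks) >= 0.9


class TestM6aLevel:
    def test_doubling_counts_and_totals_stable(self):
        a = mp.m6a_level(20, 20, 1000, 1000)
        b = mp.m6a_level(40, 40, 2000, 2000)
        assert abs(a - b) <= 0.1


class TestDifferential:
    def test_fisher_matches_enumeration(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            got = mp.fisher_test([[a, b], [c, d]])
            want = fisher_oracle(int(a), int(b), int(c), int(d))
            assert math.isclose(got, want, rel_tol=1e-9, abs_tol=1e-12)

    def test_balanced_table_is_null(self):
        assert mp.fisher_test([[10, 10], [10, 10]]) == 1.0

    def test_crossed_table_is_hyper(self):
        ip = [50] * 20
        ip[4] = ip[5] = 400
        wcm, _ = toy_wcm([50] * 20, [50] * 20, ip_d4=ip, in_d4=[50] * 20)
        union = mp.merge_peak_sets(mp.call_peaks(wcm, "D4"))
        diffs = mp.differential_peaks(union, wcm)
        assert len(diffs) == 1
        assert diffs[0].status == "hyper"
        assert diffs[0].diff_log2_fc > 0

    def test_condition_swap_antisymmetry(self, default_sim, default_peaks):
        wcm = default_sim.window_counts
        swapped_libs = wcm.libraries.copy()
        swapped_libs["condition"] = swapped_libs.condition.map(
            {"GM": "D4", "D4": "GM"})
        swapped = mp.WindowCountMatrix(wcm.windows, wcm.counts, swapped_libs)
        d1 = mp.differential_peaks(default_peaks["union"], wcm)
        d2 = mp.differential_peaks(default_peaks["union"], swapped)
        for a, b in zip(d1, d2):
            assert math.isclose(a.diff_log2_fc, -b.diff_log2_fc,
                                abs_tol=1e-12)
            assert math.isclose(a.fdr, b.fdr, rel_tol=1e-12)
            assert {a.status, b.status} in \
                ({"ns"}, {"hyper", "hypo"})

    def test_planted_hypo_peak_detected(self, default_sim, default_peaks):
        # Each planted hypomethylated peak (fold dropping from GM to D4,
        # the Brip1os-like pattern) should come out hypo
        truth = default_sim.truth_peaks
        hypo_genes = set(truth.loc[truth.true_diff_meth_level < -0.5,
                                   "gene_id"])
        called = {d.peak.gene_id: d.status for d in default_peaks["diffs"]}
        hit = sum(called.get(g) == "hypo" for g in hypo_genes)
        assert hit / max(len(hypo_genes), 1) >= 0.8

    def test_peak_without_window_is_error(self, default_sim, default_peaks):
        import dataclasses
        pk = dataclasses.replace(default_peaks["union"][0],
                                 transcript_id="nonexistent.T1")
        with pytest.raises(ValueError, match="no window"):
            mp.differential_peaks([pk], default_sim.window_counts)


class TestWindows:
    def test_short_transcript_single_window(self):
        ann = make_annotation([("G1", "chr1", "+", [(10, 60)])])
        w = mp.make_windows(ann)
        assert len(w) == 1
        assert (w.sp_start.iloc[0], w.sp_end.iloc[0]) == (0, 50)

    def test_junction_window_bounding_span(self):
        ann = make_annotation([("G1", "chr1", "+", [(0, 80), (200, 400)])])
        w = mp.make_windows(ann)
        first = w.iloc[0]  # spliced [0,100) spans the junction
        assert (first.start, first.end) == (0, 220)

    def test_pieces_cover_spliced_interval(self):
        ann = make_annotation([("G1", "chr1", "+", [(0, 80), (200, 400)])])
        tx = ann.transcripts["G1.T1"]
        pieces = mp.spliced_to_genomic_pieces(tx, 50, 150)
        assert pieces == [(50, 80), (200, 270)]
        assert sum(e - s for s, e in pieces) == 100

    def test_library_pairing_enforced(self):
        ann = make_annotation([("G1", "chr1", "+", [(0, 500)])])
        windows = mp.make_windows(ann)
        counts = pd.DataFrame({"GM_IP_1": 0, "GM_input_2": 0},
                              index=windows.index)
        libs = pd.DataFrame({"condition": ["GM", "GM"],
                             "role": ["IP", "input"], "replicate": [1, 2]},
                            index=pd.Index(["GM_IP_1", "GM_input_2"],
                                           name="library"))
        with pytest.raises(ValueError, match="pair"):
            mp.WindowCountMatrix(windows, counts, libs)
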