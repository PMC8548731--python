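"""Quadrant classification, correlation/KS statistics, worked-example replay."""

import math

import numpy as np
import pandas as pd
import pytest

from lncm6a import epitx_integration as ei


def record(gene="G", rna_fc=1.0, rna_padj=0.01, meth_fc=1.0, meth_sig=0.01):
    return pd.DataFrame([{"gene_id": gene, "rna_log2fc": rna_fc,
                          "rna_padj": rna_padj, "meth_log2fc": meth_fc,
                          "meth_sig": meth_sig}])


class TestClassifyQuadrants:
    def test_brip1os_row_is_hypo_down(self):
        # worked-example row: lncRNA down, methylation down, both significant
        df, _ = ei.classify_quadrants(
            record("Brip1os", -2.020791677, 2.06e-50, -0.631, -3.96),
            meth_sig_is_log10=True)
        assert df.group.iloc[0] == "Hypo-down"

    def test_sap30bpos_row_is_hyper_up(self):
        df, _ = ei.classify_quadrants(
            record("Sap30bpos", 4.068002111, 2.01e-4, 4.75, -1.71),
            meth_sig_is_log10=True)
        assert df.group.iloc[0] == "Hyper-up"

    def test_nonsignificant_expression_excluded(self):
        df, _ = ei.classify_quadrants(record(rna_padj=0.2))
        assert df.group.iloc[0] == "Excluded"
        assert df.reason.iloc[0] == "not_significant"

    def test_missing_statistic_excluded_with_reason(self):
        df, _ = ei.classify_quadrants(record(meth_fc=np.nan))
        assert df.group.iloc[0] == "Excluded"
        assert df.reason.iloc[0] == "missing_statistic"

    def test_threshold_tie_is_significant(self):
        df, _ = ei.classify_quadrants(
            record(rna_padj=0.05, meth_sig=math.log10(0.05)),
            meth_sig_is_log10=True)
        assert df.group.iloc[0] == "Hyper-up"

    def test_partition_is_exhaustive(self, rng):
        n = 200
        records = pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(n)],
            "rna_log2fc": rng.normal(size=n),
            "rna_padj": rng.uniform(size=n),
            "meth_log2fc": rng.normal(size=n),
            "meth_sig": rng.uniform(size=n),
        })
        _, counts = ei.classify_quadrants(records)
        assert sum(counts.values()) == n

    def test_meth_negation_swaps_hyper_hypo(self, rng):
        n = 300
        records = pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(n)],
            "rna_log2fc": rng.normal(size=n),
            "rna_padj": rng.uniform(size=n),
            "meth_log2fc": rng.normal(size=n),
            "meth_sig": rng.uniform(size=n),
        })
        _, c1 = ei.classify_quadrants(records)
        flipped = records.assign(meth_log2fc=-records.meth_log2fc)
        _, c2 = ei.classify_quadrants(flipped)
        assert c1["Hyper-up"] == c2["Hypo-up"]
        assert c1["Hyper-down"] == c2["Hypo-down"]
        assert c1["Excluded"] == c2["Excluded"]


class TestCorrelation:
    def test_perfect_positive(self):
        df = pd.concat([record(f"G{i}", meth_fc=float(i), rna_fc=float(i))
                        for i in range(1, 6)])
        res = ei.meth_expr_correlation(df)
        assert res.r == pytest.approx(1.0)
        assert res.n == 5

    def test_perfect_negative(self):
        df = pd.concat([record(f"G{i}", meth_fc=x, rna_fc=y)
                        for i, (x, y) in enumerate([(1, 3), (2, 2), (3, 1)])])
        res = ei.meth_expr_correlation(df)
        assert res.r == pytest.approx(-1.0)

    def test_small_n_has_no_pvalue(self):
        df = pd.concat([record("A", meth_fc=1, rna_fc=2),
                        record("B", meth_fc=2, rna_fc=1)])
        res = ei.meth_expr_correlation(df)
        assert res.n == 2 and math.isnan(res.p)

    def test_pvalue_matches_t_distribution(self, rng):
        from scipy import stats
        n = 30
        df = pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(n)],
            "rna_log2fc": rng.normal(size=n), "rna_padj": 0.01,
            "meth_log2fc": rng.normal(size=n), "meth_sig": 0.01,
        })
        res = ei.meth_expr_correlation(df)
        t = res.r * math.sqrt((n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-9)


def ks_oracle_D(a, b):
    """Brute-force ECDF sweep."""
    a, b = np.sort(a), np.sort(b)
    points = np.concatenate([a, b])
    d = 0.0
    for v in points:
        f1 = np.searchsorted(a, v, side="right") / len(a)
        f2 = np.searchsorted(b, v, side="right") / len(b)
        d = max(d, abs(f1 - f2))
    return d


class TestKS:
    def test_identical_samples(self):
        x = [0.1, 0.5, 0.9, 1.2]
        res = ei.ks_by_methylation(x + x, [True] * 4 + [False] * 4)
        assert res.D == 0.0 and res.p == pytest.approx(1.0)

    def test_disjoint_samples(self):
        res = ei.ks_by_methylation([0, 0, 0, 1, 1, 1],
                                   [True] * 3 + [False] * 3)
        assert res.D == 1.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            ei.ks_by_methylation([1.0, 2.0], [True, True])

    def test_D_matches_ecdf_sweep(self, rng):
        for _ in range(20):
            a = rng.normal(size=20)
            b = rng.normal(0.5, 1.2, size=20)
            res = ei.ks_by_methylation(np.concatenate([a, b]),
                                       [True] * 20 + [False] * 20)
            assert res.D == pytest.approx(ks_oracle_D(a, b), abs=1e-12)

    def test_p_close_to_permutation_estimate(self, rng):
        # the asymptotic p is approximate; a 1e5-permutation Monte-Carlo
        # estimate brackets it within its own resolution
        a = rng.normal(size=20)
        b = rng.normal(0.8, 1.0, size=20)
        res = ei.ks_by_methylation(np.concatenate([a, b]),
                                   [True] * 20 + [False] * 20)
        pooled = np.sort(np.concatenate([a, b]))
        n_perm = 100_000
        # vectorized label permutations: D = max prefix ECDF gap over the
        # pooled order, which equals the two-sample KS statistic
        ranks = np.argsort(rng.random((n_perm, 40)), axis=1)
        in_a = (ranks < 20).astype(np.int32)
        cum_a = np.cumsum(in_a, axis=1)
        cum_b = np.cumsum(1 - in_a, axis=1)
        D_perm = np.abs(cum_a / 20 - cum_b / 20).max(axis=1)
        p_perm = float((D_perm >= res.D - 1e-12).mean())
        assert abs(res.p - p_perm) <= 0.05


class TestWorkedExamples:
    def test_table2_groups_reproduced_rowwise(self):
        ex = ei.load_worked_example("table2")
        df, _ = ei.classify_quadrants(ex.records, meth_sig_is_log10=True)
        assert list(df.group) == list(ex.frame.Group)

    def test_table1_direction_split(self):
        ex = ei.load_worked_example("table1")
        assert ex.name == "table1"
        counts = ex.frame.Expression.value_counts()
        assert counts["Up"] == 9 and counts["Down"] == 5
        # every printed row is significant at the stated padj cutoff
        assert (ex.frame.padj <= 0.05).all()

    def test_header_mismatch_lists_expected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(ei.FixtureError, match="Ensembl_ID"):
            ei.load_worked_example(str(p))

    def test_empty_fixture_gives_empty_records(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("\t".join(ei.TABLE2_COLUMNS) + "\n")
        ex = ei.load_worked_example(str(p))
        assert len(ex.records) == 0


class TestQuadrantRecovery:
    def test_planted_hyper_up_recovered(self):
        """Quadrant classification on estimated statistics recovers planted
        hyper-up lncRNAs with sensitivity >= 0.8 and false discovery <= 0.2
        at default effect strengths, pooled over 10 seeds."""
        from lncm6a import (call_peaks, differential_expression,
                            differential_peaks, merge_peak_sets)
        from lncm6a.syn_data import SimulationConfig, simulate
        tp = fp = fn = 0
        for seed in range(10):
            res = simulate(SimulationConfig(
                seed=seed, n_lnc=30, n_coding=30, n_chromosomes=1,
                chrom_length=450_000), with_sequence=False)
            de = differential_expression(res.gene_counts)
            wcm = res.window_counts
            diffs = differential_peaks(
                merge_peak_sets(*(call_peaks(wcm, c) for c in ("GM", "D4"))),
                wcm)
            records = ei.records_from_results(de, diffs)
            assigned, _ = ei.classify_quadrants(records)
            called = set(assigned.loc[assigned.group == "Hyper-up",
                                      "gene_id"])
            truth = set(res.truth_genes.loc[
                res.truth_genes.true_group == "Hyper-up", "gene_id"])
            tp += len(called & truth)
            fp += len(called - truth)
            fn += len(truth - called)
        assert tp / (tp + fn) >= 0.8, (tp, fn)
        assert fp / max(tp + fp, 1) <= 0.2, (tp, fp)


class TestRecordsFromResults:
    def test_best_peak_represents_gene(self, default_sim, default_peaks):
        from lncm6a import differential_expression
        de = differential_expression(default_sim.gene_counts)
        records = ei.records_from_results(de, default_peaks["diffs"])
        assert records.gene_id.is_unique
        by_gene = {}
        for d in default_peaks["diffs"]:
            g = d.peak.gene_id
            if g not in by_gene or d.fdr < by_gene[g]:
                by_gene[g] = d.fdr
        got = dict(zip(records.gene_id, records.meth_sig))
        assert got == pytest.approx(by_gene)
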