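"""Expression parsing, normalization, imputation, co-expression, QC."""

import math

import numpy as np
import pandas as pd
import pytest

from funcnet.expression import (
    CoexpressionConfig,
    ExpressionMatrix,
    ImputationConfig,
    build_coexpression_network,
    impute_knn,
    parse_expression_table,
    qc_summary,
    transform_log2,
    write_expression_table,
    zscore_rows,
)
from funcnet.fixtures import gen_expression_dataset


def em(rows: dict, samples):
    return ExpressionMatrix(pd.DataFrame(rows, index=list(samples)).T)


class TestParseWrite:
    def test_well_formed_table(self, tmp_path):
        f = tmp_path / "expr.tsv"
        f.write_text("gene\tS1\tS2\ng1\t1.5\t2\ng2\tNA\t3\ng3\t\t-1\n")
        m = parse_expression_table(f)
        assert m.shape == (3, 2)
        assert np.isnan(m.values()[1, 0]) and np.isnan(m.values()[2, 0])
        assert m.values()[2, 1] == -1.0

    def test_ragged_row_reports_line(self, tmp_path):
        f = tmp_path / "expr.tsv"
        f.write_text("gene\tS1\tS2\ng1\t1\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_expression_table(f)

    def test_duplicate_gene_rejected(self, tmp_path):
        f = tmp_path / "expr.tsv"
        f.write_text("gene\tS1\tS2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ValueError, match="g1"):
            parse_expression_table(f)

    def test_non_numeric_cell_located(self, tmp_path):
        f = tmp_path / "expr.tsv"
        f.write_text("gene\tS1\tS2\ng1\t1\toops\n")
        with pytest.raises(ValueError, match="line 2.*column 3"):
            parse_expression_table(f)

    def test_round_trip(self, tmp_path, small_matrix):
        f = tmp_path / "expr.tsv"
        write_expression_table(small_matrix, f)
        back = parse_expression_table(f)
        pd.testing.assert_frame_equal(back.data, small_matrix.data.sort_index())


class TestTransformLog2:
    @pytest.mark.parametrize("x,expected", [(1.0, 1.0), (0.0, 0.0), (7.0, 3.0)])
    def test_log2_with_unit_shift(self, x, expected):
        m = em({"g": [x, x]}, ["S1", "S2"])
        assert transform_log2(m).values()[0, 0] == pytest.approx(expected)

    def test_missing_preserved(self):
        m = em({"g": [1.0, np.nan]}, ["S1", "S2"])
        out = transform_log2(m)
        assert np.isnan(out.values()[0, 1])

    def test_nonpositive_after_shift_lists_cells(self):
        m = em({"g": [-2.0, 1.0]}, ["S1", "S2"])
        with pytest.raises(ValueError, match="g"):
            transform_log2(m)


class TestZscoreRows:
    def test_simple_row(self):
        m = em({"g": [1.0, 2.0, 3.0]}, ["S1", "S2", "S3"])
        out, stats = zscore_rows(m)
        np.testing.assert_allclose(out.values()[0], [-1.0, 0.0, 1.0])
        assert stats.table.loc["g", "sd"] == pytest.approx(1.0)  # n-1 denominator

    def test_constant_row_flagged_all_zero(self):
        m = em({"g": [5.0, 5.0, 5.0]}, ["S1", "S2", "S3"])
        out, stats = zscore_rows(m)
        np.testing.assert_array_equal(out.values()[0], [0.0, 0.0, 0.0])
        assert stats.flagged == ["g"]

    def test_stats_on_observed_subset(self):
        # observed (2, 4, 6): mean 4, sd 2 -> (-1, missing, 0, 1)
        m = em({"g": [2.0, np.nan, 4.0, 6.0]}, ["S1", "S2", "S3", "S4"])
        out, _ = zscore_rows(m)
        v = out.values()[0]
        np.testing.assert_allclose([v[0], v[2], v[3]], [-1.0, 0.0, 1.0])
        assert np.isnan(v[1])

    def test_sparse_gene_dropped(self):
        m = em(
            {"g1": [1.0, np.nan, np.nan, 2.0], "g2": [1.0, 2.0, 3.0, 4.0]},
            ["S1", "S2", "S3", "S4"],
        )
        out, stats = zscore_rows(m)
        assert stats.dropped == ["g1"]
        assert out.gene_ids == ["g2"]

    def test_invariant_mean_zero_sd_one(self, rng):
        m, _ = gen_expression_dataset(n_genes=40, n_samples=15, missing_rate=0.1, seed=5)
        out, stats = zscore_rows(m)
        x = out.values()
        for i, g in enumerate(out.gene_ids):
            if g in stats.flagged:
                continue
            row = x[i][~np.isnan(x[i])]
            assert abs(row.mean()) < 1e-9
            assert abs(row.std(ddof=1) - 1) < 1e-9


def brute_force_impute(x, g, j, k, epsilon=1e-6, min_shared=3):
    """Independent oracle: per-spec distances, k nearest, inverse-distance weights."""
    cands = []
    for h in range(x.shape[0]):
        if h == g or math.isnan(x[h, j]):
            continue
        shared = [c for c in range(x.shape[1])
                  if not math.isnan(x[g, c]) and not math.isnan(x[h, c])]
        if len(shared) < min_shared:
            continue
        d = math.sqrt(sum((x[g, c] - x[h, c]) ** 2 for c in shared) / len(shared))
        cands.append((d, h))
    cands.sort()
    top = cands[:k]
    w = [1.0 / (d + epsilon) for d, _ in top]
    s = sum(w)
    return sum(wi / s * x[h, j] for wi, (_, h) in zip(w, top))


class TestImputeKnn:
    def test_zero_distance_duplicate_dominates(self):
        samples = [f"S{i}" for i in range(5)]
        rows = {
            "dup1": [1.0, -1.0, 0.5, -0.5, np.nan],
            "dup2": [1.0, -1.0, 0.5, -0.5, 0.7],
            "far": [-1.0, 1.0, -0.5, 0.5, -0.7],
        }
        m = em(rows, samples)
        out, report = impute_knn(m, ImputationConfig(k_impute=2))
        assert abs(out.data.loc["dup1", "S4"] - 0.7) < 1e-4
        assert len(report) == 1 and not report.cells[0].fallback_used

    def test_no_missing_is_identity(self, rng):
        m, _ = gen_expression_dataset(n_genes=10, n_samples=8, n_modules=2, module_size=3, missing_rate=0.0, seed=2)
        out, report = impute_knn(m)
        assert len(report) == 0
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_matches_hand_oracle_on_toy_matrix(self):
        r = np.random.default_rng(11)
        x = r.normal(size=(5, 6))
        x[2, 3] = np.nan
        x[4, 0] = np.nan
        samples = [f"S{i}" for i in range(6)]
        m = ExpressionMatrix(pd.DataFrame(x, index=[f"g{i}" for i in range(5)], columns=samples))
        out, report = impute_knn(m, ImputationConfig(k_impute=2))
        for gi, j in [(2, 3), (4, 0)]:
            expected = brute_force_impute(x, gi, j, k=2)
            assert out.values()[gi, j] == pytest.approx(expected, abs=1e-12)
        assert np.isnan(out.values()).sum() == 0

    def test_observed_cells_bit_identical(self, rng):
        m, _ = gen_expression_dataset(n_genes=30, n_samples=12, missing_rate=0.1, seed=9)
        mz, _ = zscore_rows(m)
        out, _ = impute_knn(mz)
        obs = ~np.isnan(mz.values())
        assert np.array_equal(out.values()[obs], mz.values()[obs])

    def test_no_candidates_falls_back_to_gene_mean(self):
        # the two genes never share >= min_shared observed columns
        samples = [f"S{i}" for i in range(6)]
        m = em(
            {
                "g1": [1.0, 2.0, 3.0, np.nan, np.nan, np.nan],
                "g2": [np.nan, np.nan, np.nan, np.nan, 4.0, 6.0],
            },
            samples,
        )
        out, report = impute_knn(m, ImputationConfig(min_shared=3))
        cell = [c for c in report.cells if (c.gene, c.sample) == ("g2", "S3")][0]
        assert cell.fallback_used
        assert out.data.loc["g2", "S3"] == pytest.approx(5.0)

    def test_weights_positive_and_sum_to_one(self):
        m, _ = gen_expression_dataset(n_genes=25, n_samples=10, n_modules=2, module_size=6, missing_rate=0.08, seed=4)
        mz, _ = zscore_rows(m)
        _, report = impute_knn(mz)
        for cell in report.cells:
            if cell.neighbors:
                assert all(w > 0 for w in cell.weights)
                assert sum(cell.weights) == pytest.approx(1.0)


class TestCoexpression:
    def test_pairwise_r_matches_textbook_formula(self):
        r = np.random.default_rng(3)
        x = r.normal(size=(4, 6))
        m = ExpressionMatrix(
            pd.DataFrame(x, index=[f"g{i}" for i in range(4)], columns=[f"S{j}" for j in range(6)])
        )
        # recompute the pre-transform correlations independently
        def pearson(a, b):
            am, bm = a - a.mean(), b - b.mean()
            return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))

        net = build_coexpression_network(m)
        pairs = sorted(net.edges)
        t = {p: net.edges[p] for p in pairs}
        raw = {}
        genes = m.gene_ids
        for i in range(4):
            for j in range(i + 1, 4):
                raw[(genes[i], genes[j])] = math.atanh(
                    max(min(pearson(x[i], x[j]), 1 - 1e-12), -1 + 1e-12)
                )
        vals = np.array([raw[p] for p in pairs])
        expected = (vals - vals.mean()) / vals.std(ddof=1)
        np.testing.assert_allclose([t[p] for p in pairs], expected, atol=1e-12)

    def test_identical_genes_attain_max_weight(self):
        r = np.random.default_rng(8)
        base = r.normal(size=6)
        x = np.vstack([base, base + 1e-13, r.normal(size=(3, 6))])
        m = ExpressionMatrix(
            pd.DataFrame(x, index=[f"g{i}" for i in range(5)], columns=[f"S{j}" for j in range(6)])
        )
        net = build_coexpression_network(m)
        assert net.edges[("g0", "g1")] == max(net.edges.values())

    def test_standardized_weights_mean_zero_sd_one(self):
        m, _ = gen_expression_dataset(n_genes=20, n_samples=10, n_modules=2, module_size=6, missing_rate=0.0, seed=6)
        net = build_coexpression_network(m)
        w = np.array(list(net.edges.values()))
        assert abs(w.mean()) < 1e-9
        assert abs(w.std(ddof=1) - 1) < 1e-9
        assert net.complete and net.net_type == "coexpression"

    def test_sample_permutation_invariant_and_symmetric(self):
        m, _ = gen_expression_dataset(n_genes=8, n_samples=9, n_modules=1, module_size=4, missing_rate=0.0, seed=7)
        net1 = build_coexpression_network(m)
        perm = ExpressionMatrix(m.data[list(np.random.default_rng(0).permutation(m.sample_ids))])
        net2 = build_coexpression_network(perm)
        for key in net1.edges:
            assert net1.edges[key] == pytest.approx(net2.edges[key], abs=1e-9)

    def test_zero_variance_gene_rejected(self):
        m = em({"g1": [1.0] * 5, "g2": list(range(5)), "g3": [0, 2, 1, 4, 3]},
               [f"S{i}" for i in range(5)])
        with pytest.raises(ValueError, match="z-score"):
            build_coexpression_network(m)


class TestQcSummary:
    def test_complete_matrix_zero_missing(self):
        m, _ = gen_expression_dataset(n_genes=6, n_samples=5, n_modules=1, module_size=3, missing_rate=0.0, seed=1)
        qc = qc_summary(m)
        assert (qc["per_sample"]["missing_fraction"] == 0).all()
        assert (qc["per_gene"]["missing_fraction"] == 0).all()

    def test_single_missing_cell_fractions(self):
        m = em({"g1": [1.0, np.nan], "g2": [2.0, 3.0]}, ["S1", "S2"])
        qc = qc_summary(m)
        assert sorted(qc["per_sample"]["missing_fraction"]) == [0.0, 0.5]

    def test_fractions_equal_direct_recount(self):
        m, _ = gen_expression_dataset(n_genes=30, n_samples=11, n_modules=2, module_size=8, missing_rate=0.15, seed=13)
        qc = qc_summary(m)
        x = m.values()
        np.testing.assert_allclose(
            qc["per_gene"]["missing_fraction"].to_numpy(), np.isnan(x).mean(axis=1)
        )
        np.testing.assert_allclose(
            qc["per_sample"]["missing_fraction"].to_numpy(), np.isnan(x).mean(axis=0)
        )
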