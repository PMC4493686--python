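"""Per-dataset effects, random-effects pooling, BH FDR, permutation enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.meta_analysis import combine_effects
from statsmodels.stats.multitest import multipletests

from funcnet.expression import ExpressionMatrix
from funcnet.fixtures import gen_case_control_collection
from funcnet.meta_analysis import (
    EffectEstimate,
    GeneSet,
    RandomEffectsMeta,
    adjust_bh,
    enrich_gene_sets,
    meta_analyze,
    parse_gmt,
    per_dataset_effects,
    pool_random_effects,
)

Z975 = 1.959963984540054


def effect(gene, ds, y, v):
    half = Z975 * math.sqrt(v)
    return EffectEstimate(gene, ds, y, v, y - half, y + half, 4, 4)


class TestPerDatasetEffects:
    def mat(self, case_rows, ctrl_rows):
        n_case, n_ctrl = len(case_rows[0]), len(ctrl_rows[0])
        cols = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_ctrl)]
        data = np.hstack([np.array(case_rows, float), np.array(ctrl_rows, float)])
        labels = {c: ("case" if c.startswith("c") else "control") for c in cols}
        df = pd.DataFrame(data, index=[f"g{i}" for i in range(len(case_rows))], columns=cols)
        return ExpressionMatrix(df, sample_conditions=labels)

    def test_hand_welch_computation(self):
        m = self.mat([[3.0, 5.0]], [[1.0, 3.0]])
        (e,) = per_dataset_effects(m)
        assert e.y == pytest.approx(2.0)
        assert e.v == pytest.approx(2.0)  # 2/2 + 2/2
        assert e.ci_low == pytest.approx(2 - Z975 * math.sqrt(2))
        assert e.ci_high == pytest.approx(2 + Z975 * math.sqrt(2))

    def test_degenerate_variance_floored(self):
        m = self.mat([[2.0, 2.0]], [[1.0, 1.0]])
        (e,) = per_dataset_effects(m)
        assert e.y == pytest.approx(1.0)
        assert e.v == pytest.approx(1e-8)
        assert e.ci_low == pytest.approx(1.0, abs=1e-3)

    def test_identical_groups_zero_effect(self):
        m = self.mat([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        (e,) = per_dataset_effects(m)
        assert e.y == 0.0

    def test_small_group_rejected(self):
        m = self.mat([[1.0]], [[1.0, 2.0]])
        with pytest.raises(ValueError, match="2 samples per group"):
            per_dataset_effects(m)

    def test_gene_missing_in_one_group_skipped(self):
        m = self.mat([[np.nan, np.nan, 1.0]], [[1.0, 2.0, 3.0]])
        assert per_dataset_effects(m) == []


class TestRandomEffectsPooling:
    def test_zero_heterogeneity_both_methods(self):
        effects = [effect("g", "d1", 1.0, 0.1), effect("g", "d2", 1.0, 0.1)]
        for method in ("REML", "DL"):
            r = pool_random_effects(effects, method=method)
            assert r.mu_hat == pytest.approx(1.0)
            assert r.tau2 == pytest.approx(0.0, abs=1e-10)

    def test_dl_hand_arithmetic(self):
        # y=(0,1,2), v=0.1 each: w=10, ybar=1, Q=20, C=30-300/30=20, tau2=0.9
        m = RandomEffectsMeta([0.0, 1.0, 2.0], [0.1, 0.1, 0.1])
        res = m.fit(method="DL")
        assert res.q_stat == pytest.approx(20.0, abs=1e-12)
        assert res.c_scale == pytest.approx(20.0, abs=1e-12)
        assert res.tau2 == pytest.approx(0.9, abs=1e-12)
        assert res.mu == pytest.approx(1.0, abs=1e-12)

    def test_dl_matches_statsmodels(self, rng):
        for _ in range(10):
            k = rng.integers(3, 12)
            y = rng.normal(0.4, 0.5, size=k)
            v = rng.uniform(0.02, 0.2, size=k)
            res = RandomEffectsMeta(y, v).fit(method="DL")
            sm = combine_effects(y, v, method_re="chi2")  # DerSimonian-Laird
            # statsmodels reports the untruncated moment estimate
            assert res.tau2 == pytest.approx(max(sm.tau2, 0.0), rel=1e-8, abs=1e-12)
            if sm.tau2 > 0:
                assert res.mu == pytest.approx(sm.mean_effect_re, rel=1e-8)

    def test_reml_matches_scipy_free_optimum(self, rng):
        # independent check: REML tau2 is a stationary/boundary point of the
        # restricted likelihood evaluated on a dense grid
        y = rng.normal(0.5, 0.6, size=15)
        v = rng.uniform(0.01, 0.05, size=15)
        m = RandomEffectsMeta(y, v)
        res = m.fit(method="REML")
        grid = np.linspace(0, 5 * np.var(y, ddof=1), 20001)
        nll = [m._neg_restricted_loglik(t) for t in grid]
        assert m._neg_restricted_loglik(res.tau2) <= min(nll) + 1e-6

    def test_reml_dl_rank_correlation(self):
        r = np.random.default_rng(77)
        reml_t, dl_t = [], []
        for _ in range(100):
            k = 8
            theta = r.normal(0.0, 0.3, size=k)
            v = r.uniform(0.01, 0.05, size=k)
            y = theta + r.normal(0, np.sqrt(v))
            m = RandomEffectsMeta(y, v)
            reml_t.append(m.fit("REML").tau2)
            dl_t.append(m.fit("DL").tau2)
        rho = sps.spearmanr(reml_t, dl_t).statistic
        assert rho > 0.9

    def test_equal_effects_give_zero_tau2(self):
        m = RandomEffectsMeta([0.7] * 5, [0.1, 0.2, 0.3, 0.1, 0.2])
        for method in ("REML", "DL"):
            assert m.fit(method).tau2 == pytest.approx(0.0, abs=1e-10)

    def test_dl_reduces_to_fixed_effect_when_q_small(self):
        y, v = [1.0, 1.01, 0.99], [0.5, 0.5, 0.5]
        res = RandomEffectsMeta(y, v).fit("DL")
        assert res.q_stat <= 2
        assert res.tau2 == 0.0
        w = 1 / np.array(v)
        assert res.mu == pytest.approx(float(w @ y / w.sum()))

    def test_single_study_pass_through(self):
        r = pool_random_effects([effect("g", "d1", 0.8, 0.04)])
        assert r.k_studies == 1 and r.tau2 == 0.0
        assert r.mu_hat == pytest.approx(0.8)
        assert r.se_mu == pytest.approx(0.2)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            RandomEffectsMeta([1.0, 2.0], [0.1, 0.0])

    def test_summary_table(self):
        res = RandomEffectsMeta([0.0, 1.0, 2.0], [0.1, 0.1, 0.1]).fit("DL")
        s = res.summary()
        assert s.loc["pooled", "k"] == 3
        assert s.loc["pooled", "ci_low"] < 1.0 < s.loc["pooled", "ci_high"]


class TestAdjustBH:
    def test_hand_step_up_example(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p,expected", [([0.3], [0.3]), ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])])
    def test_edge_cases(self, p, expected):
        np.testing.assert_allclose(adjust_bh(p), expected)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            adjust_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40), st.integers(0, 999))
    def test_permutation_invariant_and_monotone(self, pvals, seed):
        p = np.array(pvals)
        q = adjust_bh(p)
        perm = np.random.default_rng(seed).permutation(len(p))
        np.testing.assert_allclose(adjust_bh(p[perm]), q[perm], atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


def make_meta_table(n=400, seed=0):
    """Synthetic null meta-analysis table (uniform p, symmetric effects)."""
    r = np.random.default_rng(seed)
    df = pd.DataFrame(
        {"mu_hat": r.normal(size=n), "p": r.uniform(size=n)},
        index=[f"g{i:03d}" for i in range(n)],
    )
    df.index.name = "gene"
    return df


class TestEnrichment:
    def test_extreme_planted_set_hits_floor(self):
        meta = make_meta_table(seed=1)
        up = meta[meta.mu_hat > 0].sort_values("p")
        gs = GeneSet("top", frozenset(up.index[:20]))
        (res_up, res_down) = enrich_gene_sets(meta, [gs], B=1000, seed=2)
        assert res_up.direction == "up"
        assert res_up.p_perm == pytest.approx(1 / 1001)
        assert res_up.p_perm >= 1 / (res_up.n_permutations + 1)

    def test_disjoint_set_skipped(self):
        meta = make_meta_table(seed=1)
        out = enrich_gene_sets(meta, [GeneSet("alien", frozenset({"x1", "x2", "x3"}))], B=50, seed=0)
        assert out == []

    def test_reproducible_with_seed(self):
        meta = make_meta_table(seed=3)
        gs = GeneSet("s", frozenset(meta.index[10:40]))
        a = enrich_gene_sets(meta, [gs], B=200, seed=9)
        b = enrich_gene_sets(meta, [gs], B=200, seed=9)
        assert [(r.p_perm, r.observed_stat) for r in a] == [(r.p_perm, r.observed_stat) for r in b]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_gene_sets(pd.DataFrame(columns=["mu_hat", "p"]), [], B=10, seed=0)


def test_parse_gmt(tmp_path):
    f = tmp_path / "sets.gmt"
    f.write_text("pathA\tdesc\tg1\tg2\tg3\npathB\tdesc\tg4\tg5\n")
    sets = parse_gmt(f)
    assert [s.name for s in sets] == ["pathA", "pathB"]
    assert sets[0].genes == frozenset({"g1", "g2", "g3"})


def test_meta_analyze_end_to_end_recovers_planted_genes():
    coll, truth = gen_case_control_collection(
        n_datasets=6, n_genes=100, n_per_group=4, frac_de=0.2, mu_de=1.0,
        tau=0.25, sigma=0.5, seed=21,
    )
    effects = []
    for m, labels in coll:
        effects.extend(per_dataset_effects(m, labels))
    table = meta_analyze(effects, method="REML")
    de = sorted(truth.de_genes)
    null = table.drop(index=de)
    assert table.loc[de, "q"].median() < 0.01
    assert null["q"].median() > 0.2
    # q-values inherit p-value order within the tested set
    srt = table.sort_values("p")
    assert (np.diff(srt["q"]) >= -1e-12).all()
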