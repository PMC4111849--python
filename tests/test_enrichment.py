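"""Count statistics: normalization, dispersion, exact test, enrichment, usage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oracles import permutation_usage_p

from novex.enrichment import (
    estimate_dispersion,
    estimate_size_factors,
    exon_usage_test,
    gene_level_test,
    nb_exact_test,
    pairwise_enrichment,
)
from novex.enrichment import _usage_stat
from novex.simulate import simulate_condition_usage

SEED = 20140713


class TestSizeFactors:
    def test_doubled_column(self):
        """Column 2 = 2 x column 1 forces factors (1/sqrt2, sqrt2)."""
        m = pd.DataFrame({"a": [10, 40, 7], "b": [20, 80, 14]})
        s = estimate_size_factors(m)
        assert s["a"] == pytest.approx(1 / np.sqrt(2))
        assert s["b"] == pytest.approx(np.sqrt(2))
        assert np.prod(s.values) == pytest.approx(1.0)

    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2], "c": [5, 9, 2]})
        assert np.allclose(estimate_size_factors(m), 1.0)

    def test_error_without_all_positive_feature(self):
        m = pd.DataFrame({"a": [0, 3], "b": [2, 0]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            estimate_size_factors(m)
        s = estimate_size_factors(m, pseudo_reference=True)
        assert (s > 0).all()

    def test_recovery_of_true_depths(self):
        """True depth factors (1, 2, 4) recovered within 5% relative error."""
        rng = np.random.default_rng(SEED)
        true_s = np.array([1.0, 2.0, 4.0])
        mu = np.exp(rng.normal(4, 1, 5000))
        r = 1 / 0.1
        k = rng.negative_binomial(r, r / (r + mu[:, None] * true_s[None, :]))
        s = estimate_size_factors(pd.DataFrame(k, columns=list("abc")))
        expected = true_s / np.exp(np.mean(np.log(true_s)))
        assert np.all(np.abs(s.values / expected - 1) < 0.05)


class TestDispersion:
    design6 = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))

    def test_constant_feature_has_zero_raw_dispersion(self):
        m = pd.DataFrame([[7] * 6, [50, 52, 49, 51, 50, 48]], columns=list("abcdef"))
        s = pd.Series(1.0, index=m.columns)
        a = estimate_dispersion(m, self.design6, s, shrink=False)
        assert a.iloc[0] == 0.0

    def test_all_zero_feature_flagged_nan(self):
        m = pd.DataFrame([[0] * 6, [50, 52, 49, 51, 50, 48]], columns=list("abcdef"))
        s = pd.Series(1.0, index=m.columns)
        a = estimate_dispersion(m, self.design6, s)
        assert np.isnan(a.iloc[0])

    def test_poisson_truth_estimated_near_zero(self):
        """Median fitted dispersion < 0.02 when counts are Poisson."""
        rng = np.random.default_rng(SEED)
        mu = np.exp(rng.normal(4, 1, 2000))
        k = rng.poisson(np.broadcast_to(mu[:, None], (2000, 6)))
        m = pd.DataFrame(k, columns=list("abcdef"))
        a = estimate_dispersion(m, self.design6, estimate_size_factors(m))
        assert float(np.nanmedian(a)) < 0.02

    def test_nb_dispersion_recovered(self):
        """True alpha = 0.2 recovered with median in [0.1, 0.3]."""
        rng = np.random.default_rng(SEED + 1)
        mu = np.exp(rng.normal(4, 1, 2000))
        r = 1 / 0.2
        k = rng.negative_binomial(r, r / (r + np.broadcast_to(mu[:, None], (2000, 6))))
        m = pd.DataFrame(k, columns=list("abcdef"))
        a = estimate_dispersion(m, self.design6, estimate_size_factors(m))
        assert 0.1 <= float(np.nanmedian(a)) <= 0.3


class TestNbExactTest:
    def test_balanced_split_gives_p_one(self):
        p, sign = nb_exact_test([10, 12], [10, 12], [1, 1], [1, 1], 0.1)
        assert p == 1.0 and sign == 0

    def test_poisson_limit_closed_form(self):
        """alpha = 0: 10 vs 0 equals the two-sided binomial split at q = 1/2."""
        p, sign = nb_exact_test([10], [0], [1.0], [1.0], 0.0)
        assert p == pytest.approx(2 * 0.5**10)
        assert sign == 1

    def test_both_groups_zero(self):
        p, sign = nb_exact_test([0, 0], [0, 0], [1, 1], [1, 1], 0.2)
        assert p == 1.0 and sign == 0

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(SEED)
        for _ in range(25):
            ka = rng.integers(0, 300, 3)
            kb = rng.integers(0, 300, 3)
            sa = rng.uniform(0.5, 2, 3)
            sb = rng.uniform(0.5, 2, 3)
            a = float(rng.uniform(0, 0.5))
            p1, s1 = nb_exact_test(ka, kb, sa, sb, a)
            p2, s2 = nb_exact_test(kb, ka, sb, sa, a)
            assert p1 == pytest.approx(p2, rel=1e-9)
            assert s1 == -s2

    def test_alpha_to_zero_converges_to_binomial(self):
        """At alpha = 1e-8 the NB test matches the conditional binomial."""
        from scipy import stats as sps

        rng = np.random.default_rng(SEED + 2)
        for _ in range(40):
            ka, kb = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            if ka + kb == 0:
                continue
            sa, sb = float(rng.uniform(0.5, 2)), float(rng.uniform(0.5, 2))
            p_nb, _ = nb_exact_test([ka], [kb], [sa], [sb], 1e-8)
            pmf = sps.binom.pmf(np.arange(ka + kb + 1), ka + kb, sa / (sa + sb))
            p_bin = float(pmf[pmf <= pmf[ka] * (1 + 1e-7)].sum())
            assert abs(p_nb - p_bin) < 1e-6

    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(SEED + 3)
        for _ in range(50):
            ka = rng.integers(0, 500, 2)
            kb = rng.integers(0, 500, 2)
            p, _ = nb_exact_test(ka, kb, [1, 1], [1, 1], float(rng.uniform(0, 1)))
            assert 0 < p <= 1


def _enrichment_matrix(rng, n_features, target_rows, fold, mu=50.0, alpha=0.1, n_rep=2):
    tissues = ["brain", "heart", "liver", "testes"]
    samples = [f"{t}_{i}" for t in tissues for i in range(n_rep)]
    design = pd.Series([t for t in tissues for _ in range(n_rep)], index=samples)
    r = 1 / alpha
    rows = []
    for i in range(n_features):
        mu_row = np.array(
            [mu * (fold if (i in target_rows and design[s] == "testes") else 1.0) for s in samples]
        )
        rows.append(rng.negative_binomial(r, r / (r + mu_row)))
    m = pd.DataFrame(rows, index=[f"f{i}" for i in range(n_features)], columns=samples)
    return m, design


class TestPairwiseEnrichment:
    def test_strong_target_excess_called_enriched(self):
        """100-fold testes excess: enriched with every comparison < 0.05."""
        rng = np.random.default_rng(SEED)
        m, design = _enrichment_matrix(rng, 40, {0, 1, 2}, fold=100.0, mu=500.0, alpha=0.05)
        res = pairwise_enrichment(m, design, "testes")
        assert res.loc[["f0", "f1", "f2"], "enriched"].all()
        assert (res.loc[["f0", "f1", "f2"], "p_max"] < 0.05).all()

    def test_flat_feature_not_enriched(self):
        rng = np.random.default_rng(SEED + 1)
        m, design = _enrichment_matrix(rng, 30, set(), fold=1.0)
        res = pairwise_enrichment(m, design, "testes")
        assert not res["enriched"].any()

    def test_high_in_two_tissues_fails_conjunction(self):
        """A feature high in testes AND heart fails the heart comparison."""
        rng = np.random.default_rng(SEED + 2)
        tissues = ["brain", "heart", "liver", "testes"]
        samples = [f"{t}_{i}" for t in tissues for i in range(2)]
        design = pd.Series([t for t in tissues for _ in range(2)], index=samples)
        r = 1 / 0.05
        dual = np.array([5000.0 if design[s] in ("testes", "heart") else 50.0 for s in samples])
        flat = np.full(len(samples), 50.0)
        rows = [rng.negative_binomial(r, r / (r + (dual if i < 3 else flat))) for i in range(30)]
        m = pd.DataFrame(rows, index=[f"f{i}" for i in range(30)], columns=samples)
        res = pairwise_enrichment(m, design, "testes")
        assert not res.loc[["f0", "f1", "f2"], "enriched"].any()
        # yet the comparisons against brain and liver do favour testes
        assert (res.loc[["f0", "f1", "f2"], "p_vs_brain"] < 0.05).all()
        assert (res.loc[["f0", "f1", "f2"], "p_vs_heart"] >= 0.05).all()

    def test_p_min_le_p_max(self):
        rng = np.random.default_rng(SEED + 3)
        m, design = _enrichment_matrix(rng, 25, {0}, fold=10.0)
        res = pairwise_enrichment(m, design, "testes")
        ok = res["tested"]
        assert (res.loc[ok, "p_min"] <= res.loc[ok, "p_max"]).all()

    def test_missing_target_group_rejected(self):
        rng = np.random.default_rng(SEED)
        m, design = _enrichment_matrix(rng, 5, set(), 1.0)
        with pytest.raises(ValueError):
            pairwise_enrichment(m, design, "spleen")

    def test_removing_a_group_never_loses_enriched_features(self):
        """Dropping one comparison group can only keep or gain calls."""
        rng = np.random.default_rng(SEED + 4)
        m, design = _enrichment_matrix(rng, 30, {0, 1, 2, 3}, fold=20.0)
        full = pairwise_enrichment(m, design, "testes")
        keep = design[design != "brain"]
        reduced = pairwise_enrichment(m[keep.index], keep, "testes")
        gained = set(full.index[full["enriched"]])
        assert gained <= set(reduced.index[reduced["enriched"]])

    def test_bh_adjustment_is_optional_and_off_by_default(self):
        rng = np.random.default_rng(SEED + 5)
        m, design = _enrichment_matrix(rng, 20, {0}, fold=50.0)
        raw = pairwise_enrichment(m, design, "testes")
        adj = pairwise_enrichment(m, design, "testes", adjust=True)
        assert not any(c.endswith("_adj") for c in raw.columns)
        adj_cols = [c for c in adj.columns if c.endswith("_adj")]
        assert adj_cols
        for c in adj_cols:
            base = c[: -len("_adj")]
            ok = adj[base].notna()
            assert (adj.loc[ok, c] >= adj.loc[ok, base] - 1e-12).all()


class TestExonUsage:
    def _design(self, n=3):
        idx = [f"sham_{i}" for i in range(n)] + [f"tac_{i}" for i in range(n)]
        return pd.Series(["sham"] * n + ["TAC"] * n, index=idx)

    def test_identical_proportions_not_significant(self):
        design = self._design()
        exon = pd.Series([30, 30, 30, 30, 30, 30], index=design.index)
        other = pd.Series([70, 70, 70, 70, 70, 70], index=design.index)
        res = exon_usage_test(exon, other, design)
        assert res.usage_change == 0.0
        assert res.p_usage == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        """0.33 -> 0.12 inclusion at depth 2000, 3 vs 3: p < 0.05 in >= 90%."""
        hits = 0
        for i in range(200):
            e, o, design = simulate_condition_usage(["x"], 0.33, 0.12, 2000, 3, seed=SEED + i)
            res = exon_usage_test(e.loc["x"], o.loc["x"], design)
            hits += res.p_usage < 0.05
        assert hits >= 180

    def test_usage_change_sign_and_magnitude(self):
        changes = []
        for i in range(100):
            e, o, design = simulate_condition_usage(["x"], 0.33, 0.12, 2000, 3, seed=SEED + i)
            changes.append(exon_usage_test(e.loc["x"], o.loc["x"], design).usage_change)
        assert abs(np.mean(changes) - (0.12 - 0.33)) < 0.05

    def test_all_zero_condition_flagged(self):
        design = self._design()
        exon = pd.Series([0, 0, 0, 5, 6, 7], index=design.index)
        other = pd.Series([0, 0, 0, 10, 10, 10], index=design.index)
        res = exon_usage_test(exon, other, design)
        assert np.isnan(res.p_usage)

    def test_three_conditions_rejected(self):
        design = pd.Series(["a", "b", "c"], index=["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            exon_usage_test(pd.Series([1, 2, 3]), pd.Series([4, 5, 6]), design)

    def test_agrees_with_permutation_reference(self):
        """Parametric p tracks a sample-relabelling permutation p (n = 10/group)."""
        rng = np.random.default_rng(SEED)
        n = 10
        design = pd.Series(
            ["sham"] * n + ["TAC"] * n,
            index=[f"s{i}" for i in range(2 * n)],
        )
        diffs = []
        for trial in range(20):
            incl_b = rng.uniform(0.2, 0.5)
            incl_a = np.clip(incl_b + rng.uniform(-0.08, 0.08), 0.05, 0.95)
            totals = rng.poisson(400, 2 * n)
            cond2 = np.array([False] * n + [True] * n)
            exon = np.array(
                [rng.binomial(t, incl_a if c else incl_b) for t, c in zip(totals, cond2)]
            )
            other = totals - exon
            res = exon_usage_test(pd.Series(exon, index=design.index),
                                  pd.Series(other, index=design.index), design)
            p_perm = permutation_usage_p(
                exon.astype(float), other.astype(float), cond2, 2000, rng
            )
            diffs.append(abs(res.p_usage - p_perm))
        # same decision scale: mean discrepancy small, none wildly off
        assert np.mean(diffs) < 0.05
        assert max(diffs) < 0.15


class TestGeneLevel:
    def _counts(self, rng, fold, depth=10_000, n=3, alpha=0.01, n_genes=50):
        """g0 carries the fold change; the rest are flat background.

        Gene-level dispersion 0.01 reflects summed counts over a whole
        gene, which average out much of the exon-level variability.
        """
        idx = [f"sham_{i}" for i in range(n)] + [f"tac_{i}" for i in range(n)]
        design = pd.Series(["sham"] * n + ["TAC"] * n, index=idx)
        r = 1 / alpha
        mu_de = np.array([depth * (fold if design[s] == "TAC" else 1.0) for s in idx])
        mu_flat = np.full(len(idx), depth)
        rows = [
            rng.negative_binomial(r, r / (r + (mu_de if i == 0 else mu_flat)))
            for i in range(n_genes)
        ]
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(n_genes)], columns=idx), design

    def test_no_change_fold_near_one(self):
        rng = np.random.default_rng(SEED)
        m, design = self._counts(rng, fold=1.0)
        _, fold = gene_level_test(m, design, "g0")
        assert 0.8 < fold < 1.25

    def test_planted_gene_fold_recovered(self):
        """0.64x change at depth 10^4 estimated within [0.55, 0.75] in >= 90%."""
        rng = np.random.default_rng(SEED + 1)
        ok = 0
        for _ in range(50):
            m, design = self._counts(rng, fold=0.64)
            p, fold = gene_level_test(m, design, "g0")
            ok += 0.55 <= fold <= 0.75
        assert ok >= 45

    def test_all_zero_gene(self):
        idx = ["a", "b", "c", "d"]
        design = pd.Series(["sham", "sham", "TAC", "TAC"], index=idx)
        m = pd.DataFrame([[0, 0, 0, 0], [10, 12, 9, 11]], index=["gz", "gref"], columns=idx)
        p, fold = gene_level_test(m, design, "gz")
        assert p == 1.0


def test_usage_stat_handles_degenerate_samples():
    """Samples with zero totals are dropped before testing."""
    exon = np.array([10.0, 0.0, 12.0, 3.0, 2.0, 4.0])
    other = np.array([20.0, 0.0, 25.0, 30.0, 28.0, 26.0])
    cond2 = np.array([False, False, False, True, True, True])
    t, diff, dof = _usage_stat(exon, other, cond2)
    assert np.isfinite(t) and dof == 3
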