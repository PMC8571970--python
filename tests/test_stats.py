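"""Aggregation, imputation, correlations, signal metrics, PGLS, RRPP
ANOVA, and group tests."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    oracle_kendall_tau_b,
    oracle_mann_whitney_u,
    oracle_permutation_t_p,
)
from toothkit.opcr import OPCRResult
from toothkit.phylo import TraitVector, random_ultrametric_tree, \
    simulate_traits
from toothkit.phylo import _parse_newick
from toothkit.stats import (
    ImputationRule,
    TaxonSummary,
    aggregate_taxon,
    blomberg_k,
    default_imputation_rules,
    group_tests,
    impute_replacement_rates,
    kendall_test,
    pagel_lambda_signal,
    pearson_test,
    permutation_t_test,
    pgls_fit,
    phylo_anova,
)


def _res(name, mps, value):
    return OPCRResult(trial_counts=[int(value)] * 8, opcr=float(value),
                      min_patch_size=mps, rotation_step_deg=5.625,
                      mesh_name=name)


@pytest.fixture
def metadata():
    return pd.DataFrame([
        {"mesh_name": f"m{i}", "taxon": t, "clade": c,
         "element": e, "replacement_rate_days": r}
        for i, (t, c, e, r) in enumerate([
            ("TaxA", "diplodocoid", "dentary", 35.0),
            ("TaxA", "diplodocoid", "dentary", 35.0),
            ("TaxA", "diplodocoid", "premaxilla_maxilla", 35.0),
            ("TaxB", "ornithischian", "dentary", None),
        ])
    ])


class TestAggregateTaxon:
    def test_unweighted_mean(self, metadata):
        per_tooth = [_res("m0", 3, 10), _res("m1", 3, 12), _res("m2", 3, 14),
                     _res("m0", 5, 8), _res("m1", 5, 9), _res("m2", 5, 10),
                     _res("m3", 3, 30), _res("m3", 5, 20)]
        out = aggregate_taxon(per_tooth, metadata)
        byname = {s.taxon: s for s in out}
        assert byname["TaxA"].opcr_avg_3 == 12.0
        assert byname["TaxA"].opcr_avg_5 == 9.0
        assert byname["TaxA"].n_teeth == 3
        assert byname["TaxB"].opcr_avg_3 == 30.0  # single tooth

    def test_element_split(self, metadata):
        per_tooth = [_res("m0", 3, 10), _res("m1", 3, 12), _res("m2", 3, 16),
                     _res("m0", 5, 8), _res("m1", 5, 10), _res("m2", 5, 12),
                     _res("m3", 3, 30), _res("m3", 5, 20)]
        out = aggregate_taxon(per_tooth, metadata, split_elements=True)
        byname = {s.taxon: s for s in out}
        assert byname["TaxA_dentary"].opcr_avg_3 == 11.0
        assert byname["TaxA_premaxilla_maxilla"].opcr_avg_3 == 16.0

    def test_missing_threshold_rejected(self, metadata):
        with pytest.raises(ValueError, match="both"):
            aggregate_taxon([_res("m0", 3, 10)], metadata)


class TestImputation:
    def _summary(self, taxon, clade, rate=None):
        return TaxonSummary(taxon=taxon, clade=clade, opcr_avg_3=12.0,
                            opcr_avg_5=9.0, replacement_rate_days=rate)

    def test_donor_mean(self):
        summaries = [self._summary("D1", "diplodocoid", 35.0),
                     self._summary("D2", "diplodocoid", 45.0),
                     self._summary("R", "diplodocoid")]
        out = impute_replacement_rates(
            summaries,
            {"R": ImputationRule("donor_mean", donors=("D1", "D2"))})
        target = {s.taxon: s for s in out}["R"]
        assert target.replacement_rate_days == 40.0
        assert target.rate_source == "imputed"

    def test_ornithischian_constant_default(self):
        summaries = [self._summary("O", "ornithischian")]
        out = impute_replacement_rates(
            summaries, default_imputation_rules(summaries))
        assert out[0].replacement_rate_days == 96.0

    def test_no_rule_left_missing(self, caplog):
        summaries = [self._summary("X", "theropod")]
        with caplog.at_level("WARNING", logger="toothkit.stats"):
            out = impute_replacement_rates(summaries, {})
        assert out[0].replacement_rate_days is None

    def test_summary_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            TaxonSummary(taxon="T", clade="theropod", opcr_avg_3=5.0,
                         opcr_avg_5=7.0)


class TestCorrelations:
    def test_pearson_perfect_lines(self):
        x = np.arange(1.0, 8)
        assert pearson_test(x, 2 * x + 1).estimate == pytest.approx(1.0)
        assert pearson_test(x, -x).estimate == pytest.approx(-1.0)

    def test_pearson_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        res = pearson_test(x, y)
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt(2 / (1 - r**2))
        from scipy.stats import t as tdist
        assert res.estimate == pytest.approx(r)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(2 * tdist.sf(abs(t), 2))

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_test([1.0, 1, 1, 1], [1.0, 2, 3, 4])

    def test_kendall_monotone_extremes(self):
        x = np.arange(6.0)
        assert kendall_test(x, x**3).estimate == pytest.approx(1.0)
        assert kendall_test(x, -x).estimate == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_kendall_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        x = rng.integers(0, 5, n).astype(float)  # ties likely
        y = rng.integers(0, 5, n).astype(float)
        if len(set(x)) == 1 or len(set(y)) == 1:
            return
        assert kendall_test(x, y).estimate \
            == pytest.approx(oracle_kendall_tau_b(x, y))

    def test_trait_vector_alignment(self):
        x = TraitVector(np.r_[1.0, 2, 3], ["a", "b", "c"])
        y = TraitVector(np.r_[30.0, 10, 20], ["c", "a", "b"])
        assert pearson_test(x, y).estimate == pytest.approx(1.0)


class TestPhylogeneticSignal:
    def test_blomberg_k_star_tree_finite(self):
        star = _parse_newick("(A:1,B:1,C:1,D:1,E:1);", "star")
        tv = TraitVector(np.r_[1.0, 3, 2, 5, 4], star.tip_labels)
        res = blomberg_k(star, tv, n_perm=99, seed=0)
        assert np.isfinite(res.estimate)
        assert 0 < res.p <= 1

    def test_blomberg_k_permuted_trait_weakens_signal(self):
        tree = random_ultrametric_tree(40, seed=3, total_depth=60)
        tv = simulate_traits(tree, "bm", 1.0, seed=10)
        k_true = blomberg_k(tree, tv, n_perm=199, seed=1)
        rng = np.random.default_rng(4)
        shuffled = TraitVector(rng.permutation(tv.values), tv.taxon_order)
        k_shuf = blomberg_k(tree, shuffled, n_perm=199, seed=1)
        assert k_shuf.estimate < k_true.estimate
        assert k_shuf.estimate < 1.0

    def test_lambda_null_recovery(self):
        tree = random_ultrametric_tree(40, seed=5, total_depth=60)
        tv = simulate_traits(tree, "lambda", 1.0, lam=0.0, seed=2)
        res = pagel_lambda_signal(tree, tv)
        assert res.estimate < 0.3

    def test_lambda_needs_enough_tips(self):
        two = _parse_newick("(A:1,B:1);", "two")
        with pytest.raises(ValueError):
            pagel_lambda_signal(two, TraitVector(np.r_[1.0, 2], ["A", "B"]))


class TestPGLS:
    def test_star_tree_equals_ols(self):
        star = _parse_newick("(" + ",".join(f"s{i}:1" for i in range(12))
                             + ");", "star")
        rng = np.random.default_rng(6)
        x = rng.normal(size=12)
        y = 1.5 - 0.4 * x + rng.normal(size=12)
        labels = star.tip_labels
        res = pgls_fit(star, TraitVector(y, labels), TraitVector(x, labels),
                       "bm")
        X = np.column_stack([np.ones(12), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)

    def test_constant_response_uninformative(self):
        tree = random_ultrametric_tree(10, seed=1)
        labels = tree.tip_labels
        y = TraitVector(np.full(10, 3.0), labels)
        x = TraitVector(np.arange(10.0), labels)
        res = pgls_fit(tree, y, x, "bm")
        assert res.slope == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("model", ["lambda", "ou"])
    def test_structure_parameter_estimated(self, model):
        tree = random_ultrametric_tree(30, seed=9, total_depth=50)
        x = simulate_traits(tree, "bm", 1.0, seed=11)
        noise = simulate_traits(tree, "bm", 0.3, seed=12)
        y = TraitVector(2.0 + 0.5 * x.values + noise.values, x.taxon_order)
        res = pgls_fit(tree, y, x, model)
        assert res.fitted_param is not None
        assert res.fitted_param >= 0
        assert res.slope == pytest.approx(0.5, abs=0.35)


class TestPhyloAnova:
    def test_singular_design_rejected(self):
        tree = random_ultrametric_tree(10, seed=2)
        y = simulate_traits(tree, "bm", 1.0, seed=1)
        # constant continuous predictor duplicates the intercept column
        with pytest.raises(np.linalg.LinAlgError):
            phylo_anova(tree, y, np.full(10, 2.5), iterations=99, seed=0)
        # a one-level factor leaves no effect to test
        with pytest.raises(ValueError):
            phylo_anova(tree, y, np.repeat(["only"], 10), iterations=99,
                        seed=0)

    def test_seeded_determinism(self):
        tree = random_ultrametric_tree(15, seed=4, total_depth=40)
        y = simulate_traits(tree, "bm", 1.0, seed=5)
        x = np.random.default_rng(3).normal(size=15)
        p1 = phylo_anova(tree, y, x, iterations=299, seed=7).p_perm
        p2 = phylo_anova(tree, y, x, iterations=299, seed=7).p_perm
        assert p1 == p2

    def test_strong_effect_detected(self):
        tree = random_ultrametric_tree(20, seed=6, total_depth=40)
        x = simulate_traits(tree, "bm", 1.0, seed=8)
        y = TraitVector(3.0 * x.values, x.taxon_order)
        res = phylo_anova(tree, y, x, iterations=499, seed=1)
        assert res.p_perm < 0.01


class TestGroupTests:
    def test_exact_enumeration_small_groups(self):
        res = permutation_t_test([1, 2, 3], [11, 12, 13], replicates=9999,
                                 seed=0)
        assert res["exact"]
        assert res["p"] == pytest.approx(
            oracle_permutation_t_p([1, 2, 3], [11, 12, 13]))
        assert res["p"] == pytest.approx(2 / 20)

    def test_identical_groups_maximal_p(self):
        rep = group_tests(np.tile([1.0, 2, 3, 4], 2),
                          np.repeat(["g1", "g2"], 4), replicates=999, seed=1)
        assert rep["pairwise"][("g1", "g2")]["perm_t"]["p"] == 1.0

    def test_small_group_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="toothkit.stats"):
            rep = group_tests([1.0, 2, 3, 4, 9],
                              ["a", "a", "b", "b", "c"],
                              replicates=99, seed=1)
        assert ("a", "b") in rep["pairwise"]
        assert ("a", "c") not in rep["pairwise"]

    def test_mann_whitney_matches_pair_count_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = rng.integers(0, 6, 7).astype(float)
            b = rng.integers(0, 6, 8).astype(float)
            import scipy.stats as sps
            u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
            assert u == pytest.approx(oracle_mann_whitney_u(a, b))

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(2, 1, 8),
                                 rng.normal(4, 1, 8)])
        groups = np.repeat(["a", "b", "c"], 8)
        rep = group_tests(values, groups, replicates=199, seed=5, holm=True)
        for pair, res in rep["pairwise"].items():
            assert res["perm_t_holm_p"] >= res["perm_t"]["p"] - 1e-12
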