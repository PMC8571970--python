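"""Tree I/O, calibration, covariance construction, and trait simulation."""

import numpy as np
import pytest

from _oracles import oracle_phylo_covariance
from toothkit.phylo import (
    PhyloCovariance,
    TraitVector,
    TreeError,
    calibrate_tips,
    lambda_max,
    load_fixture_tree,
    phylo_covariance,
    prune_to_common,
    random_ultrametric_tree,
    read_newick,
    simulate_traits,
    transform_covariance,
    write_newick,
)
from toothkit.phylo import _parse_newick


class TestNewickIO:
    def test_parse_depths(self):
        tree = _parse_newick("((A:1,B:1):1,C:2);", "t")
        assert tree.n_tips == 3
        assert set(tree.depths().values()) == {2.0}

    def test_round_trip(self, tmp_path):
        tree = load_fixture_tree()
        p = tmp_path / "tree.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert sorted(back.tip_labels) == sorted(tree.tip_labels)
        assert back.depths() == pytest.approx(tree.depths())

    def test_missing_branch_length_rejected(self):
        with pytest.raises(TreeError, match="branch length"):
            _parse_newick("((A:1,B),C:2);", "t")

    def test_fixture_tree_is_calibrated(self):
        tree = load_fixture_tree()
        assert tree.n_tips == 13
        assert tree.is_ultrametric()
        assert set(tree.depths().values()) == {83.0}  # 235 - 152 Ma


class TestCalibrateTips:
    def test_equal_ages_give_ultrametric(self):
        tree = _parse_newick("((A:1,B:2):1,C:5);", "t")
        out = calibrate_tips(tree, {"A": 152, "B": 152, "C": 152})
        assert out.is_ultrametric()

    def test_infeasible_age_names_tip(self):
        tree = _parse_newick("((A:1,B:1):1,C:2);", "t")
        with pytest.raises(TreeError, match="'B'"):
            calibrate_tips(tree, {"A": 0, "B": 100, "C": 0})

    def test_noop_when_already_satisfied(self):
        tree = _parse_newick("((A:1,B:1):1,C:2);", "t")
        out = calibrate_tips(tree, {"A": 10, "B": 10, "C": 10})
        assert out.depths() == pytest.approx(tree.depths())


class TestPhyloCovariance:
    def test_hand_example(self):
        C = phylo_covariance(_parse_newick("((A:1,B:1):1,C:2);", "t"))
        expect = {"A": {"A": 2, "B": 1, "C": 0},
                  "B": {"B": 2, "C": 0}, "C": {"C": 2}}
        for i, a in enumerate(C.taxon_order):
            for j, b in enumerate(C.taxon_order):
                key = (a, b) if a <= b else (b, a)
                assert C.matrix[i, j] == expect[key[0]][key[1]]

    def test_star_tree_zero_off_diagonals(self):
        C = phylo_covariance(_parse_newick("(A:3,B:3,C:3,D:3);", "t"))
        off = C.matrix - np.diag(C.matrix.diagonal())
        assert np.all(off == 0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_path_intersection_oracle(self, seed):
        tree = random_ultrametric_tree(8 + seed, seed=seed)
        C = phylo_covariance(tree)
        oracle_C, labels = oracle_phylo_covariance(tree)
        assert labels == C.taxon_order
        assert np.allclose(C.matrix, oracle_C, atol=1e-9)

    def test_psd_and_bounded_off_diagonals(self):
        C = phylo_covariance(load_fixture_tree()).matrix
        assert np.linalg.eigvalsh(C).min() > -1e-9
        diag = C.diagonal()
        assert np.all(C <= np.minimum.outer(diag, diag) + 1e-12)


class TestTransformCovariance:
    @pytest.fixture
    def C(self):
        return phylo_covariance(load_fixture_tree())

    def test_lambda_identity_and_star(self, C):
        assert np.array_equal(
            transform_covariance(C, "lambda", lam=1.0).matrix, C.matrix)
        diag_only = transform_covariance(C, "lambda", lam=0.0).matrix
        assert np.array_equal(diag_only, np.diag(C.matrix.diagonal()))

    def test_lambda_beyond_psd_rejected(self, C):
        lam_hi = lambda_max(C)
        with pytest.raises(ValueError, match="admissible"):
            transform_covariance(C, "lambda", lam=lam_hi * 1.5)

    def test_ou_limits(self, C):
        near_identity = transform_covariance(C, "ou", alpha=1e3).matrix
        assert np.allclose(near_identity, np.eye(len(C.taxon_order)))
        alpha0 = transform_covariance(C, "ou", alpha=0.0).matrix
        assert np.all(alpha0 == 1.0)  # no decay at alpha=0

    def test_ou_at_alpha_zero_and_lambda_one_recover_bm_structure(self, C):
        assert np.array_equal(
            transform_covariance(C, "bm").matrix, C.matrix)
        lam1 = transform_covariance(C, "lambda", lam=1.0)
        assert np.array_equal(lam1.matrix, C.matrix)


class TestSimulateTraits:
    def test_zero_variance_returns_root(self):
        tree = load_fixture_tree()
        tv = simulate_traits(tree, "bm", sigma2=0.0, root_value=7.5, seed=1)
        assert np.all(tv.values == 7.5)

    def test_seed_determinism(self):
        tree = load_fixture_tree()
        a = simulate_traits(tree, "ou", sigma2=2.0, alpha=0.05, seed=42)
        b = simulate_traits(tree, "ou", sigma2=2.0, alpha=0.05, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_bm_sample_covariance_close_to_target(self):
        tree = _parse_newick("((A:1,B:1):1,C:2);", "t")
        target = phylo_covariance(tree).matrix
        draws = np.array([
            simulate_traits(tree, "bm", sigma2=1.0, seed=s).values
            for s in range(3000)
        ])
        sample = np.cov(draws.T)
        se = 3 * np.sqrt(2.0 / 3000) * np.abs(target).max()
        assert np.all(np.abs(sample - target) < np.maximum(se, 0.2))


class TestPruneToCommon:
    def test_alignment_and_drop_report(self):
        tree = load_fixture_tree()
        tv = TraitVector(np.arange(5, dtype=float),
                         ["Diplodocus", "Apatosaurus", "Camarasaurus",
                          "Brachiosaurus", "Imaginary"], units="PPT")
        pruned, aligned, dropped = prune_to_common(tree, tv)
        assert sorted(pruned.tip_labels) == sorted(
            ["Diplodocus", "Apatosaurus", "Camarasaurus", "Brachiosaurus"])
        assert aligned.taxon_order == pruned.tip_labels
        assert dropped["data"] == ["Imaginary"]
        assert len(dropped["tree"]) == 9

    def test_order_independence(self):
        tree = load_fixture_tree()
        labels = ["Diplodocus", "Camarasaurus", "Tornieria"]
        a = prune_to_common(tree, TraitVector(np.r_[1., 2, 3], labels))[1]
        b = prune_to_common(
            tree, TraitVector(np.r_[3., 2, 1], labels[::-1]))[1]
        assert np.array_equal(a.values, b.values)

    def test_disjoint_sets_error(self):
        tree = load_fixture_tree()
        with pytest.raises(TreeError, match="no taxa"):
            prune_to_common(tree, TraitVector(np.r_[1.0], ["Nobody"]))
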