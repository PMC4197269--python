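"""Correlation-distance Ward clustering, bootstrap support, expression prep."""

import numpy as np
import pandas as pd
import pytest

from methpanel.clustering import (
    ExpressionMatrix,
    bootstrap_support,
    correlation_distance,
    detection_filter,
    quantile_normalize,
    ward_cluster,
)
from oracles import naive_ward, pearson


def profiles_from(rng, n_samples, n_features):
    return pd.DataFrame(
        rng.random((n_samples, n_features)),
        index=[f"s{i}" for i in range(n_samples)],
    )


class TestCorrelationDistance:
    def test_identical_and_affine_profiles_have_zero_distance(self):
        base = np.array([0.1, 0.5, 0.9, 0.3])
        profs = pd.DataFrame(
            [base, base, 2.0 * base + 0.5], index=["a", "b", "c"]
        )
        d = correlation_distance(profs)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)
        assert (np.diag(d) == 0).all()

    def test_matches_featurewise_pearson(self):
        rng = np.random.default_rng(0)
        profs = profiles_from(rng, 3, 40)
        d = correlation_distance(profs)
        for i in range(3):
            for j in range(3):
                expected = 1 - pearson(profs.iloc[i], profs.iloc[j])
                assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_sample_error_names_sample(self):
        profs = pd.DataFrame([[1, 1, 1], [0.2, 0.5, 0.9]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlation_distance(profs)

    def test_missing_values_rejected(self):
        profs = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            correlation_distance(profs)


class TestWard:
    def test_two_leaves_merge_at_their_distance(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        tree = ward_cluster(d)
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(0.4)

    def test_well_separated_groups_split_at_root(self):
        rng = np.random.default_rng(1)
        pattern_l = rng.random(50)
        pattern_r = rng.random(50)
        left = pattern_l + rng.normal(0, 0.02, (3, 50))
        right = pattern_r + rng.normal(0, 0.02, (3, 50))
        profs = pd.DataFrame(np.vstack([left, right]),
                             index=[f"L{i}" for i in range(3)] + [f"R{i}" for i in range(3)])
        tree = ward_cluster(correlation_distance(profs))
        clades = tree.clades()
        assert {frozenset(f"L{i}" for i in range(3)), frozenset(f"R{i}" for i in range(3))} <= set(clades)

    @pytest.mark.parametrize("trial", range(5))
    def test_agrees_with_naive_lance_williams(self, trial):
        rng = np.random.default_rng(10 + trial)
        profs = profiles_from(rng, 7, 25)
        d = correlation_distance(profs)
        tree = ward_cluster(d)
        oracle_clades, oracle_heights = naive_ward(d.to_numpy())
        got = [frozenset(int(lab[1:]) for lab in c) for c in tree.clades()]
        # same merge set; heights compared per clade (merge order may permute ties)
        assert set(got) == {frozenset(c) for c in oracle_clades}
        heights = dict(zip(got, tree.linkage[:, 2]))
        for clade, h in zip(oracle_clades, oracle_heights):
            assert heights[frozenset(clade)] == pytest.approx(h, rel=1e-9)

    def test_sample_permutation_only_relabels(self):
        rng = np.random.default_rng(5)
        profs = profiles_from(rng, 6, 30)
        perm = [3, 1, 5, 0, 2, 4]
        t1 = ward_cluster(correlation_distance(profs))
        t2 = ward_cluster(correlation_distance(profs.iloc[perm]))
        assert set(t1.clades()) == set(t2.clades())

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(6)
        tree = ward_cluster(correlation_distance(profiles_from(rng, 8, 20)))
        h = tree.linkage[:, 2]
        assert (h >= 0).all() and (np.diff(h) >= -1e-12).all()

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 0.5], [0.2, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            ward_cluster(d)


class TestBootstrap:
    def test_single_bootstrap_gives_binary_supports(self):
        rng = np.random.default_rng(2)
        tree = bootstrap_support(profiles_from(rng, 5, 20), n_boot=1, seed=0)
        assert set(tree.support.values()) <= {0.0, 1.0}
        with pytest.raises(ValueError):
            bootstrap_support(profiles_from(rng, 5, 20), n_boot=0, seed=0)

    def test_root_always_supported(self):
        rng = np.random.default_rng(3)
        tree = bootstrap_support(profiles_from(rng, 5, 30), n_boot=25, seed=0)
        assert tree.support[frozenset(tree.labels)] == 1.0
        assert all(0.0 <= v <= 1.0 for v in tree.support.values())

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        profs = profiles_from(rng, 6, 40)
        t1 = bootstrap_support(profs, n_boot=30, seed=11)
        t2 = bootstrap_support(profs, n_boot=30, seed=11)
        assert t1.support == t2.support

    def test_planted_pair_strongly_supported_noise_pairs_not(self):
        rng = np.random.default_rng(7)
        n_feat = 400
        profs = pd.DataFrame(rng.normal(0.5, 0.05, (10, n_feat)),
                             index=[f"s{i}" for i in range(10)])
        shifted = rng.random(n_feat) < 0.05  # effect 0.4 on 5% of features
        profs.iloc[0, shifted.nonzero()[0]] -= 0.4
        profs.iloc[1, shifted.nonzero()[0]] -= 0.4
        tree = bootstrap_support(profs, n_boot=100, seed=0)
        assert tree.support[frozenset(["s0", "s1"])] >= 0.95
        noise_supports = [
            v for k, v in tree.support.items()
            if 1 < len(k) < 10 and k != frozenset(["s0", "s1"])
        ]
        assert np.mean(noise_supports) < 0.95

    def test_newick_export_contains_supports_and_leaves(self):
        rng = np.random.default_rng(8)
        tree = bootstrap_support(profiles_from(rng, 4, 25), n_boot=10, seed=0)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for lab in tree.labels:
            assert lab in nwk


class TestExpressionPrep:
    def _expr(self, values, pvals):
        genes = [f"g{i}" for i in range(len(values))]
        cols = [f"s{j}" for j in range(len(values[0]))]
        return ExpressionMatrix(
            values=pd.DataFrame(values, index=genes, columns=cols),
            detection_p=pd.DataFrame(pvals, index=genes, columns=cols),
        )

    def test_detection_threshold_is_inclusive(self):
        expr = self._expr([[5.0, 6.0], [5.0, 6.0]], [[0.05, 0.01], [0.06, 0.01]])
        kept = detection_filter(expr, alpha=0.05)
        assert kept.genes == ["g0"]

    def test_detection_filter_matches_row_scan(self):
        rng = np.random.default_rng(9)
        vals = rng.random((50, 6)) + 0.1
        pvals = rng.random((50, 6)) * 0.12
        expr = self._expr(vals.tolist(), pvals.tolist())
        kept = detection_filter(expr, alpha=0.05)
        expected = [f"g{i}" for i in range(50) if all(p <= 0.05 for p in pvals[i])]
        assert kept.genes == expected

    def test_detection_filter_alpha_validation(self):
        expr = self._expr([[1.0]], [[0.01]])
        for alpha in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                detection_filter(expr, alpha=alpha)

    def test_quantile_normalize_hand_example(self):
        expr = ExpressionMatrix(values=pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]}))
        out = quantile_normalize(expr).values
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [1.5, 3.5]

    def test_quantile_normalize_equalizes_distributions(self):
        rng = np.random.default_rng(10)
        expr = ExpressionMatrix(
            values=pd.DataFrame(rng.gamma(2, 2, (40, 5)) + 0.01,
                                index=[f"g{i}" for i in range(40)])
        )
        out = quantile_normalize(expr).values
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 5):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)
        # within-column order preserved
        for j in range(5):
            assert (np.argsort(out.iloc[:, j].to_numpy(), kind="stable")
                    == np.argsort(expr.values.iloc[:, j].to_numpy(), kind="stable")).all()

    def test_identical_distributions_are_fixed_point(self):
        col = np.array([0.5, 1.5, 4.0, 9.0])
        expr = ExpressionMatrix(values=pd.DataFrame({"a": col, "b": col[::-1].copy()}))
        out = quantile_normalize(expr).values
        np.testing.assert_allclose(np.sort(out["a"]), col)
        np.testing.assert_allclose(out["b"].to_numpy(), col[::-1])
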