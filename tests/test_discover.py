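import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

import methclass as mc
from methclass import discover

from .oracles import beta_moments


def _two_block_matrix(rng, n_per_block=6, n_cpgs=40, noise=0.02):
    """Samples drawn around two anti-correlated profiles."""
    profile = rng.random(n_cpgs)
    blocks = []
    cols = []
    for b, base in enumerate([profile, 1 - profile]):
        for i in range(n_per_block):
            blocks.append(np.clip(base + rng.normal(0, noise, n_cpgs), 0, 1))
            cols.append(f"b{b}_{i:02d}")
    return pd.DataFrame(
        np.array(blocks).T, index=[f"cg{j}" for j in range(n_cpgs)], columns=cols
    )


class TestHclust:
    def test_identical_samples_merge_at_zero(self, rng):
        x = rng.random(20)
        m = pd.DataFrame({"a": x, "b": x, "c": rng.random(20)})
        dend = mc.correlation_distance_hclust(m)
        assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert dend.node_sets()[0] == frozenset({"a", "b"})

    def test_top_split_separates_planted_blocks(self, rng):
        m = _two_block_matrix(rng)
        dend = mc.correlation_distance_hclust(m)
        top_children = dend.node_sets()[-2]
        block0 = frozenset(c for c in m.columns if c.startswith("b0"))
        block1 = frozenset(c for c in m.columns if c.startswith("b1"))
        assert top_children in (block0, block1)

    def test_topology_invariant_to_sample_order(self, rng):
        m = _two_block_matrix(rng)
        shuffled = m[rng.permutation(m.columns)]
        a = set(mc.correlation_distance_hclust(m).node_sets())
        b = set(mc.correlation_distance_hclust(shuffled).node_sets())
        assert a == b

    def test_zero_variance_sample_rejected(self, rng):
        m = pd.DataFrame({"a": rng.random(10), "flat": np.full(10, 0.5)})
        with pytest.raises(ValueError, match="flat"):
            mc.correlation_distance_hclust(m)

    def test_newick_contains_all_leaves(self, rng):
        m = _two_block_matrix(rng, n_per_block=3)
        nwk = mc.correlation_distance_hclust(m).to_newick()
        assert all(c in nwk for c in m.columns)
        assert nwk.endswith(";")


class TestBootstrapSupport:
    def test_planted_blocks_have_high_support(self, rng):
        m = _two_block_matrix(rng, n_per_block=6, n_cpgs=60)
        dend, support = mc.bootstrap_support(m, B=100, seed=2)
        block0 = tuple(sorted(c for c in m.columns if c.startswith("b0")))
        block1 = tuple(sorted(c for c in m.columns if c.startswith("b1")))
        bp = support.set_index("samples")["bp"]
        assert bp[block0] >= 0.99
        assert bp[block1] >= 0.99

    def test_pure_noise_has_weak_deep_nodes(self, rng):
        m = pd.DataFrame(
            rng.random((60, 14)), columns=[f"s{i:02d}" for i in range(14)]
        )
        _, support = mc.bootstrap_support(m, B=100, seed=3)
        deep = support[(support["size"] > 2) & (support["size"] < 14)]
        assert deep["bp"].mean() < 0.5

    def test_deterministic_under_seed(self, rng):
        m = _two_block_matrix(rng, n_per_block=4)
        _, a = mc.bootstrap_support(m, B=30, seed=5)
        _, b = mc.bootstrap_support(m, B=30, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_au_values_strengthen_supported_nodes(self, rng):
        m = _two_block_matrix(rng, n_per_block=5, n_cpgs=50)
        _, support = mc.bootstrap_support(m, B=50, seed=7, compute_au=True)
        assert support["au"].between(0, 1).all()
        block0 = tuple(sorted(c for c in m.columns if c.startswith("b0")))
        au0 = support.loc[support["samples"] == block0, "au"].iloc[0]
        assert au0 > 0.9

    def test_invalid_b_rejected(self, rng):
        with pytest.raises(ValueError):
            mc.bootstrap_support(_two_block_matrix(rng), B=0)


class TestBetaMixtureEM:
    def test_parameter_recovery_from_known_shapes(self):
        rng = np.random.default_rng(10)
        draws = rng.beta(2, 10, size=(200, 1))
        fit = mc.fit_beta_mixture(draws, k=1)
        a, b = fit.a[0, 0], fit.b[0, 0]
        assert abs(a - 2) / 2 < 0.25
        assert abs(b - 10) / 10 < 0.25

    def test_identical_samples_finite_loglik(self):
        draws = np.full((10, 5), 0.42)
        fit = mc.fit_beta_mixture(draws, k=1)
        assert np.isfinite(fit.log_likelihood)
        assert (fit.a > 0).all() and (fit.b > 0).all()

    def test_two_component_separation(self):
        rng = np.random.default_rng(11)
        lo = rng.beta(2, 18, size=(25, 30))
        hi = rng.beta(18, 2, size=(25, 30))
        X = np.vstack([lo, hi])
        fit = mc.fit_beta_mixture(X, k=2)
        assign = np.argmax(fit.resp, axis=1)
        accuracy = max(
            (assign[:25] == 0).mean() / 2 + (assign[25:] == 1).mean() / 2,
            (assign[:25] == 1).mean() / 2 + (assign[25:] == 0).mean() / 2,
        )
        assert accuracy >= 0.95

    def test_loglikelihood_monotone_nondecreasing(self):
        rng = np.random.default_rng(12)
        X = np.vstack(
            [rng.beta(2, 8, size=(15, 20)), rng.beta(6, 3, size=(15, 20))]
        )
        fit = mc.fit_beta_mixture(X, k=2, tol=1e-8)
        diffs = np.diff(fit.history)
        assert (diffs >= -1e-8).all()

    def test_moment_match_against_closed_form(self):
        # the M-step inverts the closed-form beta moments exactly
        for a, b in [(2.0, 18.0), (2.0, 2.0), (5.0, 1.5)]:
            mean, var = beta_moments(a, b)
            common = mean * (1 - mean) / var - 1
            assert mean * common == pytest.approx(a)
            assert (1 - mean) * common == pytest.approx(b)

    def test_bic_parameter_count(self):
        rng = np.random.default_rng(13)
        X = rng.beta(2, 2, size=(20, 7))
        f1 = mc.fit_beta_mixture(X, k=1)
        f2 = mc.fit_beta_mixture(X, k=2)
        assert f1.n_params() == 14
        assert f2.n_params() == 29
        n = 20
        assert f1.bic(n) == pytest.approx(
            -2 * f1.log_likelihood + 14 * np.log(n)
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mc.fit_beta_mixture(np.array([[0.5, 0.5]]), k=1)


class TestRecursivePartition:
    def test_null_data_single_leaf(self):
        cfg = mc.SimConfig(
            n_cpgs=120, n_differential=0, n_tumors_per_subtype=10, n_normals=0, seed=14
        )
        ds = mc.simulate_dataset(cfg, with_expression=False)
        tree = mc.recursive_partition(ds.beta)
        assert tree.n_leaves == 1

    def test_min_node_constraint_forces_single_leaf(self, rng):
        m = _two_block_matrix(rng, n_per_block=5, n_cpgs=30)
        tree = mc.recursive_partition(m, min_node=6)
        assert tree.n_leaves == 1

    def test_four_planted_classes_recovered(self, train_test):
        train, test = train_test
        cpgs = list(train.truth.index[train.truth["is_differential"]])
        sheet = test.samples
        tumors = sheet.index[sheet["group"] != "Normal"]
        tree = mc.recursive_partition(test.beta.loc[cpgs, tumors])
        assert tree.n_leaves == 4
        labels = tree.labels().reindex(tumors)
        ct = pd.crosstab(sheet.loc[tumors, "group"], labels).to_numpy()
        r, c = linear_sum_assignment(-ct)
        agreement = ct[r, c].sum() / ct.sum()
        assert agreement >= 0.85

    def test_leaves_partition_samples(self, train_test):
        train, test = train_test
        cpgs = list(train.truth.index[train.truth["is_differential"]])
        tree = mc.recursive_partition(test.beta.loc[cpgs])
        all_ids = [s for leaf in tree.leaves() for s in leaf.sample_ids]
        assert sorted(all_ids) == sorted(test.beta.columns)

    def test_invariant_to_cpg_order(self, rng):
        m = _two_block_matrix(rng, n_per_block=6, n_cpgs=30)
        shuffled = m.iloc[rng.permutation(len(m))]
        a = mc.recursive_partition(m).labels()
        b = mc.recursive_partition(shuffled).labels()
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_estimator_interface(self, rng):
        m = _two_block_matrix(rng, n_per_block=6, n_cpgs=30)
        est = mc.RecursiveBetaMixture(min_node=4).fit(m.T)
        assert est.n_leaves_ == 2
        assert len(est.labels_) == m.shape[1]
        assert set(est.labels_) == {0, 1}


class TestEnrichment:
    def test_percent_rounding(self):
        assert discover.enrichment_percent(51, 52) == 98
        assert discover.enrichment_percent(24, 29) == 83
        assert discover.enrichment_percent(1, 2) == 50

    def test_cluster_enrichment_table(self):
        clusters = pd.Series({"a": 1, "b": 1, "c": 2, "d": 2})
        er = pd.Series({"a": "pos", "b": "pos", "c": "neg", "d": "pos"})
        table = discover.cluster_enrichment(clusters, er)
        row = table[(table["cluster"] == 1) & (table["level"] == "pos")].iloc[0]
        assert row["count"] == 2 and row["percent"] == 100
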