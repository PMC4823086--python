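import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import methclass as mc
from methclass import integrate as mi

from .oracles import spearman_oracle


def _annot(genes, distances=None):
    n = len(genes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "tss_distance": distances if distances is not None else [0] * n,
        },
        index=pd.Index([f"cg{i}" for i in range(n)], name="cpg_id"),
    )


def _probes(pairs):
    return pd.DataFrame(
        {"gene_id": [g for _, g in pairs]},
        index=pd.Index([p for p, _ in pairs], name="probe_id"),
    )


class TestGeneMap:
    def test_single_gene_single_pair(self, rng):
        expr = pd.DataFrame(rng.random((1, 4)), index=["p1"])
        annot, probes = _annot(["g1"]), _probes([("p1", "g1")])
        for mode in ("maximum", "most_variant"):
            gmap = mc.build_gene_map(annot, probes, expr, mode)
            assert len(gmap) == 1
            assert gmap.iloc[0].tolist() == ["cg0", "p1", "g1"]

    def test_most_variant_keeps_highest_variance_probe(self):
        expr = pd.DataFrame(
            [[1, 1.5, 2, 2.5], [0, 2, 4, 6]], index=["p1", "p2"], dtype=float
        )
        gmap = mc.build_gene_map(
            _annot(["g1"]), _probes([("p1", "g1"), ("p2", "g1")]), expr, "most_variant"
        )
        assert gmap["probe_id"].tolist() == ["p2"]

    def test_maximum_keeps_all_pairs(self, rng):
        expr = pd.DataFrame(rng.random((2, 4)), index=["p1", "p2"])
        gmap = mc.build_gene_map(
            _annot(["g1"]), _probes([("p1", "g1"), ("p2", "g1")]), expr, "maximum"
        )
        assert len(gmap) == 2

    def test_empty_intersection_rejected(self, rng):
        expr = pd.DataFrame(rng.random((1, 4)), index=["p1"])
        with pytest.raises(ValueError):
            mc.build_gene_map(_annot(["gA"]), _probes([("p1", "gB")]), expr)


class TestCorrelate:
    def test_perfect_anticorrelation(self, rng):
        beta = pd.DataFrame(
            rng.random((3, 6)), index=["cg0", "cg1", "cg2"],
            columns=[f"s{i}" for i in range(6)],
        )
        expr = (1 - beta).set_axis(["p0", "p1", "p2"], axis=0)
        gmap = pd.DataFrame(
            {"cpg_id": beta.index, "probe_id": expr.index, "gene_id": ["g"] * 3}
        )
        rec, summary = mc.correlate(beta, expr, gmap)
        assert (rec["rho"] == -1).all()
        assert summary["fraction_negative"] == 1.0

    def test_hand_worked_rank_example(self):
        beta = pd.DataFrame([[0.1, 0.4, 0.9]], index=["cg0"], columns=list("abc"))
        expr = pd.DataFrame([[5, 3, 1]], index=["p0"], columns=list("abc"), dtype=float)
        gmap = pd.DataFrame({"cpg_id": ["cg0"], "probe_id": ["p0"], "gene_id": ["g"]})
        rec, _ = mc.correlate(beta, expr, gmap)
        assert rec["rho"].iloc[0] == pytest.approx(-1.0)
        assert rec["rho"].iloc[0] == pytest.approx(
            spearman_oracle([0.1, 0.4, 0.9], [5, 3, 1])
        )

    def test_monotone_transform_invariance(self, rng):
        beta = pd.DataFrame(rng.random((5, 10)), columns=[f"s{i}" for i in range(10)])
        beta.index = [f"cg{i}" for i in range(5)]
        expr = pd.DataFrame(
            rng.random((5, 10)) * 4 + 4, index=[f"p{i}" for i in range(5)],
            columns=beta.columns,
        )
        gmap = pd.DataFrame(
            {"cpg_id": beta.index, "probe_id": expr.index, "gene_id": list("abcde")}
        )
        a, _ = mc.correlate(beta, expr, gmap)
        b, _ = mc.correlate(beta, 2**expr, gmap)
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-12)

    def test_null_pairs_have_near_zero_mean(self, rng):
        n_pairs, n = 1000, 50
        beta = pd.DataFrame(
            rng.random((n_pairs, n)), index=[f"cg{i}" for i in range(n_pairs)],
            columns=[f"s{i}" for i in range(n)],
        )
        expr = pd.DataFrame(
            rng.normal(8, 2, size=(n_pairs, n)),
            index=[f"p{i}" for i in range(n_pairs)], columns=beta.columns,
        )
        gmap = pd.DataFrame(
            {"cpg_id": beta.index, "probe_id": expr.index,
             "gene_id": [f"g{i}" for i in range(n_pairs)]}
        )
        _, summary = mc.correlate(beta, expr, gmap)
        assert abs(summary["mean"]) < 0.05

    def test_too_few_samples_rejected(self, rng):
        beta = pd.DataFrame([[0.5, 0.6]], index=["cg0"], columns=["a", "b"])
        expr = pd.DataFrame([[1.0, 2.0]], index=["p0"], columns=["a", "b"])
        gmap = pd.DataFrame({"cpg_id": ["cg0"], "probe_id": ["p0"], "gene_id": ["g"]})
        with pytest.raises(ValueError):
            mc.correlate(beta, expr, gmap)


class TestTssWindow:
    def test_hand_counted_fraction(self):
        annot = _annot(list("abcde"), [-600, -100, 0, 250, 900])
        assert mc.tss_window_fraction(annot, 500) == pytest.approx(3 / 5)

    def test_full_cover_and_zero_width(self):
        annot = _annot(list("abc"), [-200, 0, 100])
        assert mc.tss_window_fraction(annot, 200) == 1.0
        assert mc.tss_window_fraction(annot, 0) == pytest.approx(1 / 3)

    def test_negative_half_width_rejected(self):
        with pytest.raises(ValueError):
            mc.tss_window_fraction(_annot(["a"]), -1)

    @given(st.lists(st.integers(-3000, 3000), min_size=1, max_size=30))
    def test_monotone_in_half_width(self, distances):
        annot = _annot([f"g{i}" for i in range(len(distances))], distances)
        fracs = [mc.tss_window_fraction(annot, w) for w in (0, 100, 500, 3000)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestTssProfile:
    def test_promoter_low_distal_high(self):
        distances = [-100, 0, 100, 1500, 2000, -1800]
        beta = pd.DataFrame(
            [[0.05], [0.1], [0.08], [0.9], [0.85], [0.92]],
            index=[f"cg{i}" for i in range(6)], columns=["s1"],
        )
        profile = mc.tss_methylation_profile(
            beta, _annot([f"g{i}" for i in range(6)], distances), bin_width=200
        )
        near = profile[(profile["bin_center"].abs() <= 500) & (profile["count"] > 0)]
        far = profile[(profile["bin_center"].abs() > 1000) & (profile["count"] > 0)]
        assert near["mean_beta"].mean() < far["mean_beta"].mean()

    def test_single_cpg_single_bin(self):
        beta = pd.DataFrame([[0.3, 0.5]], index=["cg0"], columns=["a", "b"])
        profile = mc.tss_methylation_profile(beta, _annot(["g"], [50]))
        filled = profile[profile["count"] > 0]
        assert len(filled) == 1
        assert filled["mean_beta"].iloc[0] == pytest.approx(0.4)

    def test_constant_beta_flat_profile(self, rng):
        n = 30
        beta = pd.DataFrame(
            np.full((n, 3), 0.6), index=[f"cg{i}" for i in range(n)],
            columns=list("abc"),
        )
        annot = _annot(
            [f"g{i}" for i in range(n)], list(rng.integers(-2000, 2000, n))
        )
        profile = mc.tss_methylation_profile(beta, annot)
        filled = profile[profile["count"] > 0]
        assert np.allclose(filled["mean_beta"], 0.6)

    def test_bad_bin_width_rejected(self):
        beta = pd.DataFrame([[0.5]], index=["cg0"], columns=["a"])
        with pytest.raises(ValueError):
            mc.tss_methylation_profile(beta, _annot(["g"]), bin_width=0)


class TestExpressionTiers:
    def _simple_inputs(self, gene_means):
        n = len(gene_means)
        genes = [f"g{i}" for i in range(n)]
        beta = pd.DataFrame(
            np.full((n, 4), 0.5), index=[f"cg{i}" for i in range(n)],
            columns=list("abcd"),
        )
        expr = pd.DataFrame(
            np.tile(np.asarray(gene_means, dtype=float)[:, None], 4),
            index=[f"p{i}" for i in range(n)], columns=list("abcd"),
        )
        gmap = pd.DataFrame(
            {"cpg_id": beta.index, "probe_id": expr.index, "gene_id": genes}
        )
        return beta, expr, gmap

    def test_quartile_boundaries(self):
        beta, expr, gmap = self._simple_inputs([1, 2, 3, 4])
        tiers, summary, meta = mc.expression_tier_summary(beta, expr, gmap)
        assert tiers.value_counts().to_dict() == {"medium": 2, "low": 1, "high": 1}
        assert meta["q1"] == pytest.approx(1.75)
        assert meta["q3"] == pytest.approx(3.25)

    def test_constant_expression_all_medium(self):
        beta, expr, gmap = self._simple_inputs([2, 2, 2, 2])
        with pytest.warns(UserWarning, match="medium"):
            tiers, _, _ = mc.expression_tier_summary(beta, expr, gmap)
        assert (tiers == "medium").all()

    def test_too_few_genes_rejected(self):
        beta, expr, gmap = self._simple_inputs([1, 2, 3])
        with pytest.raises(ValueError):
            mc.expression_tier_summary(beta, expr, gmap)

    def test_anticorrelated_data_orders_tiers(self, small_dataset):
        ds = small_dataset
        gmap = mc.build_gene_map(
            ds.cpg_annotation, ds.probe_annotation, ds.expression, "most_variant"
        )
        _, summary, _ = mc.expression_tier_summary(ds.beta, ds.expression, gmap)
        assert (
            summary.loc["low", "mean_beta"]
            > summary.loc["medium", "mean_beta"]
            > summary.loc["high", "mean_beta"]
        )
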