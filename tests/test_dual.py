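import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from triomethyl import dual
from triomethyl.io import TrioDesign


class TestGroupDesign:
    def test_from_trios_pools_affecteds(self):
        trios = [
            TrioDesign("t1", "c1", "pa1", "pu1"),
            TrioDesign("t2", "c2", "pa2", "pu2"),
        ]
        design = dual.GroupDesign.from_trios(trios)
        assert design.affected == ("c1", "pa1", "c2", "pa2")
        assert design.unaffected == ("pu1", "pu2")

    def test_empty_or_overlapping_pools_rejected(self):
        with pytest.raises(ValueError):
            dual.GroupDesign((), ("a",))
        with pytest.raises(ValueError):
            dual.GroupDesign(("a",), ("a", "b"))


class TestRescaleBeta:
    @pytest.mark.parametrize(
        "x,y", [(0.0, -1.0), (0.5, 0.0), (1.0, 1.0), (0.75, 0.5), (0.25, -0.5)]
    )
    def test_anchor_points(self, x, y):
        assert dual.rescale_beta(x) == pytest.approx(y, abs=1e-12)

    @given(x=st.floats(0.0, 1.0))
    def test_equals_affine_map(self, x):
        assert dual.rescale_beta(x) == pytest.approx(2 * x - 1, abs=1e-12)

    def test_pieces_agree_at_junction(self):
        assert dual._LOWER.apply(0.5) == dual._UPPER.apply(0.5) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dual.rescale_beta(1.1)

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            dual.RescaleSpec(1.0, 0.0, 0.0, 1.0)


def _island_ann(probes, genes_per_probe, relations):
    return pd.DataFrame(
        {
            "chromosome": "1",
            "genes": [tuple(g) for g in genes_per_probe],
            "region_groups": [tuple("Body" for _ in g) for g in genes_per_probe],
            "island_relation": relations,
        },
        index=pd.Index(probes, name="probe_id"),
    )


class TestGeneGroupMeans:
    def setup_method(self):
        self.design = dual.GroupDesign(("a1", "a2"), ("u1", "u2"))

    def test_simple_mean(self):
        bm = pd.DataFrame(
            [[0.2, 0.4, 0.6, 0.8]], index=["p1"], columns=["a1", "a2", "u1", "u2"]
        )
        ann = _island_ann(["p1"], [["G1"]], ["Island"])
        means = dual.gene_group_means(bm, ann, self.design)
        assert means.at["G1", "mean_affected"] == pytest.approx(0.3)
        assert means.at["G1", "mean_unaffected"] == pytest.approx(0.7)
        assert means.at["G1", "n_probes"] == 1

    def test_non_island_probes_excluded(self):
        bm = pd.DataFrame(
            [[0.2, 0.4, 0.6, 0.8], [0.9, 0.9, 0.9, 0.9]],
            index=["p1", "p2"],
            columns=["a1", "a2", "u1", "u2"],
        )
        ann = _island_ann(["p1", "p2"], [["G1"], ["G2"]], ["Island", "N_Shore"])
        means = dual.gene_group_means(bm, ann, self.design)
        assert list(means.index) == ["G1"]

    def test_identical_groups_give_equal_means(self):
        vals = np.random.default_rng(0).uniform(size=(4, 2))
        bm = pd.DataFrame(
            np.hstack([vals, vals]),
            index=[f"p{i}" for i in range(4)],
            columns=["a1", "a2", "u1", "u2"],
        )
        ann = _island_ann(bm.index, [["G1"]] * 4, ["Island"] * 4)
        means = dual.gene_group_means(bm, ann, self.design)
        assert means.at["G1", "mean_affected"] == pytest.approx(
            means.at["G1", "mean_unaffected"]
        )

    def test_invariant_to_probe_and_sample_order(self):
        rng = np.random.default_rng(1)
        bm = pd.DataFrame(
            rng.uniform(size=(5, 4)),
            index=[f"p{i}" for i in range(5)],
            columns=["a1", "a2", "u1", "u2"],
        )
        ann = _island_ann(
            bm.index, [["G1"], ["G2"], ["G1", "G2"], ["G1"], ["G2"]], ["Island"] * 5
        )
        base = dual.gene_group_means(bm, ann, self.design)
        shuffled = dual.gene_group_means(
            bm.iloc[::-1, ::-1], ann, self.design
        )
        pd.testing.assert_frame_equal(base, shuffled)


class TestDualColorTable:
    def _means(self, rows):
        return pd.DataFrame(
            rows, columns=["mean_affected", "mean_unaffected", "n_probes"]
        ).set_axis(pd.Index([f"G{i}" for i in range(len(rows))], name="gene"))

    def test_dual_flag_set_when_scaled_means_differ(self):
        means = self._means([(0.9, 0.1, 1), (0.5, 0.5, 1)])
        table = dual.dual_color_table(means, {"G0", "G1"})
        assert table.at["G0", "scaled_affected"] == pytest.approx(0.8)
        assert table.at["G0", "scaled_unaffected"] == pytest.approx(-0.8)
        assert bool(table.at["G0", "dual"]) is True
        assert bool(table.at["G1", "dual"]) is False

    def test_absent_gene_emits_no_record(self):
        means = self._means([(0.9, 0.1, 1)])
        table = dual.dual_color_table(means, {"G0", "MISSING"})
        assert list(table.index) == ["G0"]


class TestSitewiseTtest:
    def test_identical_groups_give_null_result(self):
        vals = np.random.default_rng(2).uniform(0.2, 0.8, size=(6, 3))
        bm = pd.DataFrame(
            np.hstack([vals, vals]),
            index=[f"p{i}" for i in range(6)],
            columns=[f"a{i}" for i in range(3)] + [f"u{i}" for i in range(3)],
        )
        design = dual.GroupDesign(("a0", "a1", "a2"), ("u0", "u1", "u2"))
        res, skipped = dual.sitewise_ttest(bm, design)
        assert skipped == []
        assert np.allclose(res["t"], 0.0) and np.allclose(res["raw_p"], 1.0)

    def test_crafted_extreme_probe_has_smallest_p(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.4, 0.6, size=(20, 6))
        vals[7, :3] = [0.1, 0.101, 0.099]
        vals[7, 3:] = [0.9, 0.899, 0.901]
        bm = pd.DataFrame(
            vals,
            index=[f"p{i:02d}" for i in range(20)],
            columns=[f"a{i}" for i in range(3)] + [f"u{i}" for i in range(3)],
        )
        design = dual.GroupDesign(("a0", "a1", "a2"), ("u0", "u1", "u2"))
        res, _ = dual.sitewise_ttest(bm, design)
        assert res["raw_p"].idxmin() == "p07"
        # oracle: scipy on the crafted values directly
        from scipy import stats

        t, p = stats.ttest_ind(vals[7, :3], vals[7, 3:], equal_var=False)
        assert res.at["p07", "t"] == pytest.approx(t)
        assert res.at["p07", "raw_p"] == pytest.approx(p)

    def test_underpowered_probes_skipped_with_reason(self):
        bm = pd.DataFrame(
            [[0.5, np.nan, 0.6, 0.7], [0.5, 0.4, 0.6, 0.7]],
            index=["p1", "p2"],
            columns=["a1", "a2", "u1", "u2"],
        )
        design = dual.GroupDesign(("a1", "a2"), ("u1", "u2"))
        res, skipped = dual.sitewise_ttest(bm, design)
        assert [p for p, _ in skipped] == ["p1"]
        assert list(res.index) == ["p2"]


class TestBenjaminiHochberg:
    def test_matches_hand_computed_five_value_fixture(self):
        # step-up by hand: sorted p * m/i, then cumulative min from the right
        raw = [0.005, 0.009, 0.02, 0.04, 0.9]
        expected = [0.0225, 0.0225, 1 / 30, 0.05, 0.9]
        adjusted = multipletests(raw, method="fdr_bh")[1]
        np.testing.assert_allclose(adjusted, expected, atol=1e-12)

    def test_single_test_is_identity(self):
        assert multipletests([0.3], method="fdr_bh")[1][0] == pytest.approx(0.3)

    def test_monotone_in_rank(self):
        raw = np.sort(np.random.default_rng(4).uniform(size=30))
        adjusted = multipletests(raw, method="fdr_bh")[1]
        assert np.all(np.diff(adjusted) >= -1e-15)


class TestTopVarianceClustering:
    def test_argmax_selection(self):
        bm = pd.DataFrame(
            [[0.5, 0.5, 0.5], [0.1, 0.9, 0.5], [0.4, 0.4, 0.4]],
            index=["flat1", "wild", "flat2"],
            columns=["s1", "s2", "s3"],
        )
        result = dual.top_variance_clustering(bm, 1)
        assert result.selected_probes == ("wild",)

    def test_duplicated_samples_are_adjacent_leaves(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(size=(10, 4))
        bm = pd.DataFrame(
            np.hstack([vals, vals[:, [0]]]),  # s_dup duplicates s1
            index=[f"p{i}" for i in range(10)],
            columns=["s1", "s2", "s3", "s4", "s_dup"],
        )
        result = dual.top_variance_clustering(bm, 10)
        order = list(result.sample_order)
        assert abs(order.index("s1") - order.index("s_dup")) == 1

    def test_k_equals_all_probes_is_identity_set(self):
        rng = np.random.default_rng(6)
        bm = pd.DataFrame(
            rng.uniform(size=(8, 4)),
            index=[f"p{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(4)],
        )
        result = dual.top_variance_clustering(bm, 8)
        assert set(result.selected_probes) == set(bm.index)
        assert set(result.probe_order) == set(bm.index)

    def test_constant_matrix_ties_broken_by_probe_id(self):
        bm = pd.DataFrame(
            np.full((4, 3), 0.5),
            index=["pD", "pA", "pC", "pB"],
            columns=["s1", "s2", "s3"],
        )
        result = dual.top_variance_clustering(bm, 2)
        assert result.selected_probes == ("pA", "pB")

    def test_k_too_large_rejected(self):
        bm = pd.DataFrame(np.full((2, 2), 0.5), index=["p1", "p2"], columns=["a", "b"])
        with pytest.raises(ValueError):
            dual.top_variance_clustering(bm, 3)
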