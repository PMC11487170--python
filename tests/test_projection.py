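"""Pattern projection: ortholog alignment, least-squares scores, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patterntransfer.io_formats import ExpressionMatrix, OrthologMap
from patterntransfer.projection import (
    AlignedPair,
    compare_groups,
    project_patterns,
    restrict_to_orthologs,
)

from .conftest import make_annotations
from .oracles import pooled_t


def em(genes, samples, values):
    return ExpressionMatrix(genes, samples, np.asarray(values, dtype=float))


class TestRestrictToOrthologs:
    def setup_method(self):
        self.A = pd.DataFrame(
            np.arange(10.0).reshape(5, 2),
            index=[f"a{i}" for i in range(5)],
            columns=["p1", "p2"],
        )

    def test_identity_map_keeps_everything(self):
        omap = OrthologMap("A", "A2", [(f"a{i}", f"a{i}") for i in range(5)])
        Y = em([f"a{i}" for i in range(5)], ["s1"], np.ones((5, 1)))
        out = restrict_to_orthologs(self.A, Y, omap, source_species="A")
        assert list(out.A.index) == [f"a{i}" for i in range(5)]
        assert out.n_dropped == 0

    def test_partial_overlap_keeps_pairs_in_map_order(self):
        omap = OrthologMap(
            "A", "B", [("a3", "b3"), ("a0", "b0"), ("a9", "b9"), ("a1", "b1")]
        )
        Y = em(["b0", "b1", "b3"], ["s1", "s2"], np.ones((3, 2)))
        out = restrict_to_orthologs(self.A, Y, omap, source_species="A")
        assert list(out.A.index) == ["a3", "a0", "a1"]
        assert out.target_gene_ids == ["b3", "b0", "b1"]
        assert out.n_dropped == 1

    def test_orientation_inferred_and_reversible(self):
        omap = OrthologMap("B", "A", [("b0", "a0"), ("b1", "a1"), ("b2", "a2")])
        Y = em(["b0", "b1"], ["s1"], np.ones((2, 1)))
        out = restrict_to_orthologs(self.A, Y, omap)  # source matches side B
        assert list(out.A.index) == ["a0", "a1"]

    def test_no_shared_pairs_rejected(self):
        omap = OrthologMap("A", "B", [("a0", "b0")])
        Y = em(["bX"], ["s1"], np.ones((1, 1)))
        with pytest.raises(ValueError, match="no ortholog pair"):
            restrict_to_orthologs(self.A, Y, omap, source_species="A")

    def test_wrong_species_label_rejected(self):
        omap = OrthologMap("A", "B", [("a0", "b0")])
        Y = em(["b0"], ["s1"], np.ones((1, 1)))
        with pytest.raises(ValueError, match="neither"):
            restrict_to_orthologs(self.A, Y, omap, source_species="C")


class TestProjectPatterns:
    def test_worked_example_normal_equations(self):
        A = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]],
                         index=["g1", "g2", "g3"], columns=["p1", "p2"])
        Y = pd.DataFrame({"s1": [2.0, 3.0, 5.0]}, index=["g1", "g2", "g3"])
        res = project_patterns((A, Y), center=False)
        np.testing.assert_allclose(res.scores["s1"], [2.0, 3.0], atol=1e-10)

    def test_exact_recovery_when_target_is_reconstruction(self):
        rng = np.random.default_rng(5)
        A = rng.random((30, 3))
        P = rng.random((3, 6))
        res = project_patterns(
            (
                pd.DataFrame(A, index=[f"g{i}" for i in range(30)]),
                pd.DataFrame(A @ P, index=[f"g{i}" for i in range(30)]),
            ),
            center=False,
        )
        np.testing.assert_allclose(res.scores.to_numpy(), P, atol=1e-8)

    def test_orthogonal_target_scores_zero(self):
        A = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        y = pd.DataFrame({"s": [0.0, 0.0, 7.0]})
        res = project_patterns((A, y), center=False)
        np.testing.assert_allclose(res.scores["s"], [0.0, 0.0], atol=1e-10)

    def test_centering_removes_gene_means(self):
        rng = np.random.default_rng(6)
        A = pd.DataFrame(rng.random((10, 2)))
        Y = pd.DataFrame(rng.random((10, 4)))
        res = project_patterns((A, Y), center=True)
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=1, keepdims=True)
        expected, *_ = np.linalg.lstsq(A.to_numpy(), Yc, rcond=None)
        np.testing.assert_allclose(res.scores.to_numpy(), expected, atol=1e-10)

    def test_rank_deficient_rejected_naming_collinear(self):
        A = pd.DataFrame(
            {"p1": [1.0, 2.0, 3.0], "p2": [2.0, 4.0, 6.0]}
        )
        Y = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValueError, match=r"p1.*p2"):
            project_patterns((A, Y), center=False)

    def test_fewer_genes_than_patterns_rejected(self):
        A = pd.DataFrame(np.ones((1, 2)))
        Y = pd.DataFrame(np.ones((1, 1)))
        with pytest.raises(ValueError):
            project_patterns((A, Y), center=False)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(alpha=st.floats(0.01, 100.0, allow_nan=False))
    def test_projection_is_linear_in_target(self, alpha):
        rng = np.random.default_rng(9)
        A = pd.DataFrame(rng.random((12, 2)))
        Y = pd.DataFrame(rng.random((12, 3)))
        base = project_patterns((A, Y), center=False).scores.to_numpy()
        scaled = project_patterns((A, Y * alpha), center=False).scores.to_numpy()
        np.testing.assert_allclose(scaled, alpha * base, rtol=1e-8, atol=1e-10)


class TestCompareGroups:
    def _result(self, scores_row, sample_ids):
        from patterntransfer.projection import ProjectionResult

        return ProjectionResult(
            source_pattern_ids=["p1"],
            target_sample_ids=sample_ids,
            scores=pd.DataFrame([scores_row], index=["p1"], columns=sample_ids),
            n_genes_used=10,
        )

    def test_closed_form_example(self):
        sample_ids = [f"s{i}" for i in range(6)]
        res = self._result([1.0, 2.0, 3.0, 2.0, 3.0, 4.0], sample_ids)
        anns = make_annotations(
            sample_ids, ["liver"] * 6, ["torpor"] * 3 + ["euthermia"] * 3
        )
        rec = compare_groups(res, anns, "p1", "torpor", "euthermia")
        assert rec.t_statistic == pytest.approx(-1.2247, abs=1e-4)
        assert rec.df == 4
        assert rec.p_value == pytest.approx(0.2878, abs=1e-4)
        # independent closed-form oracle
        t, df, p = pooled_t([1, 2, 3], [2, 3, 4])
        assert rec.t_statistic == pytest.approx(t)
        assert rec.p_value == pytest.approx(p)

    def test_identical_groups_give_t_zero_p_one(self):
        sample_ids = [f"s{i}" for i in range(4)]
        res = self._result([5.0, 5.0, 5.0, 5.0], sample_ids)
        anns = make_annotations(
            sample_ids, ["liver"] * 4, ["torpor", "torpor", "euthermia", "euthermia"]
        )
        rec = compare_groups(res, anns, "p1", "torpor", "euthermia")
        assert rec.t_statistic == 0.0
        assert rec.p_value == 1.0

    def test_single_sample_group_rejected(self):
        sample_ids = [f"s{i}" for i in range(3)]
        res = self._result([1.0, 2.0, 3.0], sample_ids)
        anns = make_annotations(
            sample_ids, ["liver"] * 3, ["torpor", "euthermia", "euthermia"]
        )
        with pytest.raises(ValueError, match="need >= 2"):
            compare_groups(res, anns, "p1", "torpor", "euthermia")

    def test_tissue_restriction(self):
        sample_ids = [f"s{i}" for i in range(8)]
        row = [0.0, 0.1, 5.0, 5.1, 1.0, 1.1, 1.0, 1.2]
        res = self._result(row, sample_ids)
        anns = make_annotations(
            sample_ids,
            ["liver"] * 4 + ["brain"] * 4,
            ["torpor", "torpor", "euthermia", "euthermia"] * 2,
        )
        rec = compare_groups(res, anns, "p1", "torpor", "euthermia", tissue="liver")
        t, _, p = pooled_t([0.0, 0.1], [5.0, 5.1])
        assert rec.t_statistic == pytest.approx(t)
        assert rec.p_value == pytest.approx(p)

    def test_welch_flag(self):
        from scipy import stats

        sample_ids = [f"s{i}" for i in range(6)]
        row = [1.0, 2.0, 30.0, 2.0, 3.0, 4.0]
        res = self._result(row, sample_ids)
        anns = make_annotations(
            sample_ids, ["liver"] * 6, ["torpor"] * 3 + ["euthermia"] * 3
        )
        rec = compare_groups(res, anns, "p1", "torpor", "euthermia", equal_var=False)
        ref = stats.ttest_ind(row[:3], row[3:], equal_var=False)
        assert rec.t_statistic == pytest.approx(float(ref.statistic))
        assert rec.p_value == pytest.approx(float(ref.pvalue))
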