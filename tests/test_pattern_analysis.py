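"""Pattern classification, pattern-count selection and marker statistics."""

import numpy as np
import pytest

from patterntransfer.factorization import Factorization
from patterntransfer.pattern_analysis import (
    PatternClassification,
    PatternInfo,
    Thresholds,
    classify_patterns,
    drop_technical_patterns,
    pattern_markers,
    select_pattern_count,
)

from .conftest import make_annotations


def make_fact(P, A=None, gene_ids=None):
    P = np.asarray(P, dtype=float)
    k, n = P.shape
    if A is None:
        A = np.abs(np.random.default_rng(0).random((max(k + 1, 3), k)))
    A = np.asarray(A, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(A.shape[0])]
    X = A @ P
    return Factorization(
        gene_ids=gene_ids,
        sample_ids=[f"s{j}" for j in range(n)],
        A=A,
        P=P,
        k=k,
        frobenius_error=0.0,
        seed=0,
        iterations=1,
        converged=True,
    )


class TestClassifyPatterns:
    def test_single_sample_pattern_is_sample_specific(self):
        # 4 samples, first two are replicates of the same liver/torpor group
        fact = make_fact([[1.0, 0.0, 0.0, 0.0]])
        anns = make_annotations(
            fact.sample_ids,
            ["liver", "liver", "brain", "brain"],
            ["torpor", "torpor", "torpor", "torpor"],
        )
        cls = classify_patterns(fact, anns)
        assert cls.categories() == ["sample_specific"]
        assert cls.patterns[0].dominance == pytest.approx(1.0)

    def test_state_driven_pattern(self):
        # equal weights on all torpor samples across two tissues
        fact = make_fact([[1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0]])
        anns = make_annotations(
            fact.sample_ids,
            ["liver", "liver", "brain", "brain"] * 2,
            ["torpor"] * 4 + ["euthermia"] * 4,
        )
        cls = classify_patterns(fact, anns)
        assert cls.categories() == ["state"]
        assert cls.patterns[0].eta2_state == pytest.approx(1.0)

    def test_tissue_driven_pattern(self):
        fact = make_fact([[1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0]])
        anns = make_annotations(
            fact.sample_ids,
            ["liver", "liver", "brain", "brain"] * 2,
            ["torpor"] * 4 + ["euthermia"] * 4,
        )
        assert classify_patterns(fact, anns).categories() == ["tissue"]

    def test_cell_driven_pattern_is_tissue_state(self):
        fact = make_fact([[1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
        anns = make_annotations(
            fact.sample_ids,
            ["liver", "liver", "brain", "brain"] * 2,
            ["torpor"] * 4 + ["euthermia"] * 4,
        )
        assert classify_patterns(fact, anns).categories() == ["tissue_state"]

    def test_depth_proportional_pattern_is_technical(self):
        lib = [100.0, 220.0, 150.0, 400.0]
        fact = make_fact([np.asarray(lib) / 400.0])
        anns = make_annotations(
            fact.sample_ids,
            ["liver", "liver", "liver", "liver"],
            ["torpor", "torpor", "euthermia", "euthermia"],
            library_sizes=lib,
        )
        cls = classify_patterns(fact, anns)
        assert cls.categories() == ["technical"]
        assert cls.patterns[0].depth_correlation == pytest.approx(1.0)

    def test_missing_annotation_rejected(self):
        fact = make_fact([[1.0, 0.0]])
        anns = make_annotations(["s0"], ["liver"], ["torpor"])
        with pytest.raises(ValueError, match="without annotation"):
            classify_patterns(fact, anns)

    def test_invariant_to_sample_order_and_scaling(self):
        rng = np.random.default_rng(4)
        P = rng.random((2, 8))
        fact = make_fact(P)
        tissues = ["liver", "liver", "brain", "brain"] * 2
        states = ["torpor"] * 4 + ["euthermia"] * 4
        lib = list(rng.random(8) * 100 + 50)
        anns = make_annotations(fact.sample_ids, tissues, states, library_sizes=lib)
        base = classify_patterns(fact, anns)

        scaled = make_fact(P * np.array([[3.7], [0.2]]))
        assert classify_patterns(scaled, anns).categories() == base.categories()

        perm = rng.permutation(8)
        shuffled = make_fact(P[:, perm])
        shuffled.sample_ids = [fact.sample_ids[i] for i in perm]
        anns_perm = [anns[i] for i in perm]
        out = classify_patterns(shuffled, anns_perm)
        assert out.categories() == base.categories()
        for a, b in zip(out.patterns, base.patterns):
            assert a.eta2_tissue == pytest.approx(b.eta2_tissue)
            assert a.dominance == pytest.approx(b.dominance)


def _cls(categories):
    return PatternClassification(
        patterns=[
            PatternInfo(
                pattern_id=f"p{i}", category=c, dominance=0.1,
                eta2_tissue=0.5, eta2_state=0.5, eta2_interaction=0.5,
            )
            for i, c in enumerate(categories)
        ]
    )


class TestSelectPatternCount:
    def test_largest_clean_k(self):
        scans = {
            2: _cls(["tissue", "state"]),
            3: _cls(["tissue", "state", "tissue_state"]),
            4: _cls(["tissue", "state", "tissue", "sample_specific"]),
        }
        assert select_pattern_count(scans) == 3

    def test_all_clean_returns_max(self):
        scans = {k: _cls(["tissue"] * k) for k in range(2, 11)}
        assert select_pattern_count(scans) == 10

    def test_technical_patterns_do_not_disqualify(self):
        scans = {2: _cls(["tissue", "state"]), 3: _cls(["tissue", "state", "technical"])}
        assert select_pattern_count(scans) == 3

    def test_unspecific_pattern_disqualifies(self):
        # every retained pattern must show tissue and/or state specificity
        scans = {2: _cls(["tissue", "state"]), 3: _cls(["tissue", "state", "unclassified"])}
        assert select_pattern_count(scans) == 2

    def test_no_clean_k_raises(self):
        with pytest.raises(ValueError, match="replicates"):
            select_pattern_count({2: _cls(["sample_specific", "tissue"])})

    def test_non_contiguous_scan_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            select_pattern_count({2: _cls(["tissue"]), 4: _cls(["tissue"])})


class TestDropTechnical:
    def test_drops_only_technical_columns(self):
        rng = np.random.default_rng(1)
        fact = make_fact(rng.random((5, 6)), A=rng.random((8, 5)))
        cls = _cls(["tissue", "technical", "state", "tissue_state", "state"])
        out = drop_technical_patterns(fact, cls)
        assert out.k == 4
        keep = [0, 2, 3, 4]
        np.testing.assert_array_equal(out.A, fact.A[:, keep])
        np.testing.assert_array_equal(out.P, fact.P[keep])
        assert out.pattern_ids == [fact.pattern_ids[j] for j in keep]

    def test_identity_when_none_technical(self):
        fact = make_fact(np.random.default_rng(2).random((2, 4)))
        out = drop_technical_patterns(fact, _cls(["tissue", "state"]))
        assert out is fact

    def test_all_technical_rejected(self):
        fact = make_fact(np.random.default_rng(2).random((2, 4)))
        with pytest.raises(ValueError, match="technical"):
            drop_technical_patterns(fact, _cls(["technical", "technical"]))


class TestPatternMarkers:
    def test_exact_indicator_row_is_rank_one_marker(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5], [0.0, 0.8]])
        fact = make_fact(np.ones((2, 3)), A=A)
        table = pattern_markers(fact).table.set_index("gene_id")
        assert table.loc["g1", "pattern"] == "pattern2"
        assert table.loc["g1", "marker_score"] == pytest.approx(0.0)
        assert table.loc["g1", "rank"] == 1

    def test_uniform_row_ties_to_first_pattern(self):
        A = np.array([[1.0, 1.0], [1.0, 0.0]])
        fact = make_fact(np.ones((2, 2)), A=A)
        table = pattern_markers(fact).table.set_index("gene_id")
        assert table.loc["g0", "pattern"] == "pattern1"

    def test_matches_brute_force_distance_table(self):
        rng = np.random.default_rng(8)
        A = rng.random((5, 2))
        fact = make_fact(rng.random((2, 3)), A=A)
        result = pattern_markers(fact).table.set_index("gene_id")

        S = A / A.max(axis=0)
        for gi, gene in enumerate(fact.gene_ids):
            d = [np.linalg.norm(S[gi] - e) for e in np.eye(2)]
            j = int(np.argmin(d))
            assert result.loc[gene, "pattern"] == fact.pattern_ids[j]
            assert result.loc[gene, "marker_score"] == pytest.approx(d[j])

    def test_all_zero_gene_rows_reported_unassigned(self):
        A = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        fact = make_fact(np.ones((2, 2)), A=A)
        out = pattern_markers(fact)
        assert out.unassigned == ["g1"]
        assert set(out.table["gene_id"]) == {"g0", "g2"}

    def test_k_below_two_rejected(self):
        fact = make_fact(np.ones((1, 3)), A=np.ones((3, 1)))
        with pytest.raises(ValueError, match="k >= 2"):
            pattern_markers(fact)

    def test_exclusive_gene_always_marks_its_pattern(self):
        # property: a gene non-zero in exactly one pattern is closer to that
        # pattern's indicator than to any other
        rng = np.random.default_rng(12)
        for _ in range(20):
            k = int(rng.integers(2, 5))
            A = rng.random((6, k))
            A[0] = 0.0
            j_star = int(rng.integers(0, k))
            A[0, j_star] = rng.random() + 0.05
            fact = make_fact(rng.random((k, 3)) + 0.01, A=A)
            table = pattern_markers(fact).table.set_index("gene_id")
            assert table.loc["g0", "pattern"] == fact.pattern_ids[j_star]
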