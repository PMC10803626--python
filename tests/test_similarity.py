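"""Similarity views against naive oracles, hand-derived values and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncdap.datatypes import (
    AssociationMatrix,
    DegenerateInputError,
    DiseaseDAG,
    IdentifierError,
    SequenceSet,
)
from lncdap.similarity import (
    compute_all_views,
    disease_cosine_similarity,
    disease_semantic_similarity,
    disease_semantic_similarity_matrix,
    gip_kernel,
    lncrna_functional_similarity_matrix,
    lncrna_sequence_similarity,
    weighted_edit_cost,
)

from conftest import random_dag_edges
from oracles import (
    brute_force_edit_cost,
    lcs_edit_cost,
    naive_cosine,
    naive_dss,
    naive_gip,
    naive_lfs,
)


def random_association(rng, n_d=10, n_l=15, p=0.3):
    m = (rng.random((n_d, n_l)) < p).astype(int)
    m[0] = 0  # keep one all-zero disease row to exercise the conventions
    if m.sum() == 0:
        m[1, 1] = 1
    return AssociationMatrix(m, [f"d{i}" for i in range(n_d)],
                             [f"l{i}" for i in range(n_l)])


class TestDiseaseSemanticSimilarity:
    def test_self_similarity_is_one(self, rng):
        names, edges = random_dag_edges(rng)
        dag = DiseaseDAG(edges, nodes=names)
        for n in names:
            assert disease_semantic_similarity(dag, n, n) == pytest.approx(1.0)

    def test_disjoint_ancestors_give_zero(self):
        dag = DiseaseDAG([("a", "ra"), ("b", "rb")])
        assert disease_semantic_similarity(dag, "a", "b") == 0.0

    def test_root_with_two_children_hand_value(self):
        # ancestors(a) = {a, r}: SC=1 and 0.5, SV = 1.5; shared {r} -> 1/3
        dag = DiseaseDAG([("a", "r"), ("b", "r")], decay=0.5)
        assert dag.semantic_value("a") == pytest.approx(1.5)
        assert disease_semantic_similarity(dag, "a", "b") == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        names, edges = random_dag_edges(rng)
        dag = DiseaseDAG(edges, nodes=names)
        parents = {}
        for c, p in edges:
            parents.setdefault(c, set()).add(p)
        got = disease_semantic_similarity_matrix(dag, names).values
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert got[i, j] == pytest.approx(naive_dss(parents, a, b), abs=1e-10)

    def test_unknown_disease_raises(self):
        dag = DiseaseDAG([("a", "r")])
        with pytest.raises(IdentifierError):
            disease_semantic_similarity(dag, "a", "nope")

    def test_bounded_by_one(self, rng):
        names, edges = random_dag_edges(rng, n=12)
        net = disease_semantic_similarity_matrix(DiseaseDAG(edges, nodes=names), names)
        assert net.values.max() <= 1 + 1e-12


class TestProfileSimilarities:
    def test_cosine_matches_double_loop(self, rng):
        A = random_association(rng)
        got = disease_cosine_similarity(A).values
        np.testing.assert_allclose(got, naive_cosine(A.values.astype(float)), atol=1e-10)

    def test_cosine_hand_values(self):
        A = AssociationMatrix(np.array([[1, 1, 0], [0, 1, 1], [1, 1, 0]]),
                              ["a", "b", "c"], ["x", "y", "z"])
        got = disease_cosine_similarity(A).values
        assert got[0, 1] == pytest.approx(0.5)   # dot 1 over sqrt2*sqrt2
        assert got[0, 2] == pytest.approx(1.0)   # identical rows
        A2 = AssociationMatrix(np.eye(3, dtype=int), ["a", "b", "c"], ["x", "y", "z"])
        assert disease_cosine_similarity(A2).values[0, 1] == 0.0

    def test_gip_matches_double_loop_both_axes(self, rng):
        A = random_association(rng)
        got_d = gip_kernel(A.values, "rows", A.disease_ids).values
        np.testing.assert_allclose(got_d, naive_gip(A.values.astype(float)), atol=1e-10)
        got_l = gip_kernel(A.values, "columns", A.lncrna_ids).values
        np.testing.assert_allclose(got_l, naive_gip(A.values.T.astype(float)), atol=1e-10)

    def test_gip_identity_profiles_hand_value(self):
        # profiles (1,0) and (0,1): mean sq norm 1, distance^2 = 2
        got = gip_kernel(np.eye(2, dtype=int), "rows", ["a", "b"]).values
        assert got[0, 1] == pytest.approx(np.exp(-2.0))
        assert got[0, 0] == 1.0

    def test_gip_bandwidth_scaling_exponentiates(self, rng):
        A = random_association(rng)
        base = gip_kernel(A.values, "rows", A.disease_ids, gamma_prime=1.0).values
        scaled = gip_kernel(A.values, "rows", A.disease_ids, gamma_prime=3.0).values
        off = ~np.eye(len(base), dtype=bool)
        np.testing.assert_allclose(scaled[off], base[off] ** 3.0, atol=1e-10)

    def test_gip_all_zero_profiles_degenerate(self):
        with pytest.raises(DegenerateInputError):
            gip_kernel(np.zeros((3, 4), dtype=int), "rows", ["a", "b", "c"])

    def test_lfs_matches_double_loop(self, rng):
        A = random_association(rng)
        names, edges = random_dag_edges(rng, n=10)
        dag = DiseaseDAG(edges, nodes=names)
        dss = disease_semantic_similarity_matrix(dag, A.disease_ids[: len(names)])
        # reindex DAG names onto the association diseases
        dss.entity_ids = A.disease_ids
        got = lncrna_functional_similarity_matrix(dss, A).values
        sets_ = [list(np.flatnonzero(A.values[:, l])) for l in range(A.n_lncrnas)]
        np.testing.assert_allclose(got, naive_lfs(dss.values, sets_), atol=1e-10)

    def test_lfs_hand_values(self):
        dag = DiseaseDAG([("a", "r"), ("b", "r")], decay=0.5)
        A = AssociationMatrix(np.array([[1, 0, 1], [0, 1, 1]]), ["a", "b"], ["x", "y", "z"])
        dss = disease_semantic_similarity_matrix(dag, ["a", "b"])
        got = lncrna_functional_similarity_matrix(dss, A).values
        # D_x={a}, D_y={b}, DSS(a,b)=1/3 -> (1/3 + 1/3)/2
        assert got[0, 1] == pytest.approx(1 / 3)
        # identical disease sets -> 1
        assert got[2, 2] == 1.0
        A_empty = AssociationMatrix(np.array([[1, 0], [0, 0]]).T, ["a", "b"], ["x", "y"])
        got = lncrna_functional_similarity_matrix(
            disease_semantic_similarity_matrix(dag, ["a", "b"]), A_empty).values
        assert got[0, 1] == 0.0  # lncRNA y has no diseases


class TestEditCost:
    @pytest.mark.parametrize("s1,s2,expect", [
        ("ACGU", "ACGU", 0),
        ("AC", "A", 1),
        ("AAA", "CCC", 6),
        ("", "ACG", 3),
    ])
    def test_hand_values(self, s1, s2, expect):
        assert weighted_edit_cost(s1, s2) == expect

    def test_matches_exhaustive_search_tiny(self, rng):
        for _ in range(30):
            s1 = "".join(rng.choice(list("ACGU"), size=rng.integers(0, 6)))
            s2 = "".join(rng.choice(list("ACGU"), size=rng.integers(0, 6)))
            assert weighted_edit_cost(s1, s2) == brute_force_edit_cost(s1, s2)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGU", max_size=30), st.text(alphabet="ACGU", max_size=30))
    def test_lcs_closed_form(self, s1, s2):
        assert weighted_edit_cost(s1, s2) == lcs_edit_cost(s1, s2)

    def test_symmetry_and_bound(self, rng):
        s1 = "".join(rng.choice(list("ACGU"), size=20))
        s2 = "".join(rng.choice(list("ACGU"), size=12))
        c = weighted_edit_cost(s1, s2)
        assert c == weighted_edit_cost(s2, s1)
        assert 0 <= c <= len(s1) + len(s2)


class TestSequenceSimilarity:
    def test_matrix_matches_lcs_oracle(self, rng):
        seqs = {f"l{i}": "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 15))))
                for i in range(10)}
        ss = SequenceSet(seqs)
        ids = list(seqs)
        got = lncrna_sequence_similarity(ss, ids).values
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                expect = 1 - lcs_edit_cost(ss[a], ss[b]) / (len(ss[a]) + len(ss[b]))
                assert got[i, j] == pytest.approx(expect, abs=1e-10)

    def test_hand_values_and_raw_form(self):
        ss = SequenceSet({"x": "AAA", "y": "CCC", "z": "AC", "w": "A"})
        net = lncrna_sequence_similarity(ss, ["x", "y", "z", "w"])
        assert net.values[0, 1] == 0.0                       # 1 - 6/6
        assert net.values[2, 3] == pytest.approx(2 / 3)      # 1 - 1/3
        assert net.values[0, 0] == 1.0
        raw = lncrna_sequence_similarity(ss, ["x", "y"], raw_distance=True)
        assert raw.values[0, 1] == pytest.approx(1.0)
        assert raw.values[0, 0] == 0.0

    def test_missing_sequence_raises(self):
        ss = SequenceSet({"x": "ACGU"})
        with pytest.raises(IdentifierError):
            lncrna_sequence_similarity(ss, ["x", "missing"])


class TestAllViews:
    def test_all_six_symmetric_unit_interval(self, small_bundle):
        views = compute_all_views(small_bundle.A_observed, small_bundle.dag,
                                  small_bundle.sequences)
        assert set(views) == {"DSS", "DCS", "DGS", "LFS", "LGS", "LSES"}
        for name, net in views.items():
            m = net.values
            assert np.abs(m - m.T).max() <= 1e-12, name
            assert m.min() >= 0 and m.max() <= 1, name
            np.testing.assert_allclose(np.diag(m), 1.0)

    def test_missing_inputs_raise(self, small_bundle):
        with pytest.raises(ValueError, match="DAG"):
            compute_all_views(small_bundle.A_observed, None, small_bundle.sequences)
        with pytest.raises(ValueError, match="sequence"):
            compute_all_views(small_bundle.A_observed, small_bundle.dag, None,
                              views=("DCS", "LSES"))
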