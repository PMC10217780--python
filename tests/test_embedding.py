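"""Propagation embeddings: restart weighting, PageRank fixed point, signatures."""

import numpy as np
import pytest

from kgprodromal.embedding import (ConceptMapping, EmptySignatureError, PSEVParams,
                                   ConvergenceError, build_psev_matrix,
                                   build_raw_matrix, build_restart_vector,
                                   build_spokesig, build_spokesig_matrix,
                                   compute_psev, read_matrix, write_matrix)
from kgprodromal.kg import (EdgeRecord, KnowledgeGraph, NodeRecord, build_transition)
from kgprodromal.records import EHREvent, PatientRecord


def _rec(pid, concepts, day=10):
    return PatientRecord(patient_id=pid, birth_day=-20000,
                         events=[EHREvent(day + i, c, "diagnosis")
                                 for i, c in enumerate(concepts)],
                         last_visit_day=1000)


def dense_pagerank_oracle(kg: KnowledgeGraph, restart: np.ndarray,
                          damping: float) -> np.ndarray:
    """Independent oracle: direct linear solve of the stationary equations.

    v = d·(T + r·1_dangling^T)·v + (1−d)·r  has the closed-form solution
    v = (1−d)·(I − d·M)^{-1} r with M the dangling-patched dense transition.
    """
    tm = build_transition(kg)
    M = tm.matrix.toarray()
    M[:, tm.dangling_mask] = restart[:, None]
    v = np.linalg.solve(np.eye(kg.n_nodes) - damping * M, (1 - damping) * restart)
    return v / v.sum()


def _random_kg(rng, n):
    nodes = [NodeRecord(f"N{i:03d}", "Gene") for i in range(n)]
    edges = [EdgeRecord(f"N{i:03d}", f"N{j:03d}")
             for i in range(n) for j in range(i + 1, n)
             if rng.random() < min(1.0, 3.0 / n)]
    return KnowledgeGraph(nodes=nodes, edges=edges)


class TestRestartVector:
    def test_single_patient_single_concept(self, path_kg):
        mapping = ConceptMapping({"c": "A"})
        r = build_restart_vector("c", [_rec("p1", ["c"])], mapping, path_kg)
        expected = np.zeros(5)
        expected[path_kg.node_index["A"]] = 1.0
        np.testing.assert_allclose(r, expected)

    def test_cooccurrence_counts(self, path_kg):
        # both carriers of c also carry d: weights {X:2, Y:2} -> {0.5, 0.5}
        mapping = ConceptMapping({"c": "A", "d": "C"})
        cohort = [_rec("p1", ["c", "d"]), _rec("p2", ["c", "d"])]
        r = build_restart_vector("c", cohort, mapping, path_kg)
        assert r[path_kg.node_index["A"]] == pytest.approx(0.5)
        assert r[path_kg.node_index["C"]] == pytest.approx(0.5)
        assert r.sum() == pytest.approx(1.0)

    def test_zero_carrier_fallback(self, path_kg):
        mapping = ConceptMapping({"c": "B"})
        r = build_restart_vector("c", [_rec("p1", ["other"])], mapping, path_kg)
        assert r[path_kg.node_index["B"]] == 1.0 and r.sum() == 1.0

    def test_unmapped_concept_raises(self, path_kg):
        with pytest.raises(KeyError):
            build_restart_vector("nope", [], ConceptMapping({}), path_kg)


class TestComputePsev:
    def test_single_node_graph(self):
        kg = KnowledgeGraph(nodes=[NodeRecord("A", "Gene")], edges=[])
        tm = build_transition(kg)
        np.testing.assert_allclose(compute_psev(tm, np.array([1.0])), [1.0])

    def test_damping_to_zero_limit_returns_restart(self, path_kg):
        tm = build_transition(path_kg)
        restart = np.array([0.2, 0.3, 0.1, 0.25, 0.15])
        v = compute_psev(tm, restart, damping=1e-9)
        np.testing.assert_allclose(v, restart, atol=1e-8)

    def test_four_node_path_matches_dense_oracle(self):
        nodes = [NodeRecord(n, "Gene") for n in "ABCD"]
        edges = [EdgeRecord(a, b) for a, b in zip("ABC", "BCD")]
        kg = KnowledgeGraph(nodes=nodes, edges=edges)
        restart = np.array([1.0, 0, 0, 0])
        v = compute_psev(build_transition(kg), restart, damping=0.85, tol=1e-12)
        expected = dense_pagerank_oracle(kg, restart, 0.85)
        assert np.abs(v - expected).sum() < 1e-8

    def test_oracle_equivalence_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            kg = _random_kg(rng, int(rng.integers(5, 30)))
            restart = rng.dirichlet(np.ones(kg.n_nodes))
            v = compute_psev(build_transition(kg), restart, 0.85, tol=1e-12)
            oracle = dense_pagerank_oracle(kg, restart, 0.85)
            assert np.abs(v - oracle).sum() < 1e-8

    def test_nonconvergence_reports_residual(self, path_kg):
        tm = build_transition(path_kg)
        with pytest.raises(ConvergenceError, match="residual"):
            compute_psev(tm, np.array([1.0, 0, 0, 0, 0]), max_iter=1)

    def test_invalid_restart_rejected(self, path_kg):
        tm = build_transition(path_kg)
        with pytest.raises(ValueError):
            compute_psev(tm, np.array([0.5, 0.2, 0, 0, 0]))


class TestPsevMatrix:
    def test_row_per_observed_concept(self, path_kg):
        mapping = ConceptMapping({"c1": "A", "c2": "C", "c3": "E", "c4": "B"})
        cohort = [_rec("p1", ["c1", "c2"]), _rec("p2", ["c3"])]
        psev = build_psev_matrix(path_kg, cohort, mapping)
        assert psev.concepts == ["c1", "c2", "c3"]

    def test_patient_order_invariance(self, path_kg):
        mapping = ConceptMapping({"c1": "A", "c2": "C"})
        cohort = [_rec("p1", ["c1"]), _rec("p2", ["c2"]), _rec("p3", ["c1", "c2"])]
        a = build_psev_matrix(path_kg, cohort, mapping)
        b = build_psev_matrix(path_kg, cohort[::-1], mapping)
        np.testing.assert_array_equal(a.values, b.values)

    def test_rows_are_probability_vectors(self, world, small_cohort):
        psev = build_psev_matrix(world.kg, small_cohort.records[:30], world.mapping)
        np.testing.assert_allclose(psev.values.sum(axis=1),
                                   np.ones(len(psev.concepts)), atol=1e-9)
        assert (psev.values >= 0).all()


class TestSpokesig:
    @pytest.fixture
    def psev(self, path_kg):
        mapping = ConceptMapping({"c1": "A", "c2": "E"})
        cohort = [_rec("p1", ["c1"]), _rec("p2", ["c2"])]
        return build_psev_matrix(path_kg, cohort, mapping), mapping

    def test_single_concept_equals_psev_row(self, psev):
        matrix, mapping = psev
        sig = build_spokesig(_rec("p", ["c1"]), matrix, mapping)
        np.testing.assert_allclose(sig, matrix.values[0])

    def test_two_concepts_mean_of_rows(self, psev):
        matrix, mapping = psev
        sig = build_spokesig(_rec("p", ["c1", "c2"]), matrix, mapping)
        np.testing.assert_allclose(sig, matrix.values.mean(axis=0), atol=1e-12)

    def test_duplicate_events_count_once(self, psev):
        matrix, mapping = psev
        once = build_spokesig(_rec("p", ["c1", "c2"]), matrix, mapping)
        dup = build_spokesig(_rec("p", ["c1", "c1", "c1", "c2"]), matrix, mapping)
        np.testing.assert_allclose(once, dup)

    def test_count_weighted_mode_differs(self, psev):
        matrix, mapping = psev
        once = build_spokesig(_rec("p", ["c1", "c2"]), matrix, mapping)
        weighted = build_spokesig(_rec("p", ["c1", "c1", "c1", "c2"]), matrix, mapping,
                                  count_weighted=True)
        assert np.abs(once - weighted).sum() > 1e-6

    def test_empty_signature_raises(self, psev):
        matrix, mapping = psev
        with pytest.raises(EmptySignatureError):
            build_spokesig(_rec("p", ["unmapped"]), matrix, mapping)

    def test_matrix_rows_are_probability_vectors(self, world, small_cohort):
        from kgprodromal.embedding import build_psev_matrix
        records = small_cohort.records[:40]
        psev = build_psev_matrix(world.kg, records, world.mapping)
        sig, dropped = build_spokesig_matrix(records, psev, world.mapping)
        np.testing.assert_allclose(sig.values.sum(axis=1),
                                   np.ones(len(sig.patient_ids)), atol=1e-9)
        assert sig.node_ids == psev.node_ids


class TestRawMatrix:
    def test_binary_presence(self):
        mapping = ConceptMapping({"c1": "A", "c2": "B", "c3": "C"})
        raw = build_raw_matrix([_rec("p", ["c1", "c1", "c3"])], mapping)
        assert raw.concepts == ["c1", "c2", "c3"]
        np.testing.assert_array_equal(raw.values, [[1, 0, 1]])

    def test_empty_history_flagged(self):
        mapping = ConceptMapping({"c1": "A"})
        raw = build_raw_matrix([_rec("p", ["zzz"])], mapping)
        np.testing.assert_array_equal(raw.values, [[0]])
        assert raw.empty_patients == ["p"]


class TestSignalStructure:
    def test_prodromal_holder_scores_higher_at_target(self, world):
        """A patient holding a target-adjacent concept beats one holding only
        concepts ≥3 hops from the target at the target's signature value."""
        import networkx as nx
        g = world.kg.to_networkx()
        dist = nx.single_source_shortest_path_length(g, world.target_disease)
        near_c = world.prodromal_concepts[0]
        far_cs = [c for c in world.entry_concepts
                  if dist.get(world.mapping[c], 99) >= 3][:3]
        assert far_cs, "synthetic graph has no entry nodes >= 3 hops from target"
        cohort = [_rec("near", [near_c]), _rec("far", far_cs)]
        psev = build_psev_matrix(world.kg, cohort, world.mapping)
        t = world.kg.node_index[world.target_disease]
        near_sig = build_spokesig(cohort[0], psev, world.mapping)
        far_sig = build_spokesig(cohort[1], psev, world.mapping)
        assert near_sig[t] > far_sig[t]

    def test_adding_target_edge_never_decreases_target_value(self, path_kg):
        mapping = ConceptMapping({"c": "A"})
        rec = _rec("p", ["c"])
        base_psev = build_psev_matrix(path_kg, [rec], mapping)
        t = path_kg.node_index["E"]
        base = build_spokesig(rec, base_psev, mapping)[t]
        boosted_kg = KnowledgeGraph(
            nodes=list(path_kg.nodes),
            edges=list(path_kg.edges) + [EdgeRecord("A", "E")])
        boosted_psev = build_psev_matrix(boosted_kg, [rec], mapping)
        boosted = build_spokesig(rec, boosted_psev, mapping)[t]
        assert boosted >= base


def test_matrix_round_trip_bit_exact(tmp_path, world, small_cohort):
    psev = build_psev_matrix(world.kg, small_cohort.records[:10], world.mapping)
    write_matrix(psev, tmp_path / "psev")
    values, rows, cols = read_matrix(tmp_path / "psev")
    np.testing.assert_array_equal(values, psev.values)
    assert rows == psev.concepts and cols == psev.node_ids
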