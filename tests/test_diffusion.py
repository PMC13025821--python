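from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

from herbwalk.diffusion import (
    DiffusionConfig,
    DiffusionProfile,
    SeedVector,
    TransitionSystem,
    build_transition,
    diffuse,
    profile_similarity,
    seed_for_entity,
    seed_from_proteins,
    solve_fixed_point,
)
from herbwalk.network_model import (
    AbsentEntityError,
    LayerEdges,
    MultiscaleNetwork,
)

from conftest import random_transition_system


def _net(ppi=(), annot=(), hierarchy=()):
    net = MultiscaleNetwork()
    net.add_layer(LayerEdges("ppi", list(ppi)), ("protein", "protein"))
    if annot:
        net.add_layer(LayerEdges("protein_function", list(annot)),
                      ("protein", "function"))
    if hierarchy:
        net.add_layer(LayerEdges("function_hierarchy", list(hierarchy)),
                      ("function", "function"))
    return net


class TestBuildTransition:
    def test_unpopulated_class_mass_redistributed(self):
        # P has 2 protein neighbors and no annotations: pf weight flows to pp
        net = _net(ppi=[("P", "Q"), ("P", "R")])
        config = DiffusionConfig(layer_weights={"protein_protein": 1.0,
                                                "protein_function": 0.5})
        ts = build_transition(net, config)
        row = ts.matrix[ts.index_of("P")].toarray().ravel()
        assert row[ts.index_of("Q")] == pytest.approx(0.5)
        assert row[ts.index_of("R")] == pytest.approx(0.5)

    def test_proportional_split_between_classes(self):
        net = _net(ppi=[("P", "Q")], annot=[("P", "F1")])
        config = DiffusionConfig(layer_weights={"protein_protein": 3.0,
                                                "protein_function": 1.0})
        ts = build_transition(net, config)
        row = ts.matrix[ts.index_of("P")].toarray().ravel()
        assert row[ts.index_of("Q")] == pytest.approx(0.75)
        assert row[ts.index_of("F1")] == pytest.approx(0.25)

    def test_isolated_node_is_sink(self):
        net = _net(ppi=[("A", "B")])
        net.add_node("LONER", "protein")
        ts = build_transition(net)
        i = ts.index_of("LONER")
        assert ts.sinks[i]
        assert ts.matrix[i].nnz == 0

    def test_rows_stochastic(self, transition):
        rowsums = np.asarray(transition.matrix.sum(axis=1)).ravel()
        live = ~transition.sinks
        assert np.allclose(rowsums[live], 1.0, atol=1e-12)
        assert np.all(rowsums[transition.sinks] == 0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            DiffusionConfig(layer_weights={cls: 0.0 for cls in (
                "protein_protein", "protein_function", "function_protein",
                "function_parent", "function_child")})


def _two_node_system():
    """A -> B, B is a sink."""
    matrix = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
    return TransitionSystem(node_index=["A", "B"], node_kinds=["protein"] * 2,
                            matrix=matrix, sinks=np.array([False, True]))


class TestDiffuse:
    def test_alpha_zero_returns_seed(self):
        ts = _two_node_system()
        seed = SeedVector(np.array([1.0, 0.0]))
        profile = diffuse(ts, seed, DiffusionConfig(alpha=0.0))
        assert np.array_equal(profile.r, seed.s)
        assert profile.iterations_used == 1

    def test_two_node_closed_form(self):
        # fixed point: r_A = 0.15 + 0.85 r_B, r_B = 0.85 r_A
        ts = _two_node_system()
        seed = SeedVector(np.array([1.0, 0.0]))
        profile = diffuse(ts, seed, DiffusionConfig(alpha=0.85, epsilon=1e-14,
                                                    max_iterations=5000))
        assert profile.r[0] == pytest.approx(0.15 / 0.2775, abs=1e-10)
        assert profile.r[1] == pytest.approx(0.85 * 0.15 / 0.2775, abs=1e-10)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_dense_solve_on_random_systems(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 51))
        ts = random_transition_system(rng, n)
        s = np.zeros(n)
        s[rng.choice(n, size=3, replace=False)] = 1 / 3
        seed = SeedVector(s)
        config = DiffusionConfig(epsilon=1e-12, max_iterations=20000)
        profile = diffuse(ts, seed, config)
        direct = solve_fixed_point(ts, seed, config)
        assert np.max(np.abs(profile.r - direct)) <= 1e-8
        assert profile.r.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mass_conserved_on_disconnected_graph(self):
        net = _net(ppi=[("A", "B"), ("C", "D")])
        net.add_node("ALONE", "protein")
        ts = build_transition(net)
        seed = seed_from_proteins(["A", "ALONE"], ts)
        profile = diffuse(ts, seed)
        assert profile.r.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bitwise_deterministic(self, transition, study):
        network, disease, _ = study
        seed = seed_for_entity("disease", "disease", network, transition,
                               disease=disease)
        a = diffuse(transition, seed)
        b = diffuse(transition, seed)
        assert np.array_equal(a.r, b.r)

    def test_alpha_one_reaches_degree_stationary_distribution(self):
        # non-bipartite connected graph: simple-RW stationary law is deg/2m
        edges = [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")]
        net = _net(ppi=edges)
        ts = build_transition(net)
        n = ts.n
        seed = SeedVector(np.full(n, 1 / n))
        profile = diffuse(ts, seed, DiffusionConfig(alpha=1.0, epsilon=1e-12,
                                                    max_iterations=100000))
        degrees = {"A": 2, "B": 2, "C": 3, "D": 1}
        expected = np.array([degrees[v] / 8 for v in ts.node_index])
        assert np.allclose(profile.r, expected, atol=1e-6)

    def test_nonconvergence_flagged(self):
        ts = _two_node_system()
        seed = SeedVector(np.array([1.0, 0.0]))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            profile = diffuse(ts, seed, DiffusionConfig(epsilon=1e-15,
                                                        max_iterations=3))
        assert not profile.converged


class TestSeeds:
    def test_uniform_over_disease_proteins(self):
        net = _net(ppi=[("P1", "P2"), ("P2", "P3")])
        ts = build_transition(net)
        seed = seed_from_proteins(["P1", "P2"], ts)
        assert seed.s[ts.index_of("P1")] == pytest.approx(0.5)
        assert seed.s[ts.index_of("P2")] == pytest.approx(0.5)
        assert seed.s[ts.index_of("P3")] == 0.0

    def test_outside_network_targets_renormalized(self):
        net = _net(ppi=[("P1", "P2"), ("P2", "P3")])
        ts = build_transition(net)
        seed = seed_from_proteins(["P1", "P2", "P3", "PX"], ts)
        assert np.isclose(seed.s.max(), 1 / 3)
        assert seed.s.sum() == pytest.approx(1.0)

    def test_all_targets_absent_is_error(self):
        net = _net(ppi=[("P1", "P2")])
        ts = build_transition(net)
        with pytest.raises(AbsentEntityError):
            seed_from_proteins(["PX"], ts)

    def test_herb_seed_uses_retained_targets(self, study, transition):
        network, _, _ = study
        herb = sorted(network.herb_targets)[0]
        seed = seed_for_entity(herb, "herb", network, transition)
        support = np.count_nonzero(seed.s)
        assert support == len(set(network.herb_targets[herb]))


def _profile(values):
    return DiffusionProfile(r=np.asarray(values, dtype=float),
                            iterations_used=1, final_l1_delta=0.0)


class TestProfileSimilarity:
    def test_identical_profiles(self):
        p = _profile([0.5, 0.3, 0.2])
        assert profile_similarity(p, p) == pytest.approx(1.0)

    def test_affine_anticorrelation(self):
        assert profile_similarity(_profile([1, 2, 3]),
                                  _profile([6, 4, 2])) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        got = profile_similarity(_profile([0.5, 0.3, 0.2]),
                                 _profile([0.2, 0.3, 0.5]))
        assert got == pytest.approx(-13 / 14, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            profile_similarity(_profile([0.25] * 4), _profile([0.1, 0.2, 0.3, 0.4]))

    @given(st.lists(st.floats(min_value=0.001, max_value=1.0), min_size=3,
                    max_size=12),
           st.floats(min_value=0.1, max_value=50.0))
    def test_symmetric_and_scale_invariant(self, values, scale):
        a = np.asarray(values)
        rng = np.random.default_rng(7)
        b = a + rng.random(a.size)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return
        pa, pb = _profile(a), _profile(b)
        forward = profile_similarity(pa, pb)
        assert profile_similarity(pb, pa) == pytest.approx(forward)
        scaled = profile_similarity(_profile(scale * a), _profile(scale * b))
        assert scaled == pytest.approx(forward, abs=1e-9)
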