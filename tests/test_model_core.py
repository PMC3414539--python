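import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opinionfield import (
    AgentState,
    ConfigError,
    LogicError,
    ModelParams,
    ShellWeights,
    SocialNetwork,
    default_kernels,
    init_system,
    long_range_opinion,
    opinion_derivative,
    step_opinions,
)
from opinionfield.model_core import (
    _derivatives_vectorized,
    _shell_weight_operator,
)

finite_opinion = st.floats(-1.0, 1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestAgentState:
    def test_valid(self):
        s = AgentState(opinion=0.5, attitude=-0.2)
        assert not s.frozen

    def test_opinion_bound(self):
        with pytest.raises(ValueError):
            AgentState(opinion=1.5, attitude=0.0)

    def test_frozen_requires_extreme(self):
        with pytest.raises(ValueError):
            AgentState(opinion=0.5, attitude=0.0, frozen=True)
        AgentState(opinion=-1.0, attitude=0.0, frozen=True)


class TestSocialNetwork:
    def test_no_self_loops(self):
        with pytest.raises(ConfigError):
            SocialNetwork(3, [(1, 1)])

    def test_duplicate_edges_collapse(self):
        net = SocialNetwork(3, [(0, 1), (1, 0)])
        assert net.n_edges == 1

    def test_symmetry(self, path_graph):
        assert path_graph.has_edge(0, 1) and path_graph.has_edge(1, 0)

    def test_shells_partition_reachable(self, rng):
        params = ModelParams(n_agents=30, mean_degree=3.0, seed=3)
        net, _ = init_system(params)
        for i in range(net.n_agents):
            seen: set[int] = set()
            for n in range(1, net.max_shell_index(i) + 1):
                shell = set(net.shell(i, n))
                assert not (shell & seen)
                assert i not in shell
                seen |= shell
            d = net.distance_matrix()[i]
            reachable = {j for j in range(net.n_agents) if j != i and np.isfinite(d[j])}
            assert seen == reachable

    def test_edgelist_roundtrip(self, tmp_path, path_graph):
        p = tmp_path / "net.tsv"
        path_graph.to_edgelist_tsv(p)
        back = SocialNetwork.from_edgelist_tsv(p, n_agents=3)
        assert back == path_graph

    def test_graphml_roundtrip(self, tmp_path, star_graph):
        import networkx as nx

        p = tmp_path / "net.graphml"
        star_graph.to_graphml(p)
        g = nx.read_graphml(p)
        assert g.number_of_edges() == star_graph.n_edges


class TestModelParams:
    def test_validation(self):
        with pytest.raises(ConfigError):
            ModelParams(n_agents=1)
        with pytest.raises(ConfigError):
            ModelParams(closure_mix=1.5)
        with pytest.raises(ConfigError):
            ModelParams(step_size=0.0)
        with pytest.raises(ConfigError):
            ModelParams(links_per_event="some")
        with pytest.raises(ConfigError):
            ModelParams(mean_degree=0.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            ModelParams.from_dict({"n_agents": 10, "mean_degre": 3})

    @pytest.mark.parametrize("suffix", ["yml", "json"])
    def test_config_roundtrip(self, tmp_path, suffix):
        params = ModelParams(n_agents=33, field=-0.4, closure_mix=0.25, seed=9)
        p = tmp_path / f"c.{suffix}"
        params.to_file(p)
        assert ModelParams.from_file(p) == params


# ---------------------------------------------------------------------------
# init_system
# ---------------------------------------------------------------------------

class TestInitSystem:
    def test_determinism(self):
        params = ModelParams(n_agents=50, mean_degree=5.0, seed=11)
        n1, s1 = init_system(params)
        n2, s2 = init_system(params)
        assert n1 == n2
        assert s1 == s2

    def test_p_equal_one(self):
        net, _ = init_system(ModelParams(n_agents=2, mean_degree=1.0, seed=0))
        assert net.edges == {(0, 1)}

    def test_attitude_and_opinion_ranges(self):
        _, states = init_system(ModelParams(n_agents=500, seed=2))
        assert np.all(np.abs(states.attitude) <= 1.0)
        assert np.all(np.abs(states.opinion) < 1.0)
        assert not states.frozen.any()

    def test_mean_degree_matches_binomial_oracle(self):
        # oracle: mean degree of G(n, p) is (n-1) p with variance
        # 2 p (1 - p) (n - 1) / n per graph
        n, k, n_seeds = 200, 6.0, 100
        p = k / (n - 1)
        means = []
        for seed in range(n_seeds):
            net, _ = init_system(ModelParams(n_agents=n, mean_degree=k, seed=seed))
            means.append(net.mean_degree())
        per_graph_var = 4.0 * (n * (n - 1) / 2) * p * (1 - p) / n**2
        se = np.sqrt(per_graph_var / n_seeds)
        assert abs(np.mean(means) - k) < 3 * se


# ---------------------------------------------------------------------------
# long-range opinion
# ---------------------------------------------------------------------------

class TestLongRangeOpinion:
    def test_star_centre_is_zero(self, star_graph, make_population):
        states = make_population([0.5, 1.0, -1.0, 0.3, 0.9])
        assert long_range_opinion(star_graph, states, 0) == 0.0

    def test_path_single_shell_member(self, path_graph, make_population):
        states = make_population([0.1, 0.2, 0.7])
        w = ShellWeights(decay=0.5, scale=2.0, degree_scaled=False)
        # only shell S_2(0) = {2}: normalized weight is 1, times scale
        assert long_range_opinion(path_graph, states, 0, w) == pytest.approx(2.0 * 0.7)
        # degree-scaled variant multiplies by (degree + offset) instead
        w2 = ShellWeights(decay=0.5, scale=1.0, offset=1.5, degree_scaled=True)
        assert long_range_opinion(path_graph, states, 0, w2) == pytest.approx(2.5 * 0.7)

    def test_all_zero_opinions(self, make_population):
        net = SocialNetwork(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
        states = make_population(np.zeros(6))
        for i in range(6):
            assert long_range_opinion(net, states, i) == 0.0

    def test_weights_positive_decreasing(self):
        w = ShellWeights(decay=0.5, scale=3.0)
        raws = [w.raw(n) for n in range(1, 8)]
        assert all(r > 0 for r in raws)
        assert all(a > b for a, b in zip(raws, raws[1:]))

    def test_matrix_operator_matches_scalar(self, rng):
        params = ModelParams(n_agents=25, mean_degree=3.0, seed=5)
        net, states = init_system(params)
        op = _shell_weight_operator(net, params.shell_weights())
        m_fast = op @ states.opinion
        for i in range(net.n_agents):
            assert m_fast[i] == pytest.approx(
                long_range_opinion(net, states, i, params.shell_weights()), abs=1e-12
            )


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

class TestKernelContracts:
    @given(x=st.floats(0.01, 1.0), y=st.floats(0.01, 1.0))
    def test_pair_same_sign_reinforces(self, x, y):
        k = default_kernels()
        assert k.pair_term(x, y) > 0
        assert k.pair_term(-x, -y) < 0

    @given(x=st.floats(0.01, 1.0), y=st.floats(0.01, 1.0))
    def test_pair_opposite_sign_weakens(self, x, y):
        k = default_kernels()
        assert k.pair_term(x, -y) <= 0
        assert k.pair_term(-x, y) >= 0

    @given(x=finite_opinion)
    def test_field_zero_at_h0(self, x):
        assert default_kernels().field_term(x, 0.0) == 0.0

    @given(h=st.floats(0.01, 5.0))
    def test_field_magnitude_nonincreasing_in_x(self, h):
        k = default_kernels()
        xs = np.linspace(-1, 1, 21)
        mags = [abs(k.field_term(x, h)) for x in xs]
        assert all(a >= b - 1e-12 for a, b in zip(mags, mags[1:]))

    @given(x=finite_opinion, h=st.floats(-5, 5))
    def test_field_linear(self, x, h):
        k = default_kernels()
        assert k.field_term(x, h) == pytest.approx(
            k.field_term(0.0, h) + x * (k.field_term(1.0, h) - k.field_term(0.0, h))
        )

    @given(x=finite_opinion, m=st.floats(-10, 10))
    def test_long_range_proportional_to_attitude(self, x, m):
        k = default_kernels()
        assert k.long_range_term(0.0, x, m) == 0.0
        assert k.long_range_term(0.8, x, m) == pytest.approx(
            2 * k.long_range_term(0.4, x, m)
        )

    @given(a=st.floats(-1, 1), x=finite_opinion)
    def test_long_range_vanishes_without_distant_opinion(self, a, x):
        assert default_kernels().long_range_term(a, x, 0.0) == 0.0


# ---------------------------------------------------------------------------
# derivatives and stepping
# ---------------------------------------------------------------------------

class TestOpinionDerivative:
    def test_isolated_agent_zero(self, make_population):
        net = SocialNetwork(2, [])
        states = make_population([0.4, -0.2], [0.0, 0.0])
        assert opinion_derivative(0, states, net, default_kernels(), 0.0) == 0.0

    def test_same_sign_neighbour_positive(self, make_population):
        net = SocialNetwork(2, [(0, 1)])
        states = make_population([0.5, 0.5])
        assert opinion_derivative(0, states, net, default_kernels(), 0.0) > 0

    def test_opposite_sign_neighbour_nonpositive(self, make_population):
        net = SocialNetwork(2, [(0, 1)])
        states = make_population([0.5, -0.9])
        assert opinion_derivative(0, states, net, default_kernels(), 0.0) <= 0

    def test_frozen_agent_raises(self, make_population):
        net = SocialNetwork(2, [(0, 1)])
        states = make_population([1.0, 0.0], frozen=[True, False])
        with pytest.raises(LogicError):
            opinion_derivative(0, states, net, default_kernels(), 0.0)


class TestStepOpinions:
    def test_frozen_agent_untouched(self, make_population, small_params):
        net = SocialNetwork(2, [(0, 1)])
        states = make_population([1.0, 0.5], frozen=[True, False])
        out = states
        for _ in range(20):
            out = step_opinions(out, net, default_kernels(), small_params)
        assert out.opinion[0] == 1.0 and out.frozen[0]

    def test_overshoot_clamped_and_frozen(self, make_population):
        params = ModelParams(n_agents=2, mean_degree=1.0, step_size=1.0, seed=0)
        net = SocialNetwork(2, [(0, 1)])
        # derivative of agent 0: pair(0.9, 0.9) = 0.9 -> Euler to 1.8
        states = make_population([0.9, 0.9])
        out = step_opinions(states, net, default_kernels(), params)
        assert out.opinion[0] == 1.0
        assert out.frozen[0]

    def test_zero_step_identity(self, make_population, small_params):
        params = small_params.with_(step_size=1e-300)  # step_size must be > 0
        net = SocialNetwork(3, [(0, 1), (1, 2)])
        states = make_population([0.1, -0.4, 0.8])
        out = step_opinions(states, net, default_kernels(), params)
        assert np.allclose(out.opinion, states.opinion, atol=1e-12)

    def test_vectorized_matches_generic(self):
        params = ModelParams(n_agents=20, mean_degree=3.0, field=0.7, seed=13)
        net, states = init_system(params)
        kernels = default_kernels()
        fast = step_opinions(states, net, kernels, params)
        # route through the generic scalar path by disguising the kernels
        slow_kernels = type(kernels)(
            long_range_term=lambda a, x, m: kernels.long_range_term(a, x, m),
            pair_term=lambda xi, xj: kernels.pair_term(xi, xj),
            field_term=lambda x, h: kernels.field_term(x, h),
        )
        assert not slow_kernels.is_default
        slow = step_opinions(states, net, slow_kernels, params)
        assert np.allclose(fast.opinion, slow.opinion, atol=1e-12)
        assert np.array_equal(fast.frozen, slow.frozen)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), h=st.floats(-2, 2))
    def test_boundedness_and_freeze_permanence(self, seed, h):
        params = ModelParams(
            n_agents=15, mean_degree=3.0, field=h, seed=seed, step_size=0.05
        )
        net, states = init_system(params)
        frozen_before = states.frozen.copy()
        for _ in range(30):
            states = step_opinions(states, net, default_kernels(), params)
            assert np.all(np.abs(states.opinion) <= 1.0)
            assert np.all(states.frozen | ~frozen_before)  # non-decreasing
            frozen_before = states.frozen.copy()
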