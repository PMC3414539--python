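"""Domain types, initialization and the fast (transaction-scale) opinion dynamics.

An agent ``i`` carries a continuous opinion ``x_i`` in ``[-1, 1]``, a quenched
attitude ``alpha_i`` in ``[-1, 1]`` and a frozen flag.  Unfrozen opinions move
under three forces:

* a long-range reaction ``alpha_i * x_i * |m_i|`` to the weighted average
  opinion ``m_i`` of agents at geodesic distance >= 2,
* pairwise discussion with each network neighbour, reinforcing when the two
  opinions share a sign and weakening otherwise,
* a homogeneous external field ``(h / 2) * (1 - x_i)`` that pushes towards
  ``+1`` but vanishes there, so a positive drive weakens exactly where it
  would finish the job while a negative drive stays strong all the way down.

Once ``|x_i|`` reaches 1 the agent freezes at that extreme and never moves
again, though it remains visible to its neighbours.  The slow network
co-evolution lives in :mod:`opinionfield.rewiring`.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Iterator, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.csgraph import shortest_path
from scipy.stats import truncnorm

from .errors import ConfigError, LogicError

__all__ = [
    "AgentState",
    "Population",
    "SocialNetwork",
    "ModelParams",
    "InteractionKernels",
    "ShellWeights",
    "SimulationResult",
    "default_kernels",
    "init_system",
    "long_range_opinion",
    "opinion_derivative",
    "step_opinions",
    "run_simulation",
]


# --------------------------------------------------------------------------
# agent state
# --------------------------------------------------------------------------

@dataclass
class AgentState:
    """Opinion, attitude and conviction flag of a single agent.

    Invariants: ``|opinion| <= 1`` always; ``frozen`` implies
    ``|opinion| == 1`` and the opinion never changes again; ``attitude``
    is constant over a whole run.
    """

    opinion: float
    attitude: float
    frozen: bool = False

    def __post_init__(self) -> None:
        if abs(self.opinion) > 1.0:
            raise ValueError(f"opinion {self.opinion} outside [-1, 1]")
        if abs(self.attitude) > 1.0:
            raise ValueError(f"attitude {self.attitude} outside [-1, 1]")
        if self.frozen and abs(self.opinion) != 1.0:
            raise ValueError("frozen agents must sit at an extreme opinion")


class Population(Sequence):
    """Array-backed sequence of :class:`AgentState`.

    Stores opinions / attitudes / frozen flags as NumPy arrays for the
    vectorized integrator while still behaving like a sequence of
    ``AgentState`` records.
    """

    __slots__ = ("opinion", "attitude", "frozen")

    def __init__(
        self,
        opinion: np.ndarray,
        attitude: np.ndarray,
        frozen: np.ndarray | None = None,
    ) -> None:
        self.opinion = np.asarray(opinion, dtype=float).copy()
        self.attitude = np.asarray(attitude, dtype=float).copy()
        if frozen is None:
            frozen = np.zeros(self.opinion.shape, dtype=bool)
        self.frozen = np.asarray(frozen, dtype=bool).copy()
        if not (self.opinion.shape == self.attitude.shape == self.frozen.shape):
            raise ValueError("mismatched population array shapes")

    @classmethod
    def from_states(cls, states: Iterable[AgentState]) -> "Population":
        states = list(states)
        return cls(
            np.array([s.opinion for s in states], dtype=float),
            np.array([s.attitude for s in states], dtype=float),
            np.array([s.frozen for s in states], dtype=bool),
        )

    def __len__(self) -> int:
        return self.opinion.shape[0]

    def __getitem__(self, i):  # type: ignore[override]
        if isinstance(i, slice):
            return Population(self.opinion[i], self.attitude[i], self.frozen[i])
        return AgentState(
            opinion=float(self.opinion[i]),
            attitude=float(self.attitude[i]),
            frozen=bool(self.frozen[i]),
        )

    def __iter__(self) -> Iterator[AgentState]:
        for i in range(len(self)):
            yield self[i]

    def copy(self) -> "Population":
        return Population(self.opinion, self.attitude, self.frozen)

    @property
    def n_frozen(self) -> int:
        return int(self.frozen.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Population):
            return NotImplemented
        return (
            np.array_equal(self.opinion, other.opinion)
            and np.array_equal(self.attitude, other.attitude)
            and np.array_equal(self.frozen, other.frozen)
        )


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

class SocialNetwork:
    """Undirected simple graph over ``n_agents`` agents.

    Offers the derived queries the dynamics needs: geodesic distances,
    shells ``S_n(i)`` (agents at distance exactly ``n`` from ``i``) and the
    per-agent maximum shell index.  Distance information is cached and
    invalidated on any edge mutation.
    """

    def __init__(self, n_agents: int, edges: Iterable[tuple[int, int]] = ()) -> None:
        if n_agents < 1:
            raise ConfigError(f"n_agents must be positive, got {n_agents}")
        self.n_agents = int(n_agents)
        self._adj: list[set[int]] = [set() for _ in range(self.n_agents)]
        self._version = 0
        self._dist: np.ndarray | None = None
        for i, j in edges:
            self.add_edge(i, j)

    # -- mutation ----------------------------------------------------------
    def _check_node(self, i: int) -> None:
        if not (0 <= i < self.n_agents):
            raise ConfigError(f"agent index {i} out of range [0, {self.n_agents})")

    def add_edge(self, i: int, j: int) -> None:
        self._check_node(i)
        self._check_node(j)
        if i == j:
            raise ConfigError("self-loops are not allowed")
        if j not in self._adj[i]:
            self._adj[i].add(j)
            self._adj[j].add(i)
            self._invalidate()

    def remove_edge(self, i: int, j: int) -> None:
        self._adj[i].discard(j)
        self._adj[j].discard(i)
        self._invalidate()

    def _invalidate(self) -> None:
        self._version += 1
        self._dist = None

    @property
    def version(self) -> int:
        """Monotone counter bumped on every edge mutation (for caching)."""
        return self._version

    # -- queries -----------------------------------------------------------
    def has_edge(self, i: int, j: int) -> bool:
        return j in self._adj[i]

    def neighbors(self, i: int) -> tuple[int, ...]:
        return tuple(sorted(self._adj[i]))

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self._adj], dtype=int)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {
            (i, j) for i in range(self.n_agents) for j in self._adj[i] if i < j
        }

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self._adj) // 2

    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_agents

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_agents, self.n_agents), dtype=float)
        for i in range(self.n_agents):
            for j in self._adj[i]:
                a[i, j] = 1.0
        return a

    def distance_matrix(self) -> np.ndarray:
        """All-pairs geodesic distances; ``inf`` for unreachable pairs."""
        if self._dist is None:
            if self.n_edges == 0:
                d = np.full((self.n_agents, self.n_agents), np.inf)
                np.fill_diagonal(d, 0.0)
            else:
                rows, cols = [], []
                for i in range(self.n_agents):
                    for j in self._adj[i]:
                        rows.append(i)
                        cols.append(j)
                g = csr_matrix(
                    (np.ones(len(rows)), (rows, cols)),
                    shape=(self.n_agents, self.n_agents),
                )
                d = shortest_path(g, method="D", unweighted=True, directed=False)
            self._dist = d
        return self._dist

    def geodesic_distance(self, i: int, j: int) -> float:
        return float(self.distance_matrix()[i, j])

    def shell(self, i: int, n: int) -> tuple[int, ...]:
        """Agents at geodesic distance exactly ``n`` from ``i``."""
        if n < 1:
            raise ConfigError("shell index must be >= 1")
        d = self.distance_matrix()[i]
        return tuple(np.flatnonzero(d == n).tolist())

    def max_shell_index(self, i: int) -> int:
        """Largest finite shell index around ``i`` (0 if isolated)."""
        d = self.distance_matrix()[i]
        finite = d[np.isfinite(d)]
        return int(finite.max()) if finite.size else 0

    def connected_components(self) -> list[set[int]]:
        if self.n_edges == 0:
            return [{i} for i in range(self.n_agents)]
        rows, cols = [], []
        for i in range(self.n_agents):
            for j in self._adj[i]:
                rows.append(i)
                cols.append(j)
        g = csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(self.n_agents, self.n_agents),
        )
        n, labels = _cc(g, directed=False)
        return [set(np.flatnonzero(labels == k).tolist()) for k in range(n)]

    def copy(self) -> "SocialNetwork":
        return SocialNetwork(self.n_agents, self.edges)

    # -- I/O ---------------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_agents))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g) -> "SocialNetwork":
        mapping = {v: k for k, v in enumerate(sorted(g.nodes()))}
        return cls(
            g.number_of_nodes(),
            [(mapping[u], mapping[v]) for u, v in g.edges()],
        )

    def to_edgelist_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for i, j in sorted(self.edges):
                fh.write(f"{i}\t{j}\n")

    @classmethod
    def from_edgelist_tsv(cls, path, n_agents: int | None = None) -> "SocialNetwork":
        edges = []
        top = -1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                i_s, j_s = line.split()[:2]
                i, j = int(i_s), int(j_s)
                edges.append((i, j))
                top = max(top, i, j)
        return cls(n_agents if n_agents is not None else top + 1, edges)

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SocialNetwork):
            return NotImplemented
        return self.n_agents == other.n_agents and self.edges == other.edges


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class ShellWeights:
    """Distance-weight rule for the long-range opinion.

    The raw weight of shell ``n`` is ``decay ** (n - 1)``; weights are then
    normalized per agent by the total raw weight mass of its shells at
    distance >= 2, so the weighted distant opinion is an average in
    ``[-1, 1]`` before scaling.  Effective weights are positive and strictly
    decreasing in ``n``.

    With ``degree_scaled`` (the default) the average is multiplied by
    ``scale * (degree_i + offset)``: an agent's reaction to the public
    opinion grows with its social embeddedness.  This degree tracking is
    what makes the response to the external drive asymmetric in the way the
    frozen-extreme dynamics needs: the long-range reaction of an agent can
    balance its pairwise discussions (whose strength is also proportional
    to degree) plus a bounded field contribution of at most ``offset``, so
    a drive stronger than ``offset`` towards the always-felt extreme (-1)
    decides every agent, while the drive towards +1 — which dies out near
    +1 — leaves negatively-disposed agents suspended.  With
    ``degree_scaled = False`` the multiplier is just ``scale``.
    """

    decay: float = 0.5
    scale: float = 1.0
    offset: float = 1.9
    degree_scaled: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.decay < 1.0):
            raise ConfigError("shell weight decay must lie in (0, 1)")
        if self.scale <= 0.0:
            raise ConfigError("shell weight scale must be positive")
        if self.degree_scaled and self.offset < 0.0:
            raise ConfigError("shell weight offset must be non-negative")

    def raw(self, n: int) -> float:
        return self.decay ** (n - 1)

    def agent_scale(self, degree: int) -> float:
        if self.degree_scaled:
            return self.scale * (degree + self.offset)
        return self.scale


@dataclass
class ModelParams:
    """All simulation constants.

    ``attitude`` samples are i.i.d. uniform on ``[-1, 1]`` (center 0, unit
    half-width); initial opinions are i.i.d. standard normal truncated to
    ``(-1, 1)``.  ``transactions_per_rewiring`` (``g``) opinion transactions
    happen between consecutive rewiring phases.
    """

    n_agents: int = 200
    mean_degree: float = 6.0
    field: float = 0.0
    closure_mix: float = 0.0
    transactions_per_rewiring: int = 100
    step_size: float = 0.01
    max_steps: int = 50_000
    links_per_event: Union[str, int] = "all"
    seed: int = 0
    shell_decay: float = 0.5
    shell_scale: float = 1.0
    shell_offset: float = 1.9
    shell_degree_scaled: bool = True
    shell_normalized: bool = True
    record_every: int = 100
    nn_degree_weighted: bool = True
    agreement_frozen_only: bool = False
    stop_when_all_frozen: bool = True

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ConfigError(f"n_agents must be >= 2, got {self.n_agents}")
        if not (0.0 < self.mean_degree < self.n_agents - 1 + 1e-12):
            raise ConfigError(
                f"mean_degree must lie in (0, n_agents - 1], got {self.mean_degree}"
            )
        if not (0.0 <= self.closure_mix <= 1.0):
            raise ConfigError(f"closure_mix must lie in [0, 1], got {self.closure_mix}")
        if self.step_size <= 0.0:
            raise ConfigError(f"step_size must be > 0, got {self.step_size}")
        if self.transactions_per_rewiring < 1:
            raise ConfigError("transactions_per_rewiring must be >= 1")
        if self.max_steps < 0:
            raise ConfigError("max_steps must be >= 0")
        if isinstance(self.links_per_event, str):
            if self.links_per_event != "all":
                raise ConfigError(
                    f"links_per_event must be 'all' or a positive integer, "
                    f"got {self.links_per_event!r}"
                )
        elif self.links_per_event < 1:
            raise ConfigError("links_per_event must be >= 1")
        if self.record_every < 1:
            raise ConfigError("record_every must be >= 1")

    @property
    def edge_probability(self) -> float:
        return min(1.0, self.mean_degree / (self.n_agents - 1))

    def shell_weights(self) -> ShellWeights:
        return ShellWeights(
            decay=self.shell_decay,
            scale=self.shell_scale,
            offset=self.shell_offset,
            degree_scaled=self.shell_degree_scaled,
            normalized=self.shell_normalized,
        )

    # -- config round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        text = open(path).read()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a flat mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        if str(path).endswith(".json"):
            open(path, "w").write(json.dumps(self.to_dict(), indent=2))
        else:
            import yaml

            open(path, "w").write(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


# --------------------------------------------------------------------------
# interaction kernels
# --------------------------------------------------------------------------

def _signp(x: float) -> float:
    """Sign with the measure-zero convention sign(0) = +1."""
    return 1.0 if x >= 0.0 else -1.0


def _default_long_range(attitude: float, opinion: float, m_i: float) -> float:
    return attitude * opinion * abs(m_i)


def _default_pair(x_i: float, x_j: float) -> float:
    return _signp(x_i) * (abs(x_i + x_j) - abs(x_i - x_j)) / 2.0


def _default_field(x_i: float, h: float) -> float:
    return 0.5 * h * (1.0 - x_i)


@dataclass(frozen=True)
class InteractionKernels:
    """Pluggable algebraic forms of the three opinion forces.

    ``pair_term`` must reinforce same-sign pairs and weaken opposite-sign
    pairs; ``field_term`` must vanish at ``h = 0``, be linear in ``x_i`` and
    (for ``h > 0``) weaken as ``x_i`` grows; ``long_range_term`` must be
    proportional to the attitude and vanish with ``m_i``.
    """

    long_range_term: Callable[[float, float, float], float] = _default_long_range
    pair_term: Callable[[float, float], float] = _default_pair
    field_term: Callable[[float, float], float] = _default_field

    @property
    def is_default(self) -> bool:
        return (
            self.long_range_term is _default_long_range
            and self.pair_term is _default_pair
            and self.field_term is _default_field
        )


def default_kernels() -> InteractionKernels:
    return InteractionKernels()


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def _sample_truncated_normal(rng: np.random.Generator, size: int) -> np.ndarray:
    """Standard normal truncated to the open interval (-1, 1)."""
    x = truncnorm.rvs(-1.0, 1.0, size=size, random_state=rng)
    # rvs lands on the closed endpoints with probability zero; nudge just in
    # case so the open-interval contract holds exactly.
    return np.clip(x, -1.0 + 1e-12, 1.0 - 1e-12)


def init_system(params: ModelParams) -> tuple[SocialNetwork, Population]:
    """Erdős–Rényi network plus i.i.d. attitudes and initial opinions.

    Edge probability is ``mean_degree / (n_agents - 1)``.  The draw order is
    fixed (edges, then attitudes, then opinions) so identical parameters and
    seed give bit-identical systems.
    """
    rng = np.random.default_rng(params.seed)
    return _init_with_rng(params, rng)


# --------------------------------------------------------------------------
# long-range opinion
# --------------------------------------------------------------------------

def long_range_opinion(
    net: SocialNetwork,
    states: Population,
    i: int,
    weights: ShellWeights | None = None,
) -> float:
    """Distance-weighted opinion of all agents at geodesic distance >= 2.

    Direct neighbours and ``i`` itself are excluded (they enter through the
    pair term).  Returns 0 for agents with no shell beyond ``n = 1``.
    """
    if weights is None:
        weights = ShellWeights()
    net._check_node(i)
    d = net.distance_matrix()[i]
    far = np.isfinite(d) & (d >= 2)
    if not far.any():
        return 0.0
    raw = weights.decay ** (d[far] - 1.0)
    total = float(raw @ states.opinion[far])
    if weights.normalized:
        total /= raw.sum()
    return weights.agent_scale(net.degree(i)) * total


def _shell_weight_operator(net: SocialNetwork, weights: ShellWeights) -> np.ndarray:
    """Matrix ``B`` with ``m = B @ x``; row i holds agent i's shell weights."""
    d = net.distance_matrix()
    with np.errstate(invalid="ignore"):
        b = np.where(np.isfinite(d) & (d >= 2), weights.decay ** (d - 1.0), 0.0)
    if weights.normalized:
        z = b.sum(axis=1, keepdims=True)
        z[z == 0.0] = 1.0
        b = b / z
    scales = np.array(
        [weights.agent_scale(net.degree(i)) for i in range(net.n_agents)]
    )
    return scales[:, None] * b


# --------------------------------------------------------------------------
# derivatives and stepping
# --------------------------------------------------------------------------

def opinion_derivative(
    i: int,
    states: Population,
    net: SocialNetwork,
    kernels: InteractionKernels,
    h: float,
    weights: ShellWeights | None = None,
) -> float:
    """Instantaneous opinion velocity of unfrozen agent ``i``."""
    if states.frozen[i]:
        raise LogicError(f"opinion_derivative called on frozen agent {i}")
    m_i = long_range_opinion(net, states, i, weights)
    x_i = float(states.opinion[i])
    total = kernels.long_range_term(float(states.attitude[i]), x_i, m_i)
    for j in net.neighbors(i):
        total += kernels.pair_term(x_i, float(states.opinion[j]))
    total += kernels.field_term(x_i, h)
    return total


def _derivatives_vectorized(
    states: Population,
    adjacency: np.ndarray,
    shell_op: np.ndarray,
    h: float,
) -> np.ndarray:
    """All-agent derivative under the default kernels (used by the fast path)."""
    x = states.opinion
    m = shell_op @ x
    long_range = states.attitude * x * np.abs(m)
    # pair term: sum_j A_ij * sign(x_j) * min(|x_i|, |x_j|), which is the
    # closed form of sign(x_i) * (|x_i + x_j| - |x_i - x_j|) / 2
    ax = np.abs(x)
    mins = np.minimum.outer(ax, ax)
    pair = np.einsum("ij,ij,j->i", adjacency, mins, np.sign(x))
    fld = 0.5 * h * (1.0 - x)
    return long_range + pair + fld


def step_opinions(
    states: Population,
    net: SocialNetwork,
    kernels: InteractionKernels,
    params: ModelParams,
    *,
    _adjacency: np.ndarray | None = None,
    _shell_op: np.ndarray | None = None,
) -> Population:
    """One explicit-Euler transaction of size ``step_size``.

    Any agent whose updated opinion reaches or exceeds +/-1 in magnitude is
    clamped to the extreme value attained and frozen there; frozen agents are
    untouched but keep influencing their neighbours.  Returns a new
    Population (the input is not mutated).
    """
    out = states.copy()
    if params.step_size == 0.0:
        return out
    unfrozen = ~states.frozen
    if not unfrozen.any():
        return out

    if kernels.is_default:
        adjacency = _adjacency if _adjacency is not None else net.adjacency_matrix()
        shell_op = (
            _shell_op
            if _shell_op is not None
            else _shell_weight_operator(net, params.shell_weights())
        )
        deriv = _derivatives_vectorized(states, adjacency, shell_op, params.field)
    else:
        deriv = np.zeros(len(states))
        for i in np.flatnonzero(unfrozen):
            deriv[i] = opinion_derivative(
                int(i), states, net, kernels, params.field, params.shell_weights()
            )

    x_new = states.opinion + params.step_size * deriv
    x_new = np.where(unfrozen, x_new, states.opinion)
    hit = unfrozen & (np.abs(x_new) >= 1.0)
    x_new[hit] = np.sign(x_new[hit])
    out.opinion = x_new
    out.frozen = states.frozen | hit
    return out


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory summary of a full run."""

    params: ModelParams
    network: SocialNetwork
    states: Population
    records: list  # list[ObservableRecord]
    n_steps: int
    n_rewirings: int
    converged: bool  # all agents frozen before max_steps


def run_simulation(
    params: ModelParams,
    kernels: InteractionKernels | None = None,
    *,
    record_observables: bool = True,
) -> SimulationResult:
    """Alternate ``g`` opinion transactions with one rewiring phase.

    Runs until ``max_steps`` transactions have happened or every agent is
    frozen.  Observables are recorded every ``record_every`` transactions and
    at the final state.  Fully reproducible from ``params.seed``: the single
    RNG stream is consumed in a fixed order (initialization first, then one
    block per rewiring phase).
    """
    from . import observables as obs
    from . import rewiring as rw

    if kernels is None:
        kernels = default_kernels()
    rng = np.random.default_rng(params.seed)
    net, states = _init_with_rng(params, rng)
    return _run_dynamics(
        net, states, params, kernels, rng, record_observables=record_observables
    )


def _run_dynamics(
    net: SocialNetwork,
    states: Population,
    params: ModelParams,
    kernels: InteractionKernels,
    rng: np.random.Generator,
    *,
    record_observables: bool = True,
) -> SimulationResult:
    """Transaction/rewiring loop on an already-initialized system."""
    from . import observables as obs
    from . import rewiring as rw

    weights = params.shell_weights()
    records: list = []
    if record_observables:
        records.append(obs.summarize(net, states, params, time=0))

    adjacency = net.adjacency_matrix()
    shell_op = _shell_weight_operator(net, weights)
    net_version = net.version

    n_rewirings = 0
    step = 0
    converged = bool(states.frozen.all())
    while step < params.max_steps and not converged:
        step += 1
        states = step_opinions(
            states, net, kernels, params, _adjacency=adjacency, _shell_op=shell_op
        )
        if step % params.transactions_per_rewiring == 0:
            rw.rewire_phase(states, net, params, rng)
            n_rewirings += 1
        if net.version != net_version:
            adjacency = net.adjacency_matrix()
            shell_op = _shell_weight_operator(net, weights)
            net_version = net.version
        if record_observables and step % params.record_every == 0:
            records.append(obs.summarize(net, states, params, time=step))
        if params.stop_when_all_frozen and states.frozen.all():
            converged = True

    if record_observables and (not records or records[-1].time != step):
        records.append(obs.summarize(net, states, params, time=step))

    return SimulationResult(
        params=params,
        network=net,
        states=states,
        records=records,
        n_steps=step,
        n_rewirings=n_rewirings,
        converged=converged,
    )


def _init_with_rng(
    params: ModelParams, rng: np.random.Generator
) -> tuple[SocialNetwork, Population]:
    """Like :func:`init_system` but drawing from an existing stream."""
    n = params.n_agents
    p = params.edge_probability
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < p
    net = SocialNetwork(n, zip(iu[mask].tolist(), ju[mask].tolist()))
    attitude = rng.uniform(-1.0, 1.0, size=n)
    opinion = _sample_truncated_normal(rng, n)
    return net, Population(opinion, attitude)
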