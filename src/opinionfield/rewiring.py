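"""Slow-timescale network co-evolution: disagreement cutting plus closure.

Every rewiring phase each *undecided* (unfrozen) agent cuts its most
disagreeing links and creates the same number of new ones, either by triadic
closure (a "friend of a friend", ranked by how much the new contact would
help the agent towards total conviction) or by focal closure (a distant agent
with a similar opinion).  The mechanism is drawn per agent: focal with
probability ``closure_mix`` (q), triadic otherwise.

The phase is conceptually simultaneous: all plans are built against a frozen
pre-phase snapshot of the network, then all cuts are applied as a set union
and all creations afterwards, with duplicate proposals collapsing onto a
single edge.  Because two neighbours may both cut the same link but each
create fresh ones, the total edge count is free to drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelParams, Population, SocialNetwork

__all__ = [
    "RewiringPlan",
    "select_cut_links",
    "closure_candidates",
    "build_plan",
    "apply_plans",
    "rewire_phase",
]


@dataclass
class RewiringPlan:
    """One agent's intended cuts and creations for a phase."""

    agent: int
    cuts: tuple[int, ...]
    creations: tuple[int, ...]
    mechanism: str  # "triadic" | "focal"
    shortfall: int = 0  # requested creations that had no candidate


def _ranked(
    items: list[int],
    score: np.ndarray,
    rng: np.random.Generator,
) -> list[int]:
    """Sort ``items`` by descending score, ties broken by a seeded draw."""
    if not items:
        return []
    tiebreak = rng.random(len(items))
    order = np.lexsort((tiebreak, -score))
    return [items[k] for k in order]


def select_cut_links(
    i: int,
    states: Population,
    net: SocialNetwork,
    links_per_event,
    rng: np.random.Generator | None = None,
) -> tuple[int, ...]:
    """Neighbours of ``i`` in decreasing order of opinion difference.

    ``links_per_event = "all"`` returns the full (sorted) neighbour list,
    otherwise the first ``links_per_event`` entries.  Equal differences are
    ordered by a seeded random tie-break.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    neigh = list(net.neighbors(i))
    if not neigh:
        return ()
    diffs = np.abs(states.opinion[i] - states.opinion[neigh])
    ranked = _ranked(neigh, diffs, rng)
    if links_per_event == "all":
        return tuple(ranked)
    return tuple(ranked[: int(links_per_event)])


def closure_candidates(
    i: int,
    states: Population,
    net: SocialNetwork,
    mechanism: str,
    rng: np.random.Generator | None = None,
) -> tuple[int, ...]:
    """Ranked link-creation candidates for agent ``i``.

    triadic
        Second neighbours (geodesic distance exactly 2), ranked by the
        conviction-helping score ``|x_i + x_j|`` descending.
    focal
        Agents at distance >= 3 or in other components, ranked by opinion
        similarity, i.e. ``|x_i - x_j|`` ascending.

    Both exclude ``i`` itself and its current neighbours.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    d = net.distance_matrix()[i]
    if mechanism == "triadic":
        cand = np.flatnonzero(d == 2).tolist()
        score = np.abs(states.opinion[i] + states.opinion[cand]) if cand else None
    elif mechanism == "focal":
        far = (~np.isfinite(d)) | (d >= 3)
        far[i] = False
        cand = np.flatnonzero(far).tolist()
        score = -np.abs(states.opinion[i] - states.opinion[cand]) if cand else None
    else:
        raise ValueError(f"unknown closure mechanism {mechanism!r}")
    if not cand:
        return ()
    return tuple(_ranked(cand, score, rng))


def build_plan(
    i: int,
    states: Population,
    net: SocialNetwork,
    params: ModelParams,
    rng: np.random.Generator,
) -> RewiringPlan:
    """Draw a mechanism and assemble one agent's plan from the snapshot.

    RNG consumption order per agent: mechanism draw, cut tie-breaks,
    candidate tie-breaks.
    """
    mech = "focal" if rng.random() < params.closure_mix else "triadic"
    cuts = select_cut_links(i, states, net, params.links_per_event, rng)
    creations: tuple[int, ...] = ()
    shortfall = 0
    if cuts:
        cands = closure_candidates(i, states, net, mech, rng)
        creations = cands[: len(cuts)]
        shortfall = len(cuts) - len(creations)
    return RewiringPlan(
        agent=i, cuts=cuts, creations=creations, mechanism=mech, shortfall=shortfall
    )


def apply_plans(net: SocialNetwork, plans: list[RewiringPlan]) -> SocialNetwork:
    """Apply all cuts (set union) and then all creations to ``net`` in place.

    Order-independent: the result depends only on the set of plans, so
    permuting the plan list leaves the final edge set unchanged.
    """
    cut_edges = set()
    new_edges = set()
    for p in plans:
        for j in p.cuts:
            cut_edges.add((min(p.agent, j), max(p.agent, j)))
        for j in p.creations:
            new_edges.add((min(p.agent, j), max(p.agent, j)))
    for i, j in cut_edges:
        net.remove_edge(i, j)
    for i, j in new_edges:
        net.add_edge(i, j)
    return net


def rewire_phase(
    states: Population,
    net: SocialNetwork,
    params: ModelParams,
    rng: np.random.Generator,
    log: list | None = None,
) -> SocialNetwork:
    """One simultaneous rewiring phase over all undecided agents.

    Frozen agents initiate nothing but may be cut from or linked to.  Agents
    are visited in index order purely for RNG reproducibility; the outcome is
    order-independent given the per-agent draws.  If ``log`` is given, one
    ``(agent, mechanism, n_cut, n_created)`` tuple is appended per initiator.
    """
    plans = []
    for i in range(len(states)):
        if states.frozen[i]:
            continue
        plan = build_plan(i, states, net, params, rng)
        plans.append(plan)
        if log is not None:
            log.append((i, plan.mechanism, len(plan.cuts), len(plan.creations)))
    return apply_plans(net, plans)
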