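"""Agent group classification and per-step summary quantities.

Agents fall into eight groups: four opinion classes (expert = frozen at +1,
fundamentalist = frozen at -1, ignorant with positive / negative opinion for
the undecided) crossed with the sign of the quenched attitude.  Measure-zero
boundaries are fixed for determinism: opinion 0 counts as positive lean,
attitude 0 as positive attitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import AgentState, ModelParams, Population, SocialNetwork

__all__ = [
    "GroupLabel",
    "ObservableRecord",
    "ALL_GROUPS",
    "OPINION_CLASSES",
    "classify",
    "classify_all",
    "summarize",
    "agreement_count_fraction",
    "group_internal_mean_degree",
    "undecided_bridging",
]

OPINION_CLASSES = (
    "expert",
    "ignorant_positive",
    "ignorant_negative",
    "fundamentalist",
)
ATTITUDE_SIGNS = ("positive", "negative")


@dataclass(frozen=True)
class GroupLabel:
    opinion_class: str
    attitude_sign: str

    def __post_init__(self) -> None:
        if self.opinion_class not in OPINION_CLASSES:
            raise ValueError(f"bad opinion class {self.opinion_class!r}")
        if self.attitude_sign not in ATTITUDE_SIGNS:
            raise ValueError(f"bad attitude sign {self.attitude_sign!r}")


ALL_GROUPS = tuple(
    GroupLabel(s, a) for s in OPINION_CLASSES for a in ATTITUDE_SIGNS
)


def classify(state: AgentState) -> GroupLabel:
    """Map one agent onto its (opinion class, attitude sign) group."""
    if state.frozen:
        cls = "expert" if state.opinion > 0 else "fundamentalist"
    else:
        cls = "ignorant_positive" if state.opinion >= 0 else "ignorant_negative"
    sign = "positive" if state.attitude >= 0 else "negative"
    return GroupLabel(cls, sign)


def classify_all(states: Population) -> list[GroupLabel]:
    return [classify(states[i]) for i in range(len(states))]


@dataclass
class ObservableRecord:
    """Snapshot of all summary quantities at one recording step.

    ``group_fractions`` and ``degree_contributions`` each sum to 1 (the
    latter whenever the mean degree is positive); ``nn_avg_opinion`` entries
    are ``None`` where undefined (group empty or entirely isolated).
    """

    time: int
    group_fractions: dict = field(default_factory=dict)
    degree_contributions: dict = field(default_factory=dict)
    nn_avg_opinion: dict = field(default_factory=dict)
    mean_degree: float = 0.0
    clustering: float = 0.0
    undecided_fraction: float = 0.0
    agreement_fraction: float | None = None


def agreement_count_fraction(
    states: Population, frozen_only: bool = False
) -> float | None:
    """Model-side agreement fraction n+ = (#x>0) / (#x>0 + #x<0).

    With ``frozen_only`` the count is restricted to decided agents,
    mirroring a survey that drops "do not know" answers.  ``None`` when no
    agent has a nonzero opinion.
    """
    x = states.opinion[states.frozen] if frozen_only else states.opinion
    pos = int((x > 0).sum())
    neg = int((x < 0).sum())
    if pos + neg == 0:
        return None
    return pos / (pos + neg)


def _nn_average(
    net: SocialNetwork,
    states: Population,
    members: np.ndarray,
    degree_weighted: bool,
) -> float | None:
    """Group-level weighted nearest-neighbours' average opinion."""
    vals = []
    weights = []
    for i in members:
        neigh = net.neighbors(int(i))
        if not neigh:
            continue  # isolated agents are excluded from the aggregate
        vals.append(float(np.mean(states.opinion[list(neigh)])))
        weights.append(float(len(neigh)) if degree_weighted else 1.0)
    if not vals:
        return None
    return float(np.average(vals, weights=weights))


def summarize(
    net: SocialNetwork,
    states: Population,
    params: ModelParams | None = None,
    time: int = 0,
) -> ObservableRecord:
    """Compute every recorded quantity for the current system state."""
    import networkx as nx

    degree_weighted = params.nn_degree_weighted if params is not None else True
    frozen_only = params.agreement_frozen_only if params is not None else False

    n = len(states)
    labels = classify_all(states)
    degs = net.degrees()
    kbar = float(degs.mean())

    fractions: dict = {}
    contributions: dict = {}
    nn: dict = {}
    for g in ALL_GROUPS:
        members = np.array(
            [i for i, lab in enumerate(labels) if lab == g], dtype=int
        )
        frac = len(members) / n
        fractions[g] = frac
        if kbar > 0 and len(members):
            contributions[g] = float(degs[members].mean()) * frac / kbar
        else:
            contributions[g] = 0.0
        nn[g] = _nn_average(net, states, members, degree_weighted)

    clustering = nx.average_clustering(net.to_networkx())
    return ObservableRecord(
        time=time,
        group_fractions=fractions,
        degree_contributions=contributions,
        nn_avg_opinion=nn,
        mean_degree=kbar,
        clustering=float(clustering),
        undecided_fraction=float((~states.frozen).mean()),
        agreement_fraction=agreement_count_fraction(states, frozen_only),
    )


# --------------------------------------------------------------------------
# structural diagnostics used by the asymmetry analyses
# --------------------------------------------------------------------------

def group_internal_mean_degree(
    net: SocialNetwork, states: Population, opinion_class: str
) -> float | None:
    """Mean number of links a member has to other members of its class.

    ``None`` when the class is empty.
    """
    labels = classify_all(states)
    members = {i for i, lab in enumerate(labels) if lab.opinion_class == opinion_class}
    if not members:
        return None
    internal = [
        sum(1 for j in net.neighbors(i) if j in members) for i in members
    ]
    return float(np.mean(internal))


def undecided_bridging(
    net: SocialNetwork, states: Population
) -> tuple[float, float] | None:
    """Fraction of fundamentalist-expert shortest paths touching an
    undecided agent, paired with the undecided population share.

    Returns ``None`` when there is no connected fundamentalist-expert pair.
    """
    import networkx as nx

    labels = classify_all(states)
    experts = [i for i, lab in enumerate(labels) if lab.opinion_class == "expert"]
    funds = [
        i for i, lab in enumerate(labels) if lab.opinion_class == "fundamentalist"
    ]
    if not experts or not funds:
        return None
    g = net.to_networkx()
    undecided = set(np.flatnonzero(~states.frozen).tolist())
    touched = 0
    total = 0
    for f in funds:
        try:
            paths = nx.single_source_shortest_path(g, f)
        except nx.NetworkXError:  # pragma: no cover
            continue
        for e in experts:
            if e not in paths:
                continue
            total += 1
            if any(v in undecided for v in paths[e][1:-1]):
                touched += 1
    if total == 0:
        return None
    return touched / total, float((~states.frozen).mean())


def record_to_rows(record: ObservableRecord) -> list[dict]:
    """Flatten a record into tidy rows (one per group, scalars repeated)."""
    rows = []
    for g in ALL_GROUPS:
        rows.append(
            {
                "time": record.time,
                "opinion_class": g.opinion_class,
                "attitude_sign": g.attitude_sign,
                "group_fraction": record.group_fractions[g],
                "degree_contribution": record.degree_contributions[g],
                "nn_avg_opinion": record.nn_avg_opinion[g],
                "mean_degree": record.mean_degree,
                "clustering": record.clustering,
                "undecided_fraction": record.undecided_fraction,
                "agreement_fraction": record.agreement_fraction,
            }
        )
    return rows
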