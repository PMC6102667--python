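"""Driver-variable control of Boolean network dynamics.

A driver set ``D`` is a subset of nodes open to instantaneous bit-flip
interventions.  Flipping any non-empty subset of ``D`` moves the system
between configurations, so the controlled state-transition graph (CSTG)
adds, to every configuration, edges to the ``2**|D| - 1`` configurations
that differ only on ``D``.  Control quality is quantified by:

* ``r(G_D, x)`` — fraction of the other ``2**N - 1`` configurations
  reachable from ``x`` along directed CSTG paths;
* ``R̄_D`` — the mean of ``r`` over all configurations, and
  ``C̄_D = R̄_D - R̄_∅`` — the gain over the uncontrolled dynamics;
* the controlled attractor graph (CAG), whose vertices are the attractors
  of the uncontrolled network with an edge ``κ -> γ`` when some CSTG path
  leads from cycle ``κ`` into cycle ``γ``, and ``Ā_D`` — the mean fraction
  of other attractors reachable in the CAG.

``R̄_D = 1`` iff the CSTG is strongly connected (full controllability).
Driver-set heuristics from network control theory are included: unmatched
nodes of a maximum matching (structural controllability) and a minimum
dominating set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import networkx as nx

from .exceptions import StructuralError
from .network import (
    Attractor,
    BooleanNetwork,
    DEFAULT_EXHAUSTIVE_LIMIT,
    TransitionGraph,
    build_stg,
    find_attractors,
)


@dataclass(frozen=True)
class DriverSet:
    """A subset of nodes subject to bit-flip interventions."""

    nodes: frozenset[str]
    method: str = "manual"
    exact: bool = True

    def __iter__(self):
        return iter(sorted(self.nodes))

    def __len__(self):
        return len(self.nodes)


class ControlledAttractorGraph(nx.DiGraph):
    """Digraph on attractor indices; ``graph['attractors']`` lists them."""

    @property
    def attractors(self) -> tuple[Attractor, ...]:
        return self.graph["attractors"]


@dataclass(frozen=True)
class ControlReport:
    """Reachability-based control measures for one driver set.

    All fractions are exact rationals.  ``per_configuration`` maps each
    configuration to ``(r_controlled, r_natural)`` when requested.
    """

    drivers: tuple[str, ...]
    mean_reachable: Fraction          # R̄_D
    mean_reachable_empty: Fraction    # R̄_∅
    mean_controlled: Fraction         # C̄_D
    mean_reachable_attractors: Fraction | None = None  # Ā_D
    per_configuration: Mapping[int, tuple[Fraction, Fraction]] | None = None


def _driver_indices(net: BooleanNetwork, drivers: Iterable[str]) -> list[int]:
    if isinstance(drivers, DriverSet):
        drivers = drivers.nodes
    names = list(drivers)
    unknown = [d for d in names if d not in net.names]
    if unknown:
        raise StructuralError(f"unknown driver node(s): {sorted(unknown)}")
    return sorted(net.index(d) for d in set(names))


def build_cstg(
    net: BooleanNetwork,
    drivers: Iterable[str] = (),
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> TransitionGraph:
    """STG plus controlled bit-flip edges over the driver set.

    Interventions are standalone instantaneous transitions: the flip moves
    the system to the perturbed configuration, from which natural dynamics
    resume.  From every configuration there are exactly ``2**|D| - 1``
    controlled transitions (an edge coinciding with the natural transition
    keeps ``kind='natural'`` and gains ``controlled=True``).
    """
    g = build_stg(net, limit=limit)
    idx = _driver_indices(net, drivers)
    if not idx:
        return g
    masks = []
    for r in range(1, len(idx) + 1):
        for comb in itertools.combinations(idx, r):
            m = 0
            for i in comb:
                m |= 1 << (net.N - 1 - i)
            masks.append(m)
    for a in range(2 ** net.N):
        for m in masks:
            b = a ^ m
            if g.has_edge(a, b):
                g.edges[a, b]["controlled"] = True
            else:
                g.add_edge(a, b, kind="controlled", controlled=True)
    return g


def reachability_fractions(g: TransitionGraph) -> dict[int, Fraction]:
    """Fraction of other configurations reachable from each vertex.

    Computed by condensing the graph into its strongly connected
    components and propagating reachable-set bitmasks up the reverse
    topological order.
    """
    n_conf = g.number_of_nodes()
    cond = nx.condensation(g)
    masks: dict[int, int] = {}
    for scc in reversed(list(nx.topological_sort(cond))):
        m = 0
        for v in cond.nodes[scc]["members"]:
            m |= 1 << v
        for succ in cond.successors(scc):
            m |= masks[succ]
        masks[scc] = m
    out: dict[int, Fraction] = {}
    denom = n_conf - 1
    for scc, data in cond.nodes(data=True):
        for v in data["members"]:
            # exclude the configuration itself from its reachable count
            reach = bin(masks[scc]).count("1") - 1
            out[v] = Fraction(reach, denom) if denom else Fraction(0)
    return out


def control_measures(
    net: BooleanNetwork,
    drivers: Iterable[str],
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
    per_configuration: bool = False,
) -> ControlReport:
    """Mean fractions of reachable (``R̄_D``) and controlled (``C̄_D``) configurations."""
    r_nat = reachability_fractions(build_stg(net, limit=limit))
    r_ctl = reachability_fractions(build_cstg(net, drivers, limit=limit))
    n = 2 ** net.N
    mean_ctl = sum(r_ctl.values(), Fraction(0)) / n
    mean_nat = sum(r_nat.values(), Fraction(0)) / n
    per = (
        {c: (r_ctl[c], r_nat[c]) for c in range(n)} if per_configuration else None
    )
    if isinstance(drivers, DriverSet):
        names = tuple(sorted(drivers.nodes))
    else:
        names = tuple(sorted(set(drivers)))
    return ControlReport(
        drivers=names,
        mean_reachable=mean_ctl,
        mean_reachable_empty=mean_nat,
        mean_controlled=mean_ctl - mean_nat,
        per_configuration=per,
    )


def build_cag(
    net: BooleanNetwork,
    drivers: Iterable[str],
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> ControlledAttractorGraph:
    """Controlled attractor graph: which attractors can steer into which.

    Vertices are the attractors of the *uncontrolled* network; an edge
    ``κ -> γ`` (κ != γ) records a CSTG path from cycle κ to cycle γ.  Cycle
    members are mutually reachable, so membership of the path's endpoints
    within their cycles is immaterial.  Self-edges are not stored.
    """
    attractors = sorted(
        find_attractors(net, method="exhaustive", limit=limit),
        key=lambda a: a.configurations,
    )
    cstg = build_cstg(net, drivers, limit=limit)
    cond = nx.condensation(cstg)
    masks: dict[int, int] = {}
    for scc in reversed(list(nx.topological_sort(cond))):
        m = 0
        for v in cond.nodes[scc]["members"]:
            m |= 1 << v
        for succ in cond.successors(scc):
            m |= masks[succ]
        masks[scc] = m
    scc_of = cond.graph["mapping"]
    cag = ControlledAttractorGraph(attractors=tuple(attractors))
    cag.add_nodes_from(range(len(attractors)))
    for ki, a in enumerate(attractors):
        reach = masks[scc_of[a.configurations[0]]]
        for gi, b in enumerate(attractors):
            if gi != ki and reach & (1 << b.configurations[0]):
                cag.add_edge(ki, gi)
    return cag


def attractor_control(
    net: BooleanNetwork,
    drivers: Iterable[str],
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> Fraction:
    """Mean fraction of other attractors reachable through interventions (``Ā_D``).

    With a single attractor there is nothing left to reach and the measure
    is defined as 1 (the fully-controlled value).
    """
    cag = build_cag(net, drivers, limit=limit)
    n_att = cag.number_of_nodes()
    if n_att == 1:
        return Fraction(1)
    total = sum(Fraction(cag.out_degree(k), n_att - 1) for k in cag.nodes)
    return total / n_att


def control_report(
    net: BooleanNetwork,
    drivers: Iterable[str],
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
    per_configuration: bool = False,
) -> ControlReport:
    """Full report: ``R̄_D``, ``C̄_D`` and ``Ā_D`` for one driver set."""
    base = control_measures(net, drivers, limit=limit, per_configuration=per_configuration)
    return ControlReport(
        drivers=base.drivers,
        mean_reachable=base.mean_reachable,
        mean_reachable_empty=base.mean_reachable_empty,
        mean_controlled=base.mean_controlled,
        mean_reachable_attractors=attractor_control(net, drivers, limit=limit),
        per_configuration=base.per_configuration,
    )


def driver_sweep(
    net: BooleanNetwork,
    max_size: int = 4,
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> list[ControlReport]:
    """Reports for every driver subset of size <= ``max_size`` (combinatorial guard)."""
    reports = []
    for r in range(0, max_size + 1):
        for comb in itertools.combinations(net.names, r):
            reports.append(control_report(net, comb, limit=limit))
    return reports


# ---------------------------------------------------------------------------
# Driver-set approximations from the interaction graph
# ---------------------------------------------------------------------------

def _maximum_matching(net: BooleanNetwork) -> dict[str, str]:
    """Deterministic maximum bipartite matching on the out/in split of ``C``.

    Kuhn's augmenting-path algorithm over out-copies (left) and in-copies
    (right), scanning nodes and neighbours in declaration order.  Returns
    the matching as ``{left: right}``; self-edges are matchable.
    """
    order = list(net.names)
    succ: dict[str, list[str]] = {u: [] for u in order}
    for lut in net.nodes:
        for inp in lut.input_names:
            if lut.node_name not in succ[inp]:
                succ[inp].append(lut.node_name)
    for u in order:
        succ[u].sort(key=order.index)
    match_right: dict[str, str] = {}  # in-copy -> out-copy

    def try_augment(u: str, seen: set[str]) -> bool:
        for v in succ[u]:
            if v in seen:
                continue
            seen.add(v)
            if v not in match_right or try_augment(match_right[v], seen):
                match_right[v] = u
                return True
        return False

    for u in order:
        try_augment(u, set())
    return {u: v for v, u in match_right.items()}


def sc_driver_set(net: BooleanNetwork) -> DriverSet:
    """Driver nodes by structural controllability: unmatched in-copies.

    Nodes whose in-copy is left unmatched by a maximum matching on the
    bipartite representation of the interaction graph must receive
    independent control signals.  With a perfect matching the single
    first-declared node is returned.
    """
    matching = _maximum_matching(net)
    matched_targets = set(matching.values())
    unmatched = [n for n in net.names if n not in matched_targets]
    if not unmatched:
        unmatched = [net.names[0]]
    return DriverSet(frozenset(unmatched), method="structural_controllability")


def mds_driver_set(net: BooleanNetwork, exact_limit: int = 25) -> DriverSet:
    """Minimum dominating set of the interaction graph.

    A set ``S`` dominates the network when every node is in ``S`` or has an
    incoming edge from ``S``.  For ``N <= exact_limit`` the lexicographically
    first minimum-cardinality set is found by exhaustive search; larger
    networks fall back to the standard greedy cover (flagged ``exact=False``).
    """
    names = list(net.names)
    n = len(names)
    dominated_by = [1 << i for i in range(n)]  # every node dominates itself
    for lut in net.nodes:
        tgt = net.index(lut.node_name)
        for inp in lut.input_names:
            dominated_by[net.index(inp)] |= 1 << tgt
    full = (1 << n) - 1

    if n <= exact_limit:
        for size in range(0, n + 1):
            for comb in itertools.combinations(range(n), size):
                cover = 0
                for i in comb:
                    cover |= dominated_by[i]
                if cover == full:
                    return DriverSet(
                        frozenset(names[i] for i in comb), method="minimum_dominating_set"
                    )
    # greedy fallback
    cover, chosen = 0, []
    while cover != full:
        best = max(
            range(n),
            key=lambda i: (bin(dominated_by[i] & ~cover).count("1"), -i),
        )
        if not dominated_by[best] & ~cover:
            break  # isolated leftovers dominate themselves
        chosen.append(best)
        cover |= dominated_by[best]
    return DriverSet(
        frozenset(names[i] for i in chosen),
        method="minimum_dominating_set",
        exact=False,
    )
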