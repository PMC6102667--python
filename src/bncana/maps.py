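"""Network-level canalization maps: effective graph, CM and DCM.

The *effective graph* reweights the interaction graph by how much each
input actually matters: edge ``j -> i`` carries the per-input
effectiveness ``e_ji`` of input ``j`` in node ``i``'s look-up table.  An
edge present in the wiring but with ``e_ji = 0`` is dynamically inert and
is pruned by default.

The *canalizing map* (CM) renders a node's minimized logic as a
McCulloch–Pitts-style threshold network: *s-units* stand for a variable in
a definite state, *t-units* for the conjunction of the literals of one
wildcard schema (threshold = number of literals).  A schema with a single
literal needs no t-unit and becomes a direct s->s edge.  Joining the CMs
of all nodes over their shared s-units yields the *dynamics canalizing
map* (DCM), a parsimonious redescription of the entire network dynamics
whose construction is linear in the number of nodes.
"""

from __future__ import annotations

import networkx as nx

from .exceptions import BNCanaError
from .network import BooleanNetwork
from .schemata import (
    LookupTable,
    WILDCARD,
    canalization_summary,
    enumerate_prime_implicants,
    pattern_str,
    two_symbol_redescription,
)


class EffectiveGraph(nx.DiGraph):
    """Weighted digraph on node names; ``weight`` of ``j -> i`` is ``e_ji``."""


class CanalizingMapGraph(nx.DiGraph):
    """Threshold-network rendering of canalizing logic.

    Node ids are strings: ``"s:<name>:<state>"`` (kind ``s-unit``, attrs
    ``variable``/``state``) and ``"t:<name>:<value>:<i>"`` (kind ``t-unit``,
    attr ``threshold``).  Edge kinds: ``condition`` (s->t input),
    ``determination`` (t->s output), ``direct`` (single-literal s->s).
    Permutation-group annotations from the two-symbol redescription are
    stored on t-units (attr ``fibers``) as readable strings.
    """


def s_unit(name: str, state: int) -> str:
    return f"s:{name}:{int(state)}"


def effective_graph(net: BooleanNetwork, prune_zero: bool = True) -> EffectiveGraph:
    """Interaction graph weighted by per-input effectiveness ``e_ji``."""
    g = EffectiveGraph()
    g.add_nodes_from(net.names)
    for lut in net.nodes:
        summary = canalization_summary(lut)
        for j, inp in enumerate(lut.input_names):
            e = summary.e[j]
            if e == 0 and prune_zero:
                continue
            g.add_edge(inp, lut.node_name, weight=float(e))
    return g


def _add_schema_units(
    g: CanalizingMapGraph,
    lut: LookupTable,
    fibers: dict[tuple[int, ...], list[str]],
) -> None:
    name = lut.node_name
    for state in (0, 1):
        g.add_node(s_unit(name, state), kind="s-unit", variable=name, state=state)
    if lut.k == 0:
        target = s_unit(name, lut.outputs[0])
        g.nodes[target]["unconditional"] = True
        return
    counters = {0: 0, 1: 0}
    for value in (0, 1):
        schemata = sorted(
            enumerate_prime_implicants(lut, value), key=lambda s: s.pattern
        )
        for schema in schemata:
            literals = [
                (lut.input_names[j], p)
                for j, p in enumerate(schema.pattern)
                if p != WILDCARD
            ]
            target = s_unit(name, value)
            if not literals:  # constant-on-all-rows schema
                g.nodes[target]["unconditional"] = True
                continue
            if len(literals) == 1:
                inp, state = literals[0]
                src = s_unit(inp, state)
                if src not in g:
                    g.add_node(src, kind="s-unit", variable=inp, state=state)
                g.add_edge(src, target, kind="direct")
                continue
            tid = f"t:{name}:{value}:{counters[value]}"
            counters[value] += 1
            annot = fibers.get(schema.pattern)
            g.add_node(
                tid,
                kind="t-unit",
                threshold=len(literals),
                schema=pattern_str(schema.pattern),
                **({"fibers": "; ".join(annot)} if annot else {}),
            )
            for inp, state in literals:
                src = s_unit(inp, state)
                if src not in g:
                    g.add_node(src, kind="s-unit", variable=inp, state=state)
                g.add_edge(src, tid, kind="condition")
            g.add_edge(tid, target, kind="determination")


def _fiber_annotations(lut: LookupTable) -> dict[tuple[int, ...], list[str]]:
    """Group-disjunction annotations, keyed by the member wildcard patterns."""
    if lut.k == 0:
        return {}
    fibers: dict[tuple[int, ...], list[str]] = {}
    for ts in two_symbol_redescription(lut):
        if not ts.groups:
            continue
        label = "groups " + ", ".join(
            "{" + ",".join(lut.input_names[p] for p in sorted(g)) + "}"
            for g in sorted(ts.groups, key=sorted)
        ) + f" of {pattern_str(ts.pattern)}->{ts.output}"
        for pat in ts.orbit():
            fibers.setdefault(pat, []).append(label)
    for v in fibers.values():
        v.sort()
    return fibers


def canalizing_map(lut: LookupTable) -> CanalizingMapGraph:
    """Threshold-network (CM) rendering of one automaton's canalizing logic."""
    g = CanalizingMapGraph()
    _add_schema_units(g, lut, _fiber_annotations(lut))
    return g


def dynamics_canalizing_map(net: BooleanNetwork) -> CanalizingMapGraph:
    """Union of all node CMs over shared s-units (the DCM)."""
    g = CanalizingMapGraph()
    for lut in net.nodes:
        _add_schema_units(g, lut, _fiber_annotations(lut))
    return g


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _canonical_copy(graph: nx.DiGraph) -> nx.DiGraph:
    """Rebuild with sorted nodes/edges so emitters produce stable bytes."""
    g = nx.DiGraph()
    g.graph.update(sorted(graph.graph.items()))
    for node in sorted(graph.nodes, key=str):
        g.add_node(node, **{k: graph.nodes[node][k] for k in sorted(graph.nodes[node])})
    for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
        data = graph.edges[u, v]
        g.add_edge(u, v, **{k: data[k] for k in sorted(data)})
    return g


def _dot_quote(s: object) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def export_graph(graph: nx.DiGraph, format: str = "dot") -> str:
    """Serialize a graph deterministically to ``dot`` or ``graphml`` text.

    Accepts effective graphs, canalizing maps and (controlled) state
    transition graphs; node/edge attributes (weights, thresholds, kinds)
    are carried along.  Identical graphs yield bit-identical output.
    """
    if not isinstance(graph, nx.DiGraph):
        raise BNCanaError("only directed graphs are exported")
    g = _canonical_copy(graph)
    if format == "graphml":
        for _, data in g.nodes(data=True):
            for k, v in data.items():
                if not isinstance(v, (str, int, float, bool)):
                    data[k] = str(v)
        for _, _, data in g.edges(data=True):
            for k, v in data.items():
                if not isinstance(v, (str, int, float, bool)):
                    data[k] = str(v)
        g.graph.clear()  # graph-level attrs are not needed and vary in type
        return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"
    if format == "dot":
        lines = ["digraph G {"]
        for node, data in g.nodes(data=True):
            attrs = ", ".join(f"{k}={_dot_quote(v)}" for k, v in sorted(data.items()))
            lines.append(f"  {_dot_quote(node)}" + (f" [{attrs}]" if attrs else "") + ";")
        for u, v, data in g.edges(data=True):
            attrs = ", ".join(f"{k}={_dot_quote(val)}" for k, val in sorted(data.items()))
            lines.append(
                f"  {_dot_quote(u)} -> {_dot_quote(v)}" + (f" [{attrs}]" if attrs else "") + ";"
            )
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise BNCanaError(f"unknown export format {format!r}")
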