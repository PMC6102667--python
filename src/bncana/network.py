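"""Boolean network container, synchronous dynamics and attractors.

A Boolean network couples ``N`` automata: node ``i`` reads the current
states of its wired inputs ``X_i`` and looks its next state up in its
:class:`~bncana.schemata.LookupTable`.  All nodes update simultaneously
(synchronous policy), so the dynamics over the ``2**N`` configurations is a
deterministic map whose graph — the state-transition graph (STG) — has
out-degree one everywhere.  Every trajectory therefore ends in an
attractor: a fixed point (period 1) or a limit cycle (period > 1), each
with a basin of attraction; the basins partition configuration space.

Configurations are encoded as integers with the first-declared node as the
most significant bit.  Exhaustive routines (full STG, basins) are guarded
by a configurable size limit; the SAT-guided enumeration in
:mod:`bncana.sat` finds the attractor set without materializing the STG.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .exceptions import CapacityError, CnetParseError, StructuralError
from .schemata import LookupTable

#: Exhaustive state-space routines refuse networks larger than this by default.
DEFAULT_EXHAUSTIVE_LIMIT = 20

#: Hard ceiling for the configurable exhaustive limit.
MAX_EXHAUSTIVE_LIMIT = 30


class TransitionGraph(nx.DiGraph):
    """Directed graph over all ``2**N`` configurations.

    Serves both as the STG (every vertex has exactly one out-edge, labeled
    ``kind='natural'``) and, once driver interventions are added, as the
    controlled STG (extra edges labeled ``kind='controlled'``; an edge that
    is both keeps ``kind='natural'`` and gains ``controlled=True``).
    The number of automata is stored in ``graph['n_automata']``.
    """

    @property
    def n_automata(self) -> int:
        return self.graph["n_automata"]


@dataclass(frozen=True)
class Attractor:
    """A periodic orbit of the synchronous dynamics.

    ``configurations`` lists the cycle in trajectory order starting from its
    smallest integer encoding; ``period`` (μ) is 1 for fixed points.
    ``basin_size`` counts the configurations that flow into the cycle
    (cycle members included); it is ``None`` when the enumeration method
    does not compute basins.
    """

    configurations: tuple[int, ...]
    basin_size: int | None = None

    @property
    def period(self) -> int:
        return len(self.configurations)

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    def __eq__(self, other):
        return (
            isinstance(other, Attractor)
            and self.configurations == other.configurations
        )

    def __hash__(self):
        return hash(self.configurations)


def _canonical_cycle(cycle: Sequence[int]) -> tuple[int, ...]:
    i = cycle.index(min(cycle))
    return tuple(cycle[i:]) + tuple(cycle[:i])


class BooleanNetwork:
    """Named Boolean automata wired into a network."""

    def __init__(self, nodes: Sequence[LookupTable]):
        self.nodes: tuple[LookupTable, ...] = tuple(nodes)
        names = [n.node_name for n in self.nodes]
        if len(set(names)) != len(names):
            raise StructuralError("node names must be unique")
        self._index: dict[str, int] = {n: i for i, n in enumerate(names)}
        for lut in self.nodes:
            for inp in lut.input_names:
                if inp not in self._index:
                    raise StructuralError(
                        f"node {lut.node_name!r} reads undeclared input {inp!r}"
                    )

    # -- basic accessors ---------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.nodes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.node_name for n in self.nodes)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise StructuralError(f"unknown node {name!r}") from None

    def __getitem__(self, name: str) -> LookupTable:
        return self.nodes[self.index(name)]

    def __eq__(self, other):
        return isinstance(other, BooleanNetwork) and self.nodes == other.nodes

    def __repr__(self):
        return f"BooleanNetwork(N={self.N}, nodes={list(self.names)!r})"

    def interaction_graph(self) -> nx.DiGraph:
        """The wiring ``C``: edge ``j -> i`` when node ``j`` is an input of ``i``."""
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for lut in self.nodes:
            for inp in lut.input_names:
                g.add_edge(inp, lut.node_name)
        return g

    # -- configurations ----------------------------------------------------

    def encode(self, states: Sequence[int]) -> int:
        """Integer encoding of a configuration (first-declared node = MSB)."""
        if len(states) != self.N:
            raise StructuralError(f"expected {self.N} states, got {len(states)}")
        c = 0
        for s in states:
            c = (c << 1) | (1 if s else 0)
        return c

    def decode(self, config: int) -> tuple[int, ...]:
        if not 0 <= config < 2 ** self.N:
            raise StructuralError(f"configuration {config} out of range for N={self.N}")
        return tuple((config >> (self.N - 1 - i)) & 1 for i in range(self.N))

    def state_of(self, config: int, name: str) -> int:
        return (config >> (self.N - 1 - self.index(name))) & 1

    # -- dynamics ----------------------------------------------------------

    def step(self, states: Sequence[int]) -> tuple[int, ...]:
        """One synchronous update of a configuration given as a state tuple."""
        cur = tuple(states)
        return tuple(
            lut(tuple(cur[self._index[i]] for i in lut.input_names))
            for lut in self.nodes
        )

    def successor_table(self, limit: int = DEFAULT_EXHAUSTIVE_LIMIT) -> np.ndarray:
        """Successor of every configuration, as an int64 array of length 2**N."""
        self._check_limit(limit)
        configs = np.arange(2 ** self.N, dtype=np.int64)
        nxt = np.zeros_like(configs)
        for i, lut in enumerate(self.nodes):
            k = lut.k
            rows = np.zeros_like(configs)
            for j, inp in enumerate(lut.input_names):
                bit = (configs >> (self.N - 1 - self._index[inp])) & 1
                rows |= bit << (k - 1 - j)
            out = np.asarray(lut.outputs, dtype=np.int64)[rows]
            nxt |= out << (self.N - 1 - i)
        return nxt

    def _check_limit(self, limit: int):
        limit = min(limit, MAX_EXHAUSTIVE_LIMIT)
        if self.N > limit:
            raise CapacityError(
                f"N={self.N} exceeds the exhaustive limit of {limit}; "
                "use the SAT-based attractor enumeration instead"
            )


def synchronous_step(net: BooleanNetwork, config: int) -> int:
    """Successor of an integer-encoded configuration under synchronous update."""
    return net.encode(net.step(net.decode(config)))


def build_stg(net: BooleanNetwork, limit: int = DEFAULT_EXHAUSTIVE_LIMIT) -> TransitionGraph:
    """The full state-transition graph (natural edges only)."""
    succ = net.successor_table(limit=limit)
    g = TransitionGraph(n_automata=net.N)
    g.add_nodes_from(range(2 ** net.N))
    g.add_edges_from(
        ((int(a), int(b), {"kind": "natural"}) for a, b in enumerate(succ))
    )
    return g


def _attractors_from_successors(succ: np.ndarray) -> list[Attractor]:
    """Cycle + basin detection on the functional graph of ``succ``."""
    n = len(succ)
    color = np.full(n, -2, dtype=np.int64)  # -2 unseen, -1 on current path
    cycles: list[tuple[int, ...]] = []
    basin_of = []
    for start in range(n):
        if color[start] != -2:
            continue
        path = []
        s = start
        while color[s] == -2:
            color[s] = -1
            path.append(s)
            s = int(succ[s])
        if color[s] == -1:  # closed a new cycle
            at = path.index(s)
            cycles.append(_canonical_cycle(path[at:]))
            label = len(cycles) - 1
        else:
            label = int(color[s])
        for p in path:
            color[p] = label
    counts = np.bincount(color, minlength=len(cycles))
    return [
        Attractor(cyc, basin_size=int(counts[i])) for i, cyc in enumerate(cycles)
    ]


def find_attractors(
    net: BooleanNetwork,
    method: str = "exhaustive",
    limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> frozenset[Attractor]:
    """Complete attractor set of the synchronous dynamics.

    ``method='exhaustive'`` sweeps all ``2**N`` configurations and also
    reports basin sizes; ``method='sat'`` uses the solver-guided
    enumeration of :mod:`bncana.sat` (no basins).  Both methods return the
    same attractor set whenever both are applicable.
    """
    if method == "exhaustive":
        succ = net.successor_table(limit=limit)
        return frozenset(_attractors_from_successors(succ))
    if method == "sat":
        from .sat import sat_attractors

        return sat_attractors(net)
    raise ValueError(f"unknown attractor method {method!r}")


# ---------------------------------------------------------------------------
# cnet text format
# ---------------------------------------------------------------------------
#
# Dialect:
#   .v N                         -- node count header
#   # <index> = <name>           -- optional name directives (in comments)
#   .n <index> <k> <inputs...>   -- per-node header, 1-based indices
#   <k symbols over {0,1,-}> <output>
#                                -- LUT rows; '-' expands to both values
#   #...                         -- comments; blank lines ignored
#
# Every row of every LUT must be assigned exactly once after '-' expansion.

_NAME_DIRECTIVE = re.compile(r"#\s*(\d+)\s*=\s*(\S+)\s*$")


def parse_cnet(text: str) -> BooleanNetwork:
    """Parse the cnet truth-table dialect into a :class:`BooleanNetwork`."""
    lines = text.splitlines()
    n_declared: int | None = None
    names: dict[int, str] = {}
    # (index, k, input indices, [(lineno, symbols, output)])
    blocks: list[tuple[int, int, list[int], list[tuple[int, str, str]]]] = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _NAME_DIRECTIVE.match(line)
            if m:
                names[int(m.group(1))] = m.group(2)
            continue
        if line.startswith(".v"):
            try:
                n_declared = int(line.split()[1])
            except (IndexError, ValueError):
                raise CnetParseError("malformed .v header", lineno)
            continue
        if line.startswith(".n"):
            parts = line.split()
            try:
                idx, k = int(parts[1]), int(parts[2])
                inputs = [int(p) for p in parts[3:]]
            except (IndexError, ValueError):
                raise CnetParseError("malformed .n header", lineno)
            if len(inputs) != k:
                raise CnetParseError(
                    f"node {idx}: {len(inputs)} inputs listed for k={k}", lineno
                )
            blocks.append((idx, k, inputs, []))
            continue
        # LUT row
        if not blocks:
            raise CnetParseError("LUT row before any .n header", lineno)
        parts = line.split()
        k = blocks[-1][1]
        if k == 0:
            if len(parts) != 1:
                raise CnetParseError("constant node row must be a single output", lineno)
            symbols, output = "", parts[0]
        else:
            if len(parts) != 2:
                raise CnetParseError("expected '<symbols> <output>'", lineno)
            symbols, output = parts
        blocks[-1][3].append((lineno, symbols, output))

    if n_declared is None:
        raise CnetParseError("missing .v header")
    if len(blocks) != n_declared:
        raise CnetParseError(
            f".v declares {n_declared} nodes but {len(blocks)} .n blocks found"
        )
    declared = [idx for idx, *_ in blocks]
    if sorted(declared) != list(range(1, n_declared + 1)):
        raise CnetParseError(f".n indices must cover 1..{n_declared} exactly once")

    def node_name(idx: int) -> str:
        return names.get(idx, f"x{idx}")

    luts = []
    for idx, k, inputs, rows in blocks:
        for inp in inputs:
            if not 1 <= inp <= n_declared:
                raise StructuralError(
                    f"node {node_name(idx)!r} references undeclared input index {inp}"
                )
        outputs: list[int | None] = [None] * (2 ** k)
        assigned_at: list[int | None] = [None] * (2 ** k)
        for lineno, symbols, output in rows:
            if len(symbols) != k:
                raise CnetParseError(
                    f"row has {len(symbols)} symbols, node has k={k}", lineno
                )
            if output not in ("0", "1"):
                raise CnetParseError(f"output must be 0 or 1, got {output!r}", lineno)
            if any(c not in "01-" for c in symbols):
                raise CnetParseError(f"bad row symbols {symbols!r}", lineno)
            targets = [0]
            for c in symbols:
                if c == "-":
                    targets = [t << 1 for t in targets] + [
                        (t << 1) | 1 for t in targets
                    ]
                else:
                    targets = [(t << 1) | int(c) for t in targets]
            for t in targets:
                if outputs[t] is not None:
                    raise CnetParseError(
                        f"row {t:0{k}b} of node {node_name(idx)!r} assigned twice "
                        f"(first at line {assigned_at[t]})",
                        lineno,
                    )
                outputs[t] = int(output)
                assigned_at[t] = lineno
        missing = [r for r, o in enumerate(outputs) if o is None]
        if missing:
            raise CnetParseError(
                f"node {node_name(idx)!r} is missing {len(missing)} LUT row(s), "
                f"e.g. {missing[0]:0{k}b}"
            )
        luts.append(
            LookupTable(
                node_name(idx),
                tuple(node_name(i) for i in inputs),
                tuple(outputs),  # type: ignore[arg-type]
            )
        )
    ordered = [None] * n_declared
    for (idx, *_), lut in zip(blocks, luts):
        ordered[idx - 1] = lut
    return BooleanNetwork(ordered)  # type: ignore[arg-type]


def write_cnet(net: BooleanNetwork) -> str:
    """Serialize a network to the cnet dialect (rows in ascending order, no '-')."""
    out = [f".v {net.N}"]
    for i, name in enumerate(net.names, start=1):
        out.append(f"# {i} = {name}")
    for i, lut in enumerate(net.nodes, start=1):
        inputs = " ".join(str(net.index(inp) + 1) for inp in lut.input_names)
        out.append(f".n {i} {lut.k}" + (f" {inputs}" if inputs else ""))
        for row, o in enumerate(lut.outputs):
            if lut.k == 0:
                out.append(f"{o}")
            else:
                out.append(f"{row:0{lut.k}b} {o}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Random NK ensemble and packaged examples
# ---------------------------------------------------------------------------

def random_nk(N: int, K: int, bias: float = 0.5, seed: int | None = None) -> BooleanNetwork:
    """A random Kauffman NK network.

    Each node receives ``K`` distinct inputs drawn uniformly from all nodes
    (self-inputs allowed) and a LUT whose outputs are i.i.d. Bernoulli with
    the given ``bias``.  The same seed reproduces the same network.
    """
    if not 0 <= K <= N:
        raise ValueError(f"K={K} must satisfy 0 <= K <= N={N}")
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must be a probability")
    rng = random.Random(seed)
    names = [f"x{i + 1}" for i in range(N)]
    luts = []
    for name in names:
        inputs = tuple(rng.sample(names, K))
        outputs = tuple(1 if rng.random() < bias else 0 for _ in range(2 ** K))
        luts.append(LookupTable(name, inputs, outputs))
    return BooleanNetwork(luts)


def load_example(name: str) -> BooleanNetwork:
    """Load a packaged example network by name (see :func:`bncana.datasets.fixture_manifest`)."""
    from . import datasets

    return datasets.load_example(name)
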