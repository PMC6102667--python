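"""Deliberately naive reference implementations for the test suite.

Each oracle recomputes a quantity by exhaustive enumeration, sharing no
code with the production algorithms it cross-checks: prime implicants by
scanning all ``3**k`` patterns, permutation closure by expanding every
group arrangement, reachability by iterating the adjacency closure to a
fixed point, and driver-set sizes by brute force.  All are capped at tiny
problem sizes; independence matters here, speed does not.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping

from .exceptions import CapacityError
from .schemata import LookupTable, TwoSymbolSchema, WILDCARD, WildcardSchema


def _expand_pattern(pattern: tuple[int, ...]) -> list[int]:
    rows = [0]
    for p in pattern:
        if p == WILDCARD:
            rows = [r << 1 for r in rows] + [(r << 1) | 1 for r in rows]
        else:
            rows = [(r << 1) | p for r in rows]
    return rows


def oracle_prime_implicants(lut: LookupTable, value: int) -> frozenset[WildcardSchema]:
    """All maximal consistent patterns, by scanning every pattern over {0,1,#}."""
    if lut.k > 6:
        raise CapacityError("pattern-scan oracle is capped at k <= 6")
    if lut.k == 0:
        return (
            frozenset({WildcardSchema((), value)})
            if lut.outputs[0] == value
            else frozenset()
        )
    consistent = [
        pat
        for pat in itertools.product((0, 1, WILDCARD), repeat=lut.k)
        if all(lut.outputs[r] == value for r in _expand_pattern(pat))
    ]

    def generalizes(a, b):  # a covers strictly more than b
        return a != b and all(x == WILDCARD or x == y for x, y in zip(a, b))

    maximal = [
        pat
        for pat in consistent
        if not any(generalizes(other, pat) for other in consistent)
    ]
    return frozenset(WildcardSchema(pat, value) for pat in maximal)


def oracle_permutation_closure(schema: TwoSymbolSchema, lut: LookupTable) -> bool:
    """Exhaustively verify the two-symbol invariant: every group arrangement
    of the pattern is a consistent wildcard pattern for the schema's output."""
    patterns = [schema.pattern]
    for group in schema.groups:
        pos = sorted(group)
        nxt = []
        for pat in patterns:
            for perm in set(itertools.permutations([pat[p] for p in pos])):
                lst = list(pat)
                for p, s in zip(pos, perm):
                    lst[p] = s
                nxt.append(tuple(lst))
        patterns = nxt
    return all(
        lut.outputs[r] == schema.output
        for pat in patterns
        for r in _expand_pattern(pat)
    )


def oracle_reachability(edges: Iterable[tuple[int, int]], vertices: Iterable[int]) -> dict[int, set[int]]:
    """Per-vertex reachable sets (self excluded) by closure iteration."""
    vertices = list(vertices)
    if len(vertices) > 4096:
        raise CapacityError("closure oracle is capped at 2**12 vertices")
    adj: dict[int, set[int]] = {v: set() for v in vertices}
    for u, v in edges:
        adj[u].add(v)
    reach = {v: set(adj[v]) for v in vertices}
    changed = True
    while changed:
        changed = False
        for v in vertices:
            new = set(reach[v])
            for w in list(reach[v]):
                new |= reach[w]
            if new != reach[v]:
                reach[v] = new
                changed = True
    for v in vertices:
        reach[v].discard(v)
    return reach


def oracle_min_dominating_size(
    out_neighbors: Mapping[str, set[str]], nodes: Iterable[str]
) -> int:
    """Minimum dominating-set size by exhaustive subset search."""
    nodes = list(nodes)
    if len(nodes) > 16:
        raise CapacityError("dominating-set oracle is capped at 16 nodes")
    for size in range(len(nodes) + 1):
        for comb in itertools.combinations(nodes, size):
            covered = set(comb)
            for c in comb:
                covered |= out_neighbors.get(c, set())
            if covered == set(nodes):
                return size
    return len(nodes)
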