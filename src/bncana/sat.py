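"""SAT-guided complete attractor enumeration.

For networks too large for the exhaustive sweep, the attractor set can be
recovered without materializing the state-transition graph: a SAT solver
repeatedly proposes a configuration not yet known to reach a recorded
attractor, the deterministic trajectory from that configuration is
followed until it either closes a new cycle or meets an already-explored
configuration, and every configuration on the trajectory is excluded from
the search with a blocking clause.  When the formula becomes unsatisfiable
the attractor set is provably complete.  This is the bounded-search
variant of solver-driven enumeration for deterministic update maps; basins
are not computed on this path.

The embedded solver is a small iterative DPLL with unit propagation —
entirely adequate here because the clauses are plain blockers over the
``N`` state variables.  The practical ceiling is the total number of
configurations visited across trajectories, not ``N`` itself, so sparsely
attracting networks far beyond the exhaustive limit remain tractable.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .network import Attractor, BooleanNetwork, _canonical_cycle


def dpll(n_vars: int, clauses: Sequence[Sequence[int]]) -> list[int] | None:
    """Satisfy a CNF over variables ``1..n_vars`` (DIMACS-signed literals).

    Returns a full assignment as a list of signed literals, or ``None`` if
    unsatisfiable.  Branching is deterministic: lowest-index unassigned
    variable first, negative polarity first.
    """
    clauses = [tuple(c) for c in clauses]
    if any(len(c) == 0 for c in clauses):
        return None
    assign: dict[int, bool] = {}

    def value(lit: int) -> bool | None:
        v = assign.get(abs(lit))
        if v is None:
            return None
        return v if lit > 0 else not v

    def propagate(trail: list[int]) -> bool:
        changed = True
        while changed:
            changed = False
            for clause in clauses:
                unassigned = []
                satisfied = False
                for lit in clause:
                    v = value(lit)
                    if v is True:
                        satisfied = True
                        break
                    if v is None:
                        unassigned.append(lit)
                if satisfied:
                    continue
                if not unassigned:
                    return False  # conflict
                if len(unassigned) == 1:
                    lit = unassigned[0]
                    assign[abs(lit)] = lit > 0
                    trail.append(abs(lit))
                    changed = True
        return True

    # iterative DPLL with an explicit decision stack
    stack: list[tuple[int, bool, list[int]]] = []  # (var, tried_true, trail)
    trail: list[int] = []
    if not propagate(trail):
        return None
    while True:
        var = next((v for v in range(1, n_vars + 1) if v not in assign), None)
        if var is None:
            return [v if assign[v] else -v for v in range(1, n_vars + 1)]
        assign[var] = False
        new_trail = [var]
        stack.append((var, False, new_trail))
        while not propagate(new_trail):
            # backtrack to the most recent decision with an untried branch
            while stack:
                dvar, tried_true, dtrail = stack.pop()
                for v in dtrail:
                    del assign[v]
                if not tried_true:
                    assign[dvar] = True
                    new_trail = [dvar]
                    stack.append((dvar, True, new_trail))
                    break
            else:
                return None


def sat_attractors(net: BooleanNetwork) -> frozenset[Attractor]:
    """Complete attractor set via solver-guided search (no basin sizes)."""
    n = net.N
    blocked: list[tuple[int, ...]] = []
    visited: set[int] = set()
    attractors: list[Attractor] = []

    def config_from_model(model: Iterable[int]) -> int:
        c = 0
        for lit in model:
            i = abs(lit) - 1  # variable i+1 is node i, first-declared = MSB
            if lit > 0:
                c |= 1 << (n - 1 - i)
        return c

    def blocking_clause(config: int) -> tuple[int, ...]:
        return tuple(
            -(i + 1) if (config >> (n - 1 - i)) & 1 else (i + 1) for i in range(n)
        )

    while True:
        model = dpll(n, blocked)
        if model is None:
            return frozenset(attractors)
        s = config_from_model(model)
        path: list[int] = []
        seen_here: dict[int, int] = {}
        while s not in visited and s not in seen_here:
            seen_here[s] = len(path)
            path.append(s)
            s = net.encode(net.step(net.decode(s)))
        if s in seen_here:  # new cycle closed inside this trajectory
            cycle = path[seen_here[s]:]
            attractors.append(Attractor(_canonical_cycle(cycle), basin_size=None))
        for c in path:
            visited.add(c)
            blocked.append(blocking_clause(c))
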