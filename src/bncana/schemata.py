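"""Node-level canalization: schemata redescription and redundancy measures.

A Boolean automaton with ``k`` inputs is specified by its look-up table
(LUT): an output bit for each of the ``2**k`` input combinations.  Not all
inputs are equally necessary for every transition.  This module makes that
redundancy explicit by redescribing the LUT in two steps:

1. *Wildcard schemata* (``F'``): the prime implicants of the function,
   obtained by Quine-McCluskey minimization.  A position marked ``#``
   ("don't care") is an input whose state is irrelevant given the rest of
   the schema.

2. *Two-symbol schemata* (``F''``): wildcard schemata augmented with
   position-free groups (the ``°`` mark) — disjoint sets of input positions
   whose symbols may be permuted arbitrarily without breaking the schema.
   These capture group symmetry (e.g. the full input symmetry of a
   majority function).

From the redescriptions the module computes the canalization measures of a
node: input redundancy ``k_r`` (mean number of ``#`` per LUT entry, taking
for each entry the most-redundant covering schema), effective connectivity
``k_e = k - k_r``, input symmetry ``k_s`` (same tally over ``°`` marks),
and the per-input profiles ``r_j`` / ``e_j`` / ``s_j`` that weight the
*effective graph* of a network.  All measures are computed in exact
rational arithmetic (:class:`fractions.Fraction`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

from .exceptions import CapacityError, StructuralError

#: Integer stand-in for the wildcard ("don't care") symbol in patterns.
WILDCARD = 2

_SYMBOLS = {0: "0", 1: "1", WILDCARD: "#"}

#: Largest in-degree for which the exponential closure checks are attempted.
DEFAULT_K_LIMIT = 16


def pattern_str(pattern: Sequence[int]) -> str:
    """Render a pattern over {0, 1, #} in the conventional string form."""
    return "".join(_SYMBOLS[p] for p in pattern)


@dataclass(frozen=True)
class LookupTable:
    """Transition function of one Boolean automaton.

    ``outputs[r]`` is the next state for the input combination whose integer
    encoding is ``r``, with the first-listed input as the most significant
    bit (so for inputs ``(a, b)`` row 2 means ``a=1, b=0``).
    """

    node_name: str
    input_names: tuple[str, ...]
    outputs: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "input_names", tuple(self.input_names))
        object.__setattr__(self, "outputs", tuple(int(o) for o in self.outputs))
        if len(self.outputs) != 2 ** self.k:
            raise StructuralError(
                f"node {self.node_name!r}: {len(self.outputs)} outputs for k={self.k}"
            )
        if any(o not in (0, 1) for o in self.outputs):
            raise StructuralError(f"node {self.node_name!r}: outputs must be 0/1")

    @property
    def k(self) -> int:
        """In-degree (number of inputs)."""
        return len(self.input_names)

    @classmethod
    def from_function(
        cls,
        node_name: str,
        input_names: Sequence[str],
        fn: Callable[..., int],
    ) -> "LookupTable":
        """Tabulate ``fn`` (one bool/int argument per input, MSB first)."""
        k = len(input_names)
        outputs = []
        for row in range(2 ** k):
            states = [(row >> (k - 1 - j)) & 1 for j in range(k)]
            outputs.append(int(bool(fn(*states))))
        return cls(node_name, tuple(input_names), tuple(outputs))

    def row_states(self, row: int) -> tuple[int, ...]:
        """Decode a row index to the tuple of input states (MSB first)."""
        return tuple((row >> (self.k - 1 - j)) & 1 for j in range(self.k))

    def __call__(self, states: Sequence[int]) -> int:
        row = 0
        for s in states:
            row = (row << 1) | (1 if s else 0)
        return self.outputs[row]


@dataclass(frozen=True)
class WildcardSchema:
    """A prime implicant: pattern over {0, 1, #} plus the implied output."""

    pattern: tuple[int, ...]
    output: int

    def __post_init__(self):
        object.__setattr__(self, "pattern", tuple(self.pattern))
        if any(p not in (0, 1, WILDCARD) for p in self.pattern):
            raise StructuralError("pattern symbols must be 0, 1 or #")

    @property
    def k(self) -> int:
        return len(self.pattern)

    @property
    def n_wildcards(self) -> int:
        """Number of ``#`` positions (``n#`` of the schema)."""
        return sum(1 for p in self.pattern if p == WILDCARD)

    @property
    def n_literals(self) -> int:
        """Number of specified (non-wildcard) input conditions — *enputs*."""
        return self.k - self.n_wildcards

    def covers_row(self, row: int) -> bool:
        for j, p in enumerate(self.pattern):
            if p != WILDCARD and ((row >> (self.k - 1 - j)) & 1) != p:
                return False
        return True

    def expand(self) -> frozenset[int]:
        """Row indices obtained by expanding every wildcard position."""
        rows = [0]
        for j, p in enumerate(self.pattern):
            shift = self.k - 1 - j
            if p == WILDCARD:
                rows = [r for base in rows for r in (base, base | (1 << shift))]
            elif p == 1:
                rows = [base | (1 << shift) for base in rows]
        return frozenset(rows)

    def __str__(self) -> str:
        return f"{pattern_str(self.pattern)} -> {self.output}"


@dataclass(frozen=True)
class TwoSymbolSchema:
    """Wildcard schema with disjoint permutable position groups (``°`` marks).

    ``groups`` holds disjoint position sets of size >= 2.  Permuting the
    pattern symbols within any group must again yield a pattern consistent
    with the LUT for the same output; the schema redescribes the union of
    the expansions of every pattern in that permutation orbit.
    """

    pattern: tuple[int, ...]
    output: int
    groups: frozenset[frozenset[int]] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "pattern", tuple(self.pattern))
        object.__setattr__(
            self, "groups", frozenset(frozenset(g) for g in self.groups)
        )
        seen: set[int] = set()
        for g in self.groups:
            if len(g) < 2:
                raise StructuralError("permutable groups must have size >= 2")
            if seen & g:
                raise StructuralError("permutable groups must be disjoint")
            seen |= g

    @property
    def k(self) -> int:
        return len(self.pattern)

    @property
    def n_position_free(self) -> int:
        """Number of positions carrying the ``°`` mark (``n°`` of the schema)."""
        return sum(len(g) for g in self.groups)

    def marks(self, position: int) -> bool:
        """Whether ``position`` belongs to some permutable group."""
        return any(position in g for g in self.groups)

    def orbit(self) -> frozenset[tuple[int, ...]]:
        """All patterns reachable by permuting symbols within each group."""
        patterns = {self.pattern}
        for g in sorted(self.groups, key=sorted):
            pos = sorted(g)
            new: set[tuple[int, ...]] = set()
            for pat in patterns:
                symbols = [pat[p] for p in pos]
                for perm in set(itertools.permutations(symbols)):
                    lst = list(pat)
                    for p, s in zip(pos, perm):
                        lst[p] = s
                    new.add(tuple(lst))
            patterns = new
        return frozenset(patterns)

    def expand(self) -> frozenset[int]:
        """Rows redescribed by the schema (union over its orbit)."""
        rows: set[int] = set()
        for pat in self.orbit():
            rows |= WildcardSchema(pat, self.output).expand()
        return frozenset(rows)

    def __str__(self) -> str:
        grp = ",".join(
            "{" + ",".join(map(str, sorted(g))) + "}" for g in sorted(self.groups, key=sorted)
        )
        return f"{pattern_str(self.pattern)} -> {self.output}" + (f" °{grp}" if grp else "")


@dataclass(frozen=True)
class CanalizationSummary:
    """Node-level and per-input canalization measures (exact rationals).

    ``k_r + k_e == k`` always; ``e_j == 1 - r_j`` for each input.  Under the
    ``mean`` norm ``k_r == sum_j r_j`` and ``k_s == sum_j s_j``; under the
    ``max`` norm (the literal per-entry maximum) these identities need not
    hold.
    """

    node_name: str
    k: int
    k_r: Fraction
    k_e: Fraction
    k_s: Fraction
    input_names: tuple[str, ...]
    r: tuple[Fraction, ...]
    e: tuple[Fraction, ...]
    s: tuple[Fraction, ...]
    norm: str

    @property
    def sum_r(self) -> Fraction:
        return sum(self.r, Fraction(0))

    @property
    def sum_s(self) -> Fraction:
        return sum(self.s, Fraction(0))

    def per_input(self) -> dict[str, tuple[Fraction, Fraction, Fraction]]:
        return {
            n: (self.r[j], self.e[j], self.s[j])
            for j, n in enumerate(self.input_names)
        }


# ---------------------------------------------------------------------------
# Quine-McCluskey prime implicants
# ---------------------------------------------------------------------------

def enumerate_prime_implicants(lut: LookupTable, value: int) -> frozenset[WildcardSchema]:
    """All prime implicants of ``lut`` for the given output ``value``.

    Classic Quine-McCluskey merging: implicants are ``(bits, mask)`` pairs
    (a position is specified iff its mask bit is set); two implicants with
    the same mask merge when they differ in exactly one specified bit.
    Terms that never merge are prime.  The full prime set is returned — not
    a minimum cover — because the canalization measures range over every
    covering schema.
    """
    if value not in (0, 1):
        raise ValueError("value must be 0 or 1")
    k = lut.k
    minterms = [r for r, o in enumerate(lut.outputs) if o == value]
    if not minterms:
        return frozenset()
    full_mask = (1 << k) - 1
    if k == 0:
        return frozenset({WildcardSchema((), value)})

    current = {(m, full_mask) for m in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        next_level: set[tuple[int, int]] = set()
        by_mask: dict[int, list[int]] = {}
        for bits, mask in current:
            by_mask.setdefault(mask, []).append(bits)
        for mask, group in by_mask.items():
            group_set = set(group)
            for bits in group:
                for b in range(k):
                    bit = 1 << b
                    if mask & bit and (bits ^ bit) in group_set and bits & bit == 0:
                        merged.add((bits, mask))
                        merged.add((bits | bit, mask))
                        next_level.add((bits, mask & ~bit))
        primes |= current - merged
        current = next_level

    result = set()
    for bits, mask in primes:
        pattern = tuple(
            WILDCARD if not mask & (1 << (k - 1 - j)) else (bits >> (k - 1 - j)) & 1
            for j in range(k)
        )
        result.add(WildcardSchema(pattern, value))
    return frozenset(result)


def schema_coverage(schema: WildcardSchema, lut: LookupTable) -> frozenset[int]:
    """LUT row indices redescribed by ``schema`` (its set ``Υ``)."""
    if schema.k != lut.k:
        raise StructuralError(
            f"schema length {schema.k} does not match LUT in-degree {lut.k}"
        )
    return schema.expand()


def _consistent(pattern: tuple[int, ...], lut: LookupTable, value: int) -> bool:
    """Every expansion row of ``pattern`` has output ``value``."""
    return all(lut.outputs[r] == value for r in WildcardSchema(pattern, value).expand())


# ---------------------------------------------------------------------------
# Two-symbol redescription
# ---------------------------------------------------------------------------

def _admissible_group(
    pattern: tuple[int, ...],
    positions: tuple[int, ...],
    lut: LookupTable,
    value: int,
) -> bool:
    """Whether every arrangement of the group's symbols stays consistent."""
    symbols = [pattern[p] for p in positions]
    for perm in set(itertools.permutations(symbols)):
        cand = list(pattern)
        for p, s in zip(positions, perm):
            cand[p] = s
        if not _consistent(tuple(cand), lut, value):
            return False
    return True


def _groups_for_pattern(
    pattern: tuple[int, ...],
    lut: LookupTable,
    value: int,
    include_identical: bool,
) -> frozenset[frozenset[int]]:
    """Greedy maximal disjoint permutable groups for one schema pattern.

    Seeds every admissible position pair, grows each seed in ascending
    position order while the enlarged set stays admissible, then keeps a
    disjoint family preferring larger (then lexicographically earlier)
    groups.  Groups whose symbols are all identical are admissible by
    convention when ``include_identical`` (permutation trivially preserves
    the pattern); turning the convention off requires at least two distinct
    symbols per group.
    """
    k = len(pattern)
    candidates: set[tuple[int, ...]] = set()
    for i, j in itertools.combinations(range(k), 2):
        if pattern[i] == pattern[j] and not include_identical:
            continue
        if not _admissible_group(pattern, (i, j), lut, value):
            continue
        candidates.add((i, j))
        grp = [i, j]
        for q in range(k):
            if q in grp:
                continue
            trial = tuple(sorted(grp + [q]))
            if not include_identical and len({pattern[p] for p in trial}) < 2:
                continue
            if _admissible_group(pattern, trial, lut, value):
                grp = list(trial)
        candidates.add(tuple(sorted(grp)))

    # Disjoint family maximizing the number of ° positions.  Group
    # permutations compose across a family, so a candidate family is only
    # admitted if the *combined* orbit of all its groups stays consistent;
    # the candidate pool (admissible pairs plus their greedy closures) is
    # small, so a pruned depth-first packing is affordable and deterministic.
    pool = sorted(candidates, key=lambda g: (-len(g), g))
    best: tuple[int, tuple[tuple[int, ...], ...]] = (0, ())

    def family_ok(groups: tuple[tuple[int, ...], ...]) -> bool:
        schema = TwoSymbolSchema(pattern, value, frozenset(frozenset(g) for g in groups))
        return all(_consistent(p, lut, value) for p in schema.orbit())

    def pack(idx: int, used: int, total: int, chosen: tuple[tuple[int, ...], ...]):
        nonlocal best
        key = (total, tuple(sorted(chosen)))
        if key > best:
            best = key
        remaining = sum(len(pool[i]) for i in range(idx, len(pool)))
        if total + remaining <= best[0]:
            return
        for i in range(idx, len(pool)):
            mask = 0
            for p in pool[i]:
                mask |= 1 << p
            if mask & used:
                continue
            if len(chosen) and not family_ok(chosen + (pool[i],)):
                continue
            pack(i + 1, used | mask, total + len(pool[i]), chosen + (pool[i],))

    pack(0, 0, 0, ())
    return frozenset(frozenset(g) for g in best[1])


def _canonical_two_symbol(schema: TwoSymbolSchema) -> TwoSymbolSchema:
    """Orbit-minimal representative (lexicographic on the pattern)."""
    best = min(schema.orbit())
    return TwoSymbolSchema(best, schema.output, schema.groups)


def two_symbol_redescription(
    lut: LookupTable,
    k_limit: int = DEFAULT_K_LIMIT,
    include_identical_groups: bool = True,
) -> tuple[TwoSymbolSchema, ...]:
    """Two-symbol schemata ``F''`` for both output values of ``lut``.

    Built from the prime implicants: each implicant is annotated with its
    greedy-maximal permutable groups, canonicalized to the orbit-minimal
    pattern, and de-duplicated; schemata whose coverage and ``°`` count are
    dominated by another schema are pruned.  The result is sorted
    canonically (output, pattern, groups) and covers every LUT row.
    """
    if lut.k > k_limit:
        raise CapacityError(
            f"two-symbol redescription of k={lut.k} exceeds the limit of {k_limit}; "
            "raise k_limit explicitly if you accept the exponential cost"
        )
    if lut.k == 0:
        return (TwoSymbolSchema((), lut.outputs[0], frozenset()),)

    candidates: set[TwoSymbolSchema] = set()
    for value in (0, 1):
        for pi in enumerate_prime_implicants(lut, value):
            groups = _groups_for_pattern(pi.pattern, lut, value, include_identical_groups)
            candidates.add(
                _canonical_two_symbol(TwoSymbolSchema(pi.pattern, value, groups))
            )

    info = {
        s: (s.expand(), s.n_position_free) for s in candidates
    }
    order = sorted(
        candidates,
        key=lambda s: (s.output, s.pattern, sorted(map(sorted, s.groups))),
    )
    kept: list[TwoSymbolSchema] = []
    for s in order:
        cov, nfree = info[s]
        dominated = False
        for t in order:
            if t is s or t.output != s.output:
                continue
            tcov, tfree = info[t]
            if cov <= tcov and nfree <= tfree and (
                cov != tcov or nfree != tfree or order.index(t) < order.index(s)
            ):
                dominated = True
                break
        if not dominated:
            kept.append(s)
    return tuple(kept)


# ---------------------------------------------------------------------------
# Canalization measures
# ---------------------------------------------------------------------------

def canalization_summary(
    lut: LookupTable,
    norm: str = "max",
    k_limit: int = DEFAULT_K_LIMIT,
    include_identical_groups: bool = True,
) -> CanalizationSummary:
    """Node-level (``k_r``, ``k_e``, ``k_s``) and per-input measures.

    ``norm='max'`` tallies, for each LUT entry, the most redundant covering
    schema (the literal definition of the node-level measures);
    ``norm='mean'`` instead sums the per-input measures, which makes
    ``k_r = sum_j r_j`` and ``k_s = sum_j s_j`` hold by construction.
    Per-input measures always average over all covering schemata of each
    entry.
    """
    if norm not in ("max", "mean"):
        raise ValueError("norm must be 'max' or 'mean'")
    k = lut.k
    if k == 0:
        zero = Fraction(0)
        return CanalizationSummary(
            lut.node_name, 0, zero, zero, zero, (), (), (), (), norm
        )

    nrows = 2 ** k
    primes = {v: enumerate_prime_implicants(lut, v) for v in (0, 1)}
    two_sym = two_symbol_redescription(
        lut, k_limit=k_limit, include_identical_groups=include_identical_groups
    )
    ts_cov = [(s, s.expand()) for s in two_sym]

    kr_max = Fraction(0)
    ks_max = Fraction(0)
    r = [Fraction(0)] * k
    s_meas = [Fraction(0)] * k
    for row in range(nrows):
        out = lut.outputs[row]
        covering = [p for p in primes[out] if p.covers_row(row)]
        kr_max += max(p.n_wildcards for p in covering)
        ncov = len(covering)
        for j in range(k):
            hits = sum(1 for p in covering if p.pattern[j] == WILDCARD)
            r[j] += Fraction(hits, ncov)
        ts_covering = [s for s, cov in ts_cov if s.output == out and row in cov]
        ks_max += max(s.n_position_free for s in ts_covering)
        nts = len(ts_covering)
        for j in range(k):
            hits = sum(1 for s in ts_covering if s.marks(j))
            s_meas[j] += Fraction(hits, nts)

    r = [x / nrows for x in r]
    s_meas = [x / nrows for x in s_meas]
    e = [1 - x for x in r]
    if norm == "max":
        k_r = kr_max / nrows
        k_s = ks_max / nrows
    else:
        k_r = sum(r, Fraction(0))
        k_s = sum(s_meas, Fraction(0))
    return CanalizationSummary(
        lut.node_name,
        k,
        k_r,
        k - k_r,
        k_s,
        lut.input_names,
        tuple(r),
        tuple(e),
        tuple(s_meas),
        norm,
    )


def node_canalization(lut: LookupTable, norm: str = "max", **kwargs) -> CanalizationSummary:
    """Node-level measures ``k_r``, ``k_e``, ``k_s`` (see :func:`canalization_summary`)."""
    return canalization_summary(lut, norm=norm, **kwargs)


def per_input_canalization(lut: LookupTable, **kwargs) -> CanalizationSummary:
    """Per-input measures ``r_j``, ``e_j``, ``s_j`` (see :func:`canalization_summary`)."""
    return canalization_summary(lut, **kwargs)
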