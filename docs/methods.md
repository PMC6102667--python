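# Methods

## Model class

A Boolean network is a set of `N` named binary automata. Node `i` has an
ordered input list `X_i` (the wiring `C`, self-inputs allowed) and a
look-up table (LUT) of `2^k_i` output bits, indexed by the integer
encoding of the input tuple with the first-listed input as most
significant bit. Updates are synchronous and deterministic; the package
does not simulate asynchronous schedules. Configurations (joint states)
are encoded as integers with the first-declared node as MSB, so encoding
and printing round-trip unambiguously.

The canalization analysis (schemata, measures, effective graph, CM/DCM)
depends only on individual LUTs, not on the update schedule; the control
analysis is specific to synchronous dynamics.

## Schemata redescription

**Wildcard schemata `F′`.** For each output value, the LUT rows with that
output are minimized with the textbook Quine–McCluskey merge: implicants
are `(bits, mask)` pairs, two implicants with equal masks merge when they
differ in one specified bit, and anything that never merges is prime. We
keep *all* prime implicants rather than a minimum cover, because the
measures below range over every schema covering a row. A brute-force
oracle (scan all `3^k` patterns, keep maximal consistent ones) cross-checks
this for `k ≤ 4` in the test suite.

**Two-symbol schemata `F″`.** A two-symbol schema is a wildcard pattern
plus disjoint position groups of size ≥ 2; permuting the symbols inside
any group (and composing permutations across groups) must again give a
pattern consistent with the LUT. Construction, per prime implicant:

1. every admissible position pair seeds a group, grown greedily in
   ascending position order while all arrangements of its symbol multiset
   stay consistent;
2. a pruned depth-first packing selects a disjoint family of candidate
   groups maximizing the number of marked positions, admitting a family
   only if the *combined* orbit of all its groups stays consistent
   (single-group admissibility does not compose in general);
3. schemata are canonicalized to the lexicographically smallest pattern in
   their orbit, de-duplicated, and pruned when coverage and `°` count are
   dominated by another schema. The result is a deterministic, canonically
   ordered cover of every LUT row.

This is a heuristic in the choice of candidate groups (the definition
itself does not prescribe an algorithm), but every emitted schema is
validated by exhaustive permutation expansion, and an independent closure
oracle re-validates in the tests. The closure check is exponential in
`k`, so the redescription is guarded by a configurable limit (default
`k ≤ 16`).

**`°`-counting convention.** A position counts toward `n°` iff it belongs
to a permutable group of size ≥ 2. Groups whose member symbols are all
identical are admitted (their permutations are trivially valid); this
makes fully input-symmetric functions such as 3-input majority report
`k_s = k`, which we consider the informative convention. It can be
disabled (`include_identical_groups=False`), which then requires at least
two distinct symbols per group.

## Canalization measures

With `|F| = 2^k` LUT entries, `n#_υ` the wildcard count of schema
`f′_υ` and `n°_θ` the marked-position count of `f″_θ`:

* `k_r = (1/|F|) Σ_α max{n#_υ : f_α ∈ Υ_υ}` — for each entry, the most
  redundant covering wildcard schema; `k_e = k − k_r`;
* `k_s` — identical tally over two-symbol schemata and `n°`;
* per-input: `r_j = (1/|F|) Σ_α avg{[input j is # in f′_υ] : f_α ∈ Υ_υ}`,
  `e_j = 1 − r_j`, and `s_j` analogously with `°` marks.

The node-level and per-input definitions use different aggregations (max
vs average), so `k_r = Σ_j r_j` does **not** hold in general. Both views
are faithful to their definitions; `canalization_summary(..., norm="mean")`
switches the node-level numbers to `Σ_j r_j` / `Σ_j s_j`, under which the
sum identities hold by construction (the effective-graph invariant
`Σ_j e_ji = k_e(x_i)` is stated and tested under this norm). Measures are
computed as exact `Fraction`s; no floating-point tolerances enter the
tests. Constant nodes (`k = 0`) take `k_r = k_e = k_s = 0` by convention
and are redescribed by a single empty schema.

## Effective graph, CM and DCM

The effective graph keeps edge `j → i` with weight `e_ji`; weights of
exactly zero (an input the LUT never uses) are pruned — no epsilon, since
the weights are exact rationals. The canalizing map renders each wildcard
schema with ≥ 2 literals as a t-unit whose threshold equals its literal
count, connected from the s-units of its input conditions and determining
the s-unit of the output state; single-literal schemata become direct
s→s edges (no threshold-1 t-units). Permutation groups from `F″` are
attached to t-units as textual fiber annotations rather than structural
merges — the information is preserved without complicating the graph
schema. Constant nodes yield an s-unit determination flagged
`unconditional`. The DCM is the union of all node CMs over shared
s-units (`2N` s-units total); its cost is linear in the number of nodes,
with the per-node Quine–McCluskey minimization as the only exponential
factor (an Espresso-style heuristic back end would be the natural
extension for very large `k`, and is out of scope).

Graphs export deterministically (sorted nodes, edges and attributes) to
DOT text and GraphML; rendering/layout is left to external tools.

## Dynamics and attractor enumeration

Successor tables are computed vectorized over all `2^N` configurations;
exhaustive attractor detection walks the functional graph, labeling each
trajectory, which yields periods, cycle members and exact basin sizes.
Exhaustive routines are guarded by a configurable limit (default
`N ≤ 20`, hard ceiling 30 — full state spaces beyond that are a memory
promise we do not make).

The `sat` method trades basins for scale: a small embedded DPLL solver
(unit propagation, deterministic branching) is queried for any
configuration not yet excluded; the deterministic trajectory from that
configuration is followed until it closes a new cycle or meets explored
territory, and every visited configuration is excluded with a blocking
clause. Unsatisfiability proves the attractor set complete. This is a
solver-guided exhaustive-completion scheme rather than a bounded-model-
checking unrolling; its practical ceiling is the number of configurations
actually visited, so it suits networks whose transient trees are shallow.
Equivalence with the exhaustive method is asserted on random ensembles in
the tests.

## Control

Interventions are instantaneous bit-flips of driver nodes: a controlled
edge goes from each configuration to each of the `2^|D| − 1`
configurations differing on a non-empty driver subset (flip, then natural
dynamics resume — the flip is not fused with a synchronous step; this
matches the stated controlled-edge count). Reachability fractions
`r(G_D, x) = |reachable \ {x}| / (2^N − 1)` are computed by SCC
condensation plus bitmask propagation in reverse topological order;
`R̄_D` averages `r` over all configurations and `C̄_D = R̄_D − R̄_∅`.
`R̄_D = 1` iff the CSTG is strongly connected.

The controlled attractor graph has the uncontrolled attractors as
vertices and an edge `κ → γ` when any member of cycle κ reaches any
member of cycle γ in the CSTG (cycle members are mutually reachable, so
the choice of member is immaterial; reachability is transitive, so the
CAG is transitively closed and out-degrees are reachable counts).
Self-edges are not stored. `Ā_D` averages, over attractors, the fraction
of *other* attractors reached, mirroring the "other configurations"
convention of `r`; with a single attractor `Ā_D` is defined as 1 (the
fully-controlled value). Subset sweeps are capped at size 4 by default as
a combinatorial guard.

Driver heuristics: structural controllability returns the in-copies left
unmatched by a deterministic Kuhn maximum matching on the out/in
bipartite split of the wiring (self-edges matchable; a perfect matching
returns the first-declared node), cross-checked against an independent
Hopcroft–Karp matching in the tests. The minimum dominating set
(out-domination) is found exactly by lexicographic exhaustive search for
`N ≤ 25` and by the standard greedy cover beyond, flagged `exact=False`.

## cnet text dialect

```
.v N                       # node count
# <index> = <name>         # optional name directives (comments)
.n <index> <k> <inputs..>  # 1-based indices; first input = MSB of rows
<symbols> <output>         # one row per line; '-' expands to both values
```

After wildcard expansion every row must be assigned exactly once:
re-assignments (even consistent ones) and missing rows are parse errors
with line numbers. Constant nodes (`k = 0`) have a single output-only
row. The writer emits rows in ascending order without `-`, so
write→parse round-trips reproduce the network exactly.

## Packaged fixtures

Fixtures are transcriptions of published logical models into the cnet
dialect, generated programmatically and frozen as text:

* **thaliana** — the floral-organ determination network (Chaos et al.
  2006; Boolean lineage of Espinosa-Soto et al. 2004). Constitutive genes
  LUG and CLF are constant-1 nodes; the developmental input UFO holds its
  state via an identity self-input, so both of its values persist. The
  transcription reproduces the published behaviour exactly where the
  model is documented: TFL1 switches on iff LFY=0 ∧ EMF1=1 ∧ AP1=0 with
  AP2 wired but inert; LFY switches on when either TFL1 or EMF1 is
  absent; the AG table lists AG and AP1 among its inputs with zero
  effectiveness while CLF retains a small one; and the synchronous
  dynamics converges from every configuration onto exactly ten
  fixed points — four inflorescence states (UFO × WUS free) and the
  sepal, petal (±UFO), stamen (±UFO) and carpel fates. FUL, once
  established, persists until AP1 or TFL1 shuts it down; this
  self-maintenance is required for the global convergence the published
  model exhibits.
* **budding_yeast** — Li et al. 2004 cell-cycle threshold rules tabulated
  into LUTs (activators +1, inhibitors −1; ties hold the state except for
  the five self-degrading proteins, which decay). Reproduces the
  published seven fixed points with the G1 state draining 1764 of 2048
  configurations — both asserted in the tests.
* **drosophila_cell** — a synthetic single-cell reduction of the segment
  polarity network (after Albert & Othmer 2003): one parasegment cell
  with the neighbouring WG/HH signals and the SLP prepattern aggregated
  into held external inputs. A convenience fixture; no published numbers
  are claimed for it.
* **motif_\*** — two- and three-node control motifs (chain, mutual
  inhibition, copy loop).

## Random ensemble and what the tests do and do not show

`random_nk(N, K, bias, seed)` draws, per node, `K` distinct uniform
inputs (self allowed) and i.i.d. Bernoulli(`bias`) LUT outputs — the
classical NK ensemble, reproducible by seed. Property tests run on this
ensemble at small sizes (`N ≤ 8`, `K ≤ 3`, 100–200 draws per property),
checking oracle equivalence of the minimization, permutation closure,
measure bounds and identities, STG functionality, basin partitioning,
SAT/exhaustive agreement, and control-measure ordering and monotonicity.
Passing them shows the algorithms are correct on the model class; it does
not show anything about the statistics of *biological* networks, whose
LUTs are far more canalizing than unbiased random ones — that is what the
transcribed fixtures probe.

## Numerical and degenerate-case choices

* All measures and fractions are exact rationals end to end; floats
  appear only at presentation boundaries (CLI, graph attributes).
* Deterministic tie-breaks everywhere: canonical schema ordering,
  lexicographic dominating sets, declaration-order matchings, sorted
  graph exports (bit-identical re-export).
* Degenerate inputs: `k = 0` nodes (constants) are first-class; empty
  driver sets give the plain STG; a single-attractor CAG has no edges and
  `Ā = 1`; empty off/on-sets yield empty schema sets.

## Known limitations

* The two-symbol group search is heuristic (validated, but a pathological
  LUT could admit a larger disjoint family than the packing finds).
* The solver-guided attractor path blocks every visited configuration, so
  its memory grows with explored state, not with `N`; it extends the
  exhaustive range rather than replacing bounded model checking for
  thousands of variables.
* Exact minimum dominating sets use exhaustive search; beyond `N = 25`
  the greedy result is an upper bound only.
* Asynchronous update schedules, multi-valued automata and heuristic
  (Espresso-style) minimization are out of scope.
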