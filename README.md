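# bncana

Canalization and control analysis for Boolean network models of
biochemical regulation.

Logical (Boolean) models capture the dynamics of gene regulatory and
signaling networks without kinetic parameters: each molecular species is a
binary automaton updated synchronously from a look-up table (LUT) over its
inputs. Most biological automata are strongly *canalizing* — for many
transitions, only a few inputs actually decide the outcome. `bncana`
charts that redundancy and exploits it:

* **Schemata redescription.** Each LUT is minimized to its prime
  implicants (Quine–McCluskey), giving *wildcard schemata* `F′` where `#`
  marks an input that is irrelevant in context; a second pass finds
  *two-symbol schemata* `F″` whose position-free marks (`°`) capture
  groups of inputs that may permute freely (e.g. a majority function is
  fully symmetric).
* **Canalization measures.** From the schemata: input redundancy
  `k_r(x)` (mean number of `#` per LUT entry, each entry scored by its
  most-redundant covering schema), effective connectivity
  `k_e = k − k_r`, input symmetry `k_s` (same tally over `°`), and
  per-input profiles `r_j`, `e_j = 1 − r_j`, `s_j` (averaged over all
  covering schemata per entry). All arithmetic is exact (rationals).
* **Network maps.** The *effective graph* re-weights the wiring by
  `e_ji`, pruning edges the dynamics never uses; the *canalizing map* (CM)
  renders a node's minimized logic as a McCulloch–Pitts threshold network
  of s-units (variable states) and t-units (condition thresholds); gluing
  all CMs over shared s-units yields the *dynamics canalizing map* (DCM).
* **Dynamics.** Synchronous state-transition graphs (STG), complete
  attractor enumeration with basins (exhaustive) or via a solver-guided
  search with blocking clauses (no STG materialization).
* **Control.** For a driver set `D` of nodes open to instantaneous
  bit-flips, the controlled STG adds `2^|D| − 1` intervention edges per
  configuration. Reachability measures follow: `R̄_D` (mean fraction of
  other configurations reachable), `C̄_D = R̄_D − R̄_∅`, the controlled
  attractor graph (CAG), and `Ā_D` (mean fraction of other attractors
  reachable). Driver-set heuristics: maximum-matching structural
  controllability and minimum dominating sets.

Transcriptions of published models ship as text fixtures: the
*Arabidopsis thaliana* floral-organ network (Chaos et al. 2006), the
budding-yeast cell cycle (Li et al. 2004), a simplified single-cell
segment-polarity network (after Albert & Othmer 2003), and small control
motifs. A seeded random NK (Kauffman) generator supports experiments and
property tests.

## Worked example

The floral-repressor automaton TFL1 (inputs AP2, LFY, EMF1, AP1) from the
packaged *Arabidopsis* network:

```python
>>> from bncana import load_example, enumerate_prime_implicants, canalization_summary
>>> net = load_example("thaliana")
>>> lut = net["TFL1"]
>>> [str(s) for s in enumerate_prime_implicants(lut, 1)]
['#010 -> 1']
>>> sorted(str(s) for s in enumerate_prime_implicants(lut, 0))
['###1 -> 0', '##0# -> 0', '#1## -> 0']
```

A single conjunction of three conditions (LFY=0 ∧ EMF1=1 ∧ AP1=0) turns
the node on, while any one of three single conditions turns it off — and
AP2, although wired in, never matters:

```python
>>> s = canalization_summary(lut)
>>> s.k, s.k_r, s.k_e           # in-degree, input redundancy, effective connectivity
(4, Fraction(11, 4), Fraction(5, 4))
>>> {n: float(e) for n, e in zip(s.input_names, s.e)}
{'AP2': 0.0, 'LFY': 0.4166666666666667, 'EMF1': 0.4166666666666667, 'AP1': 0.4166666666666667}
```

`e(AP2) = 0` means the AP2→TFL1 edge disappears from the effective graph:
of the four wired inputs only 1.25 are effectively needed on average.
Network-level dynamics and control:

```python
>>> from bncana import find_attractors, control_report
>>> len(find_attractors(net))          # inflorescence + floral organ fates
10
>>> rep = control_report(net, ("UFO", "LUG", "CLF", "SEP", "TFL1"))
>>> float(rep.mean_reachable), float(rep.mean_reachable_attractors)
(0.02356982634968108, 0.45555555555555555)
```

Driving these five nodes steers the network between 45.6% of ordered
attractor pairs on average, even though only 2.4% of raw configurations
are reachable from a typical state.

The same analyses are available from the shell:

```sh
bncana attractors example:thaliana
bncana canalization model.cnet --node TFL1 --norm max
bncana effective-graph model.cnet -o eff.graphml
bncana control model.cnet --drivers UFO,SEP --json
bncana drivers model.cnet --method sc
bncana generate --n 10 --k 2 --seed 1 -o random.cnet
```

Networks are read from cnet-style truth-table text files (see
`docs/methods.md` for the dialect) or built programmatically from
`LookupTable` objects.

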