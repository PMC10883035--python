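# ringlock

Topology-based detection and tracking of **deadlocks** — consequential,
pull-stable interlockings of unlinked ring polymers — in coarse-grained
ring-polymer melts, together with the analyses built on top of them:
deadlock-cluster graphs, threading classification, mobility metrics, and a
desk-scale Kremer–Grest simulator with active (hot-stretch) rings.

## Who this is for

Soft-matter and polymer-physics researchers studying entangled ring melts:
active topological glasses, ring melts under elongational or shear flow,
chromatin-inspired ring mixtures — any system where rings that are neither
knotted nor linked can still jam each other geometrically, and where one
wants to find those pairs in an instantaneous configuration, not by
watching trajectories.

## The reconnection method

Two rings are *deadlocked* when they cannot be pulled apart from their
exposed ends without a chain crossing, even though each ring is unknotted
and the pair is unlinked. The detector turns this geometric property into a
topological one:

1. **Prefilter.** Examine all distinct ring pairs and discard the linearly
   separable ones (a separating plane exists ⇒ evidently disentangled).
   Separability is decided by a linear program with a maximized margin.
2. **Exposed segments.** For each retained pair, find every exposed
   three-monomer segment: a window `{i−1, i, i+1}` that is linearly
   separable from all other monomers of *both* rings. The separating
   normal is the window's outward direction.
3. **Cut selection.** Pick one exposed segment per ring, furthest from the
   pair's center of mass, whose four termini rays mutually diverge (each
   radial extension clears every bond of both chains by `ε_arc ≥ 1σ`).
4. **Reconnection.** Remove the middle monomer of each segment, opening
   both rings into chains; extend the four termini radially to enclosing
   spheres and cross-wire chain ends with great-circle arcs. The two
   possible wirings — `(a₁b₁, a₂b₂)` and `(a₁b₂, a₂b₁)` — each yield a
   single closed curve.
5. **Knot test.** The pair is deadlocked iff both closures are knotted
   (free iff both are unknotted; a disagreement is reported as
   indeterminate, never resolved silently). Knottedness is decided by KMT
   simplification, generic projection, and exact integer evaluation of the
   Alexander polynomial: `(|Δ(−1)|, |Δ(−2)|) ≠ (1, 1)` certifies a knot.

Downstream, deadlocked pairs define a graph over rings whose connected
components are deadlock clusters (`n_k` clusters of size `k`, largest
cluster, peak times `t_max(k)`); threading is detected as piercing of a
ring's spanning surface, and nondeadlocked rings split into NtD (threaded
by deadlocked rings), NtN and unthreaded; mobility is
`μ(t, t₀) = ⟨g₃(t, t₀)⟩/(t − t₀)` with `⟨g₃⟩` the mean squared COM
displacement, and `τ_diff = ⟨R_g²⟩/6D`.

All geometry runs in reduced units: lengths in σ, energies in ε, times in τ.

## Worked example

```python
import numpy as np
from ringlock import make_labeled_pair, classify_pair, ClosureParams, pull_apart_oracle

pair = make_labeled_pair("deadlocked", seed=3)   # two hairpins, mutually wrapped
verdict = classify_pair(pair.ring_a, pair.ring_b, ClosureParams(seed=7))
print(verdict.verdict)                            # deadlocked
print([(i.det_minus1, i.det_minus2) for i in verdict.invariants])
print(pull_apart_oracle(pair.ring_a, pair.ring_b))
```

prints

```
deadlocked
[(9, 20), (9, 49)]
stuck
```

Both reconnection wirings are knotted — `|Δ(−1)| = 9` for each closure —
so the pair is deadlocked, and the physical oracle (pulling the rings
apart along their COM axis with bonds and excluded volume active) confirms
they jam. A `threaded_free` pair, by contrast, classifies `free` with both
closures at `(1, 1)` and separates under pulling.

A full melt pipeline from the shell:

```bash
ringlock simulate --config sim.json --steps 2000 --dump-every 200 --out melt.dump
ringlock scan melt.dump --out edges.csv --verdicts verdicts.jsonl
ringlock thread melt.dump --out threads.csv
ringlock ntd threads.csv edges.csv --n-rings 20 --out labels.csv
ringlock clusters edges.csv --n-rings 20 --out stats.csv
ringlock mobility melt.dump --out mu.csv
```

## Layout

| module | contents |
| --- | --- |
| `ringlock.melt_io` | LAMMPS data/dump + extended-XYZ I/O, ring traversals, periodic unwrapping |
| `ringlock.separability` | LP separating planes, candidate pairs, exposed segments |
| `ringlock.reconnection` | cut selection, closure construction, pair/frame classification |
| `ringlock.knots` | KMT simplification, crossing diagrams, exact Alexander magnitudes |
| `ringlock.threading_analysis` | spanning surfaces, piercing counts, NtD/NtN labels |
| `ringlock.clusters` | deadlock graphs, `n_k` populations, `t_max`, hub cuts |
| `ringlock.mobility` | `g₃`, `μ`, group mobility, `τ_diff` |
| `ringlock.simulator` | Kremer–Grest BAOAB engine, melt packing, ring cutting, pull-apart oracle |
| `ringlock.fixtures` | reference knots, labeled ring pairs, synthetic graph sequences |
| `ringlock.cli` | the `ringlock` command |

See `docs/methods.md` for model details, parameter choices and limitations.
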