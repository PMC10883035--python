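# Methods

This note records the models, algorithms and parameter choices behind
`ringlock`, what the synthetic generators do and do not emulate, and the
known limitations. Units throughout: lengths in σ (bead diameter), energies
in ε, times in τ, with k_B = 1 and bead mass 1.

## Deadlock detection by reconnection

A deadlocked pair is an unlinked, individually unknotted pair of rings that
cannot be pulled apart from its exposed ends without a chain crossing. The
detector converts this into a knot computation: cut one exposed segment per
ring far from the intermingling region, extend the four new termini away
from both rings, and join them pairwise into a single closed curve. If the
interlock is real, the closure is knotted no matter which of the two
pairings is used; if the rings are merely intermingled or threaded, both
closures are unknots.

**Separability.** The prefilter and the exposure test both reduce to linear
separability of point sets, solved as an LP (HiGHS): maximize the margin δ
of `w·x = c` subject to `|w_i| ≤ 1`, with a small L1 tie-break (10⁻⁵) on
`w` so symmetric inputs return the axis-aligned plane. The reported margin
is the Euclidean margin of the plane found — a lower bound within √3 of the
optimum, which is irrelevant to the binary verdict. The decision threshold
is `min_margin = 10⁻⁹ σ`: separability is conceptually binary and the guard
only suppresses floating-point flip-flop. An exposed segment is a cyclic
three-monomer window separable from *all* remaining monomers of both rings;
note this makes exposure a pair-level property — windows facing the partner
ring are never exposed, at any distance.

**Cut selection and divergence.** Candidate segment pairs (one per ring)
are ranked by summed window distance to the pair's center of mass,
descending, ties broken by lower (ring, bead) index. A pair is accepted
when its four termini rays diverge, operationalized as: every radial leg,
beyond 1σ from its terminus, clears every bond of both chains by
`ε_arc` (bonds incident to that terminus's own window exempt — with the
window's own separating plane this clearance is in fact guaranteed
analytically, and the explicit check is verification); and legs of termini
from different segments clear each other by `ε_arc`. Same-segment termini
share one outward normal — parallel rays cannot converge — and are exempt.
A failed closure is retried once with the next-ranked pair.

**Closure geometry.** Termini extend radially along their outward
directions to spheres centered on the pair COM. The two arcs of one
closure run on spheres of different radii (inner `2 × max pair extent`,
outer `+ 2ε_arc + 1`), so they cannot cross each other; the inner arc's
great-circle track additionally detours around the two points where the
outer legs pierce the inner sphere. This matters: with both arcs on one
sphere their tracks generically intersect and the closure's knot type
becomes a discretization accident. Defaults: `ε_arc = 1σ`, arc step
`0.5σ`, middle-removal width 1 bead (configurable to any odd width).

**Verdict policy.** Deadlocked iff both wirings knotted; free iff both
unknotted (or the pair was separable outright); anything else —
disagreement, no divergent cut, closure failure, degenerate projections —
is *indeterminate* and carried as a diagnostic, never majority-resolved.

## Knot engine

KMT simplification removes a vertex when its elision triangle is crossed by
no other segment of the curve (near-singular contacts within 10⁻⁹ keep the
vertex; in-plane contacts are resolved by 2-D clipping, where a bare corner
touch does not block). Sweeps run in index order to a fixpoint, which makes
the reduction deterministic.

The simplified curve is projected along a seeded random direction; any
non-generic incidence (parallel overlapping edges, endpoint crossings,
depth ties, coincident crossings — tolerance 10⁻⁹) raises a retry, up to 20
directions. From the crossing diagram the Alexander matrix is built from
the Wirtinger relations (positive crossing row `t·x_in + (1−t)·x_over −
x_out`, negative row `x_in + (t−1)·x_over − t·x_out`), one row and column
deleted, and the determinant computed *exactly*: the entries are linear in
t, so the determinant polynomial is obtained by fraction-free integer
Bareiss evaluation at integer points followed by exact interpolation. The
unit `±t^k` is stripped and the polynomial evaluated at t = −1 and −2.
This is why both magnitudes are well defined: a direct numeric determinant
at t = −2 would carry a residual power-of-two that cannot always be
normalized away. The unknot gives (1, 1); any other pair certifies a knot;
`|Δ(−1)|` must be odd, and an even value is treated as a broken diagram
and retried. Alexander-trivial knots would be missed — irrelevant for the
low-complexity closures produced here, but a real limitation for exotic
inputs.

## Threading surfaces

True minimal surfaces are replaced by a layered cone mesh over the ring
polygon (default 4 layers) relaxed by up to 200 accept-if-area-decreases
Jacobi sweeps of the interior vertices, boundary fixed, with damped
fallback so total area is monotonically non-increasing. Piercings are
transversal segment–triangle intersections (batched Möller–Trumbore);
grazing contacts within 10⁻⁹ are re-counted under a tiny fixed offset of
the other ring. For unlinked pairs the count is even; an odd count is
surfaced as a linkage warning. Threading requires count ≥ 2 (one passage
in, one out — the minimal transversal count for an unlinked pair).
Piercing counts on strongly non-convex rings may differ from true minimal
surfaces; the parity and zero/nonzero structure used downstream is robust
to this, totals on pathological shapes are not.

## Cluster and mobility analyses

Deadlock edges define a simple graph over all N rings; isolated rings are
size-1 clusters. "Nontrivial" clusters are components with k ≥ 2; a
component with as many edges as vertices carries a cycle flag (cluster
graphs are not trees). `t_max(k)` is the earliest time at which the size-k
population peaks. Hub cutting removes the n highest-degree rings (degree
centrality, ties to lower id) — edges only, since cutting a ring open does
not remove it from the melt.

Mobility uses continuously unwrapped COM tracks: image flags when frames
carry them, otherwise minimum-image displacements accumulated frame to
frame (never between distant frames, which fails once displacements exceed
L/2). `μ(t, t₀) = ⟨g₃(t, t₀)⟩/(t − t₀)` averages over all rings by default;
group mobility evaluates `μ(t_i, t_{i−1})` on log-spaced grids per label
(deadlocked / NtD / NtN / unthreaded), flagging groups under 1% of rings
(or 3 rings) as scarce while still reporting them. `τ_diff = ⟨R_g²⟩/6D`
with D from a least-squares MSD slope over the last half of the trajectory
by default; a sublinear fit (R² < 0.9) warns and returns diagnostics.

## Simulator

Kremer–Grest bead-spring rings: FENE bonds (K = 30 ε/σ², R₀ = 1.5 σ) plus
purely repulsive truncated-shifted Lennard-Jones (WCA, cutoff 2^{1/6} σ)
between all bead pairs, which together forbid chain crossing. Langevin
integration uses the BAOAB splitting; the damping parameter 1.5 τ is read
as the velocity relaxation time (friction γ = 1/1.5 per unit mass), and
the O-step noise uses each bead's own target temperature — passive beads
at T = 1, a stretch of beads in each active ring at T_a = 3T (stretch
length 50 beads at production scale, shortened proportionally for desk
rings). With the thermostat off the step is exactly velocity Verlet, which
the energy-conservation checks exercise. Default dt = 0.005 τ (energy
tests use 2.5·10⁻⁴).

**Initialization.** Rings start as compact multi-turn torus coils (turns
chosen so the coil fits its lattice cell), placed with seeded random
orientations on a cubic lattice in a box large enough that they are
disjoint — hence unknotted, uncatenated and unthreaded by construction —
then box and ring centers contract by 3% steps toward the target density
with displacement-capped (≤ 0.05 σ) steepest-descent sweeps in between,
which cannot cross chains. The descent step sits below the overdamped
stability bound of the WCA/FENE stiffness; a larger step merely bounces.
Note the FENE+WCA bond rest energy is ≈ 20 ε/bond, so a healthy packed
melt reports ≈ 21 ε/bead of potential energy.

**Pull-apart oracle.** The ground-truth arbiter for pairwise interlocking:
quench the isolated pair, then apply equal-and-opposite constant forces
(default 8 ε/σ total per ring, spread over its beads) along the COM axis
with bonds and excluded volume active, integrating damped velocity-Verlet
at zero temperature with a 0.04 σ displacement cap. "Separated" when the
COM distance exceeds 3× the summed contour radii, or earlier once the
rings are linearly separable with a ≥ 1 σ margin (outward pulling cannot
re-entangle a margin-separated pair); "stuck" when the COM distance
plateaus (< 0.02 σ over 1200 steps) — the taut-bond, flat-distance
signature of a jam — or the step budget runs out. Inertial damped dynamics
is used deliberately: overdamped Euler at this stiffness requires a step
so small that the displacement cap erases the pull signal.

## Synthetic fixtures: what they emulate

The labeled pairs emulate the three pairwise situations a melt scan must
distinguish, with ground truth fixed by construction and certified under
rigid motions plus Gaussian vertex jitter up to 0.05 σ (the generator
refuses > 0.1 σ, which could change labels):

- **separable** — two circles with a clear gap;
- **threaded_free** — a narrow stadium loop dipping through a circle's
  disk and back (two opposite piercings, removable by translation);
- **deadlocked** — two hairpins whose folds helically wrap the *other*
  ring's doubled strand bundle by one full turn (a mutual girth hitch).
  The rings are individually unknotted and their linking number is zero
  (the wrap crossings cancel in signed pairs), yet pulling the far caps
  apart only tightens the wraps: unscrewing either fold would pump winding
  into the taut central section, which the tension forbids.

The deadlock geometry was chosen after explicitly testing the simpler hook
morphologies: flat J-hooks engaged orthogonally slip apart sideways, a
single half-turn hook yields one knotted and one unknotted wiring (the
method's indeterminate signature for a slippable hook), and an
eye-and-pinched-ring "necklace" separates because a flexible lobe can
collapse through the eye. Both the reconnection closures and the pull
oracle agree on all of these — which is itself a nontrivial cross-check of
the method. Melt deadlocks are more diverse than this one clasp family;
the fixtures certify the detector's discrimination, not the full
morphology spectrum of dense melts.

Reference curves (unknot, trefoil, figure-eight, granny = 3₁#3₁ built by
splicing two trefoils across a separating plane, so each splice segment
crosses the mid-plane exactly once) calibrate the knot engine against
symbolically evaluated Alexander polynomials. Aggregation schedules and
seeded random graphs exercise the cluster analytics against brute-force
oracles.

What passing fixture tests does *not* show: behavior at production melt
density (ρ = 0.85 σ⁻³, N = 1600 × 400), where exposure statistics,
indeterminate rates and threading multiplicities differ from desk scale;
long-time aging observables; or deadlocks irreducible to pairwise tests.

## Desk-scale study conditions

Analyses and checks run on melts of 8–20 rings × 20–60 beads at
ρ = 0.2 σ⁻³, desk-scale stand-ins for the production system: large enough
to exercise every code path (packing, activity, scanning, threading,
clusters, mobility) end-to-end, small enough for interactive runs. The
`SimParams` defaults keep the production force-field constants (T = 1,
T_a = 3T, damping 1.5 τ, ρ = 0.85, FENE/WCA as above); density and sizes
are overridden per run. Fixture rings are ~30–70 beads at spacing 0.95 σ,
near the FENE+WCA rest bond so the pull oracle sees a nearly relaxed
chain. Diffusion-recovery checks use 10⁴ synthetic Brownian COM tracks
(rigid 3-bead rings on exact random walks), where `μ = 6D` holds in
closed form.

## Known limitations

- Alexander magnitudes miss Alexander-trivial knots (none arise from the
  closures produced by the fixture and desk-melt geometry).
- The spanning-surface surrogate is not a true minimal surface; piercing
  counts on strongly non-convex rings are approximate (parity is exact for
  transversal configurations).
- The pull oracle explores a single pulling protocol; "stuck" is a
  statement about that protocol, not a proof that no escape path exists.
  Conversely its "separated" early exit is rigorous.
- The divergence predicate is a documented geometric substitute for
  informal "divergent outward directions"; other reasonable predicates
  would differ only on marginal cut candidates, which are retried anyway.
- Three-body deadlocks irreducible to pairwise tests are out of scope, as
  are linear-chain systems and triclinic/deforming boxes.
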