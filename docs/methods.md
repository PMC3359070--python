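# Methods

## Generating model

Alignments evolve along a fixed unrooted tree under Jukes–Cantor: along an
edge of length *t* (expected substitutions/site) at site-rate multiplier
*r*, a base is retained with probability 1/4 + (3/4)e^(−4rt/3) and
otherwise replaced by each alternative with probability
(1/4)(1 − e^(−4rt/3)).  The root sequence is uniform over {A,C,G,T};
sites are independent; no indels are simulated.

Among-site rate variation is the Γ+I mixed distribution: each site is
invariant (rate exactly 0) with probability `p_inv`, otherwise its rate is
drawn from a **continuous** Gamma(shape α, mean 1) and divided by
(1 − p_inv).  The rescaling makes the expected rate over *all* sites equal
to 1, so branch lengths keep their substitutions-per-site meaning; it is
the convention of the standard simulation and inference tools and is
mirrored exactly on the inference side (below), keeping simulated and
estimated branch lengths commensurable.  The study-wide generating values
are α = 1.0 and p_inv = 0.3.

Simulation is invariant in distribution to the traversal root because JC
is time-reversible with uniform stationary distribution (checked by a
test comparing re-rooted serializations).

## Model topologies

Two 11-taxon shapes, all "remaining branches" (RB) constant:

* **Topology A** — `((((t1,t2),(t3*,t4)),((t5,t6),(t7*,t8))),(t9,t10),t11)`;
  the starred leaves t3 and t7 carry the elongated terminal branches
  (LtB), each in a cherry whose stem is the short internal branch (SiB).
  t3 and t7 are separated by more than one internal edge, so their mutual
  attraction (class III) is not a trivial rearrangement.
* **Topology B** — a central edge of length SiB whose endpoints carry the
  short terminals t5 and t6 and, via internal edges of length LiB, a
  4-leaf clade {t1..t4} and a 5-leaf clade {t7,t8,(t9,(t10,t11))}.

The exact placement of background taxa is a package convention: the
published drawings are not recoverable from text alone, so the shapes
above were fixed once as the simplest arrangements satisfying every
stated constraint, and `TopologySpec` is an explicit, overridable record
of the focal elements so users can substitute other shapes.  RB defaults
to 0.05 substitutions/site (configurable), inside the study's
short-branch regime between the smallest and middle SiB grid values; the
published constant is likewise not recoverable from the text.

## Likelihood and optimization

Likelihoods are computed by Felsenstein pruning over compressed site
patterns.  Inference uses the **discrete** gamma approximation with
`n_categories = 4` equal-weight classes whose rates are the means of the
Gamma(α, mean 1) density over its inter-quantile intervals (mean, not
median: the mean preserves unit expected rate exactly).  Under Γ+I the
category rates are divided by (1 − p_inv), mirroring the simulator.  The
continuous-gamma / discrete-gamma asymmetry between simulation and
inference is deliberate and matches the study design.  A JC+Γ model with
α fixed at 100 serves as the no-ASRV setting; its log-likelihoods agree
with a strict single-rate model to within 0.1% relative (tested), though
the four category rates themselves still spread ≈ ±0.13 around 1
(quartile means of a distribution with sd 0.1).

Numerical choices:

* Per-node partial-likelihood rescaling with accumulated per-category log
  factors; without it the 100,000-site long-branch cells underflow.
* Branch lengths clamped to [1e-8, 20]; optimized one edge at a time by
  bounded Brent on the closed-form 1-D profile
  L_k(t) = e_k·(A·B)/4 + (1−e_k)·(ΣA)(ΣB)/16, with the two flanking
  partials held fixed.  Sweeps visit edges in depth-first order, carrying
  the complement partial down and refreshing each subtree partial on the
  way back up, so every edge sees exact current partials at the cost of a
  few kernel passes per node.
* α and p_inv are strongly correlated (a likelihood ridge); when both are
  free they are optimized **jointly** by Nelder–Mead on (log α, p_inv)
  (bounds α ∈ [0.01, 100], p_inv ∈ [0, 0.99], clipped), alternating with
  branch-length sweeps until the joint log-likelihood gain is < 1e-4.
  Coordinate-wise alternation of the two parameters crawls along the
  ridge and was rejected.  Boundary solutions are reported as such.
* JC distances cap at 5.0 when the mismatch fraction reaches 3/4, keeping
  neighbor joining defined in the saturated regime the grid enters.
* The inner loops (JC edge kernel, rescaling, per-edge profile
  likelihood) are numba-compiled; the rank-one-plus-identity structure of
  the JC transition matrix reduces every matrix–vector product to an
  axpy on four states.

## Tree search

`ml_search` starts from neighbor joining on JC distances and hill-climbs
with nearest-neighbor interchanges.  Each round scores both NNI
rearrangements of every internal edge by re-optimizing only the central
branch against fixed outer partials — cheap, but in long-branch regimes
this score can *under-rank* an improving neighbor, because after the swap
the remaining branch lengths must shift substantially.  The search
therefore verifies the top `verify_top` (default 6) scored candidates
with a real optimization before declaring convergence; without this
verification the hill-climb demonstrably sticks in the long-branch
attractor several dozen log-units below the optimum.  While the topology
is still moving, branch lengths and free parameters are optimized to a
loose interim tolerance (0.05 log-units); the final tree is re-optimized
to the tight tolerance (1e-4).  Ties between equally improving neighbors
break on the lexicographically smallest defining bipartition, making the
whole search deterministic.  Accepted moves must improve the
log-likelihood by > 1e-4, so the reported optimum never falls below the
start tree's score.

The move set is NNI only (no SPR/TBR), and the start tree is NJ — a
documented stand-in for the original heuristic search whose details are
not specified; the likelihood-verification step above is what makes this
combination reliable at 11 taxa.

## Error classification

Precedence: exact topology match → `correct`; then (topology A only) the
two long terminals adjacent → `class_III`; then (topology B only) the two
short terminals adjacent → `class_I`; then exactly one focal long element
(a long-terminal leaf for A, an intact long-branch clade for B) whose
removal makes the remaining restriction identical to the truth →
`class_II`; else `other`.  "Grouped/attracted" is operationalized as
unrooted adjacency (sharing an internal node), the strictest reading that
needs no root.  Under these strict rules class II cannot actually occur
for topology B: detaching a neighbor of the central branch necessarily
joins the two short terminals (class I wins by precedence), and the
symmetric residual cases restore the truth under *either* element's
removal and fall to `other`.  Class II for topology B is therefore a
theoretical category here; in practice B's errors surface as class I,
which matches how the simulation grid behaves.

## Experiment design and scale

The grid reproduces the factorial design: SiB ∈ {0.01, 0.05, 0.1, 0.3,
0.5}; elongated branch 0.1–1.5 in steps of 0.2 (ratios 1/5 to 150);
alignment lengths {2000, 3000, 4000, 10000} with 100,000 admitted only
under the correct-parameter model; the four ASRV settings; 100 replicates
by default.  Every replicate's RNG substream is derived from
(master seed, topology, SiB index, elongation index, length, model,
replicate), so any single replicate is reproducible in isolation and the
whole grid is byte-deterministic given the master seed.  The full grid is
a cluster-scale computation; the shipped analyses (tests and
`scripts/acceptance.py`) run the package's own reduced design — 10–20
replicates per condition, 10,000 sites for the estimation targets,
100,000 sites for the consistency trend — which the replicate and length
fields of `GridConfig` express directly.

## What the simulations do and do not show

The generator emulates exactly the statistical structure the inference
assumes (JC, site independence, Γ+I rates, no indels, equal base
frequencies).  Passing tests therefore demonstrate properties of ML *under
a correctly specified or deliberately restricted model family* — the
interesting failures are attributable to branch-length geometry, not
model misspecification.  Real data violate most of these assumptions
(compositional bias, site-specific constraints, indels, non-reversible
processes), so observed robustness here is a best case, and the artefact
classes are lower bounds on what empirical analyses may face.

## Known limitations

* JC only; no GTR/HKY, codon or amino-acid models.
* NNI-only search; pathological start trees outside the study's regimes
  may still strand the hill-climb.
* The classifier assumes fully resolved 11-taxon trees with the builders'
  focal elements; polytomies are out of scope.
* The α = 100 stand-in for "no ASRV" is an approximation at the
  likelihood level, not a literal single-rate model (the study's own
  convention).
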