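# lbasim — long-branch artefacts in maximum-likelihood phylogenetics

`lbasim` is a simulation laboratory for studying when maximum-likelihood
(ML) tree inference fails on trees with strong branch-length disparity,
*even when the substitution model is exactly right*.  It is aimed at
phylogeneticists and methods developers who want a controlled, fully
reproducible testbed for long-branch artefacts (LBA) beyond the classical
4-taxon Felsenstein zone.

## What it does

The package simulates gap-free DNA alignments on two 11-taxon model
topologies under the Jukes–Cantor model with continuous-gamma site rates
(shape α) plus a proportion of invariant sites (p_inv) — the Γ+I
mixed-distribution model — and re-infers trees by ML under four
among-site-rate-variation (ASRV) settings:

| setting   | model      | α        | p_inv    |
|-----------|------------|----------|----------|
| `g100`    | JC+Γ       | 100 (fixed; ≈ no ASRV) | — |
| `gi_true` | JC+Γ+I     | 1.0 (fixed)  | 0.3 (fixed) |
| `gi_est`  | JC+Γ+I     | estimated | estimated |
| `g_est`   | JC+Γ       | estimated | — |

Topology **A** elongates two *terminal* branches (LtB) that are separated
by several internal edges; topology **B** elongates two *internal*
branches (LiB) flanking a short central branch (SiB) between two short
terminals.  Wrong inferred trees are classified into the three LBA
classes: **class I** (the two short terminals erroneously grouped, a
symplesiomorphy effect), **class II** (a single long element slipped to a
wrong attachment point, signal erosion), and **class III** (the two long
terminals mutually attracted, the Felsenstein case).

The likelihood engine is a Felsenstein-pruning implementation with
discrete-Γ(+I) mixtures (4 categories), per-node rescaling, Brent
branch-length optimization, joint (α, p_inv) estimation, and an NNI
hill-climbing search from a neighbor-joining start tree.  A grid runner
sweeps SiB × elongation × alignment length × model setting with
per-replicate, coordinate-addressed random substreams.

## Worked example

A hostile topology-B cell (LiB = 1.5, SiB = 0.01, 10,000 sites), analyzed
with the *correct model family* and both ASRV parameters estimated:

```python
import numpy as np
from lbasim import (build_topology_b, topology_b_spec, SimulationParams,
                    evolve_alignment, ml_search, classify, MODEL_SETTINGS,
                    rf_distance)

true_tree = build_topology_b(lib=1.5, sib=0.01)
spec = topology_b_spec()
rng = np.random.default_rng(42)
aln = evolve_alignment(true_tree,
                       SimulationParams(n_sites=10_000, alpha=1.0, p_inv=0.3),
                       rng)
result = ml_search(aln, MODEL_SETTINGS["gi_est"])
print(f"log-likelihood : {result.log_likelihood:.2f}")
print(f"alpha-hat      : {result.alpha:.3f}")
print(f"p_inv-hat      : {result.p_inv:.3f}")
print(f"RF distance    : {rf_distance(true_tree, result.best_tree)}")
print(f"error class    : {classify(spec, true_tree, result.best_tree).value}")
```

prints

```
log-likelihood : -64615.56
alpha-hat      : 0.960
p_inv-hat      : 0.315
RF distance    : 2
error class    : class_I
```

The ASRV parameters are recovered almost exactly (α̂ = 0.96 vs 1.0,
p̂_inv = 0.315 vs 0.3), yet the inferred tree is wrong: the two short
terminals t5 and t6 have been pulled together across the short central
branch — a class I artefact that accurate modelling does not prevent.

There is also a CLI (`lbasim simulate / infer / classify / grid /
summarize`); `lbasim grid --config grid.toml --out results/` runs a whole
factorial design and writes per-replicate records and per-cell summaries
as TSV.

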