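"""Tree search: JC distances, neighbor-joining start tree, branch-length
and rate-parameter optimization, and NNI hill-climbing under maximum
likelihood.

The search mirrors a standard ML heuristic: start from neighbor joining on
JC distances, then repeatedly optimize branch lengths (and any free ASRV
parameters), score every nearest-neighbor-interchange of every internal
edge by re-optimizing the central branch on fixed outer partials, and move
to the best improving neighbor until none improves.  All tie-breaks are
deterministic (lexicographically smallest defining bipartition).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .likelihood import (
    MAX_BRANCH,
    MIN_BRANCH,
    LikelihoodResult,
    ModelSpec,
    PruningEngine,
)
from .trees import Tree, parse_newick

__all__ = [
    "jc_distance_matrix",
    "nj_tree",
    "optimize_branch_lengths",
    "estimate_rate_parameters",
    "SearchConfig",
    "SearchResult",
    "ml_search",
]

JC_SATURATION_DISTANCE = 5.0  # distance assigned when p >= 0.75


def jc_distance_matrix(alignment: Alignment) -> np.ndarray:
    """Pairwise JC distances d = -(3/4) ln(1 - (4/3) p_mismatch).

    Saturated pairs (p >= 0.75) get the fixed cap so neighbor joining
    stays defined in the regimes the branch-length grid deliberately
    enters.  Row order follows ``alignment.labels``.
    """
    if alignment.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    data = alignment.data
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        mism = (data[i] != data[i + 1:]).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = -0.75 * np.log1p(-4.0 * mism / 3.0)
        dist = np.where(mism >= 0.75, JC_SATURATION_DISTANCE, dist)
        d[i, i + 1:] = dist
        d[i + 1:, i] = dist
    return d


def nj_tree(distances: np.ndarray, labels) -> Tree:
    """Neighbor-joining tree (negative intermediate lengths clamped to 0)."""
    labels = list(labels)
    distances = np.asarray(distances, dtype=float)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if distances.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(distances, distances.T):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) == 3:
        t = Tree()
        hub = t.add_node()
        d01, d02, d12 = distances[0, 1], distances[0, 2], distances[1, 2]
        lens = [
            max(0.0, (d01 + d02 - d12) / 2),
            max(0.0, (d01 + d12 - d02) / 2),
            max(0.0, (d02 + d12 - d01) / 2),
        ]
        for lab, ln in zip(labels, lens):
            t.connect(hub, t.add_node(lab), ln)
        return t
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    sk = skbio_nj(DistanceMatrix(distances, ids=labels))
    for node in sk.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    sk.write(buf)
    return parse_newick(buf.getvalue().strip())


def optimize_branch_lengths(tree: Tree, alignment: Alignment, model: ModelSpec,
                            alpha: float | None = None,
                            p_inv: float | None = None,
                            tol: float = 1e-6) -> tuple[Tree, LikelihoodResult]:
    """Coordinate-wise branch-length optimization at fixed model parameters."""
    engine = PruningEngine(alignment, model, alpha=alpha, p_inv=p_inv)
    engine.set_tree(tree)
    engine.optimize_branch_lengths(tol=tol)
    return engine.result_tree(), engine.result()


def estimate_rate_parameters(tree: Tree, alignment: Alignment,
                             model: ModelSpec,
                             joint_tol: float = 1e-4):
    """Fit the free ASRV parameters (and branch lengths, in alternation).

    Returns (alpha_hat, p_inv_hat, LikelihoodResult); entries are None for
    parameters the model does not free.  Boundary solutions are returned
    as such (the optimizer is bounded).
    """
    if not (model.estimates_alpha or model.estimates_p_inv):
        raise ValueError("model marks no parameter as 'estimate'")
    engine = PruningEngine(alignment, model)
    engine.set_tree(tree)
    engine.optimize_all(joint_tol=joint_tol)
    res = engine.result()
    a = engine.alpha if model.estimates_alpha else None
    p = engine.p_inv if model.estimates_p_inv else None
    return a, p, res


@dataclass(frozen=True)
class SearchConfig:
    """NNI hill-climbing knobs (tolerances in log-likelihood units).

    While the topology is still moving, branch lengths and parameters are
    optimized to the looser ``interim_tol``; the final tree is re-optimized
    to ``final_tol`` once no rearrangement improves.
    """

    move_tol: float = 1e-4
    max_rounds: int = 50
    interim_tol: float = 0.05
    final_tol: float = 1e-4
    verify_top: int = 6


@dataclass
class SearchResult:
    best_tree: Tree
    log_likelihood: float
    alpha: float | None
    p_inv: float | None
    n_rounds: int
    start_log_likelihood: float


def _central_edge_score(engine: PruningEngine, a_pieces, b_pieces):
    """Optimal log-likelihood over the central-edge length with the four
    subtree partials held fixed; returns (score, t_opt)."""
    (ta, sa), (tb, sb) = a_pieces
    (tc, sc), (td, sd) = b_pieces
    ab, asb = engine._edge_coeff_arrays(ta * tb, tc * td)
    fn = engine._edge_loglik_fn(ab, asb, sa + sb + sc + sd)
    res = minimize_scalar(lambda t: -fn(t), bounds=(MIN_BRANCH, MAX_BRANCH),
                          method="bounded", options={"xatol": 1e-6})
    return -float(res.fun), float(res.x)


def _nni_candidates(engine: PruningEngine):
    """Score both NNI rearrangements of every internal edge.

    Yields (score, t_opt, split_key, u_id, v_id, w_u, w_v) where the move
    exchanges tree neighbors w_u (of u) and w_v (of v), and split_key is
    the canonical sorted-label form of the rearranged central split.
    """
    engine._compute_down()
    tree = engine.tree
    all_leaves = tree.leaf_labels()
    anchor = min(all_leaves)
    n = len(engine.node_ids)
    for v in range(n):
        p = engine.parent[v]
        if p < 0 or engine.leaf_row[v] is not None:
            continue
        v_id = engine.node_ids[v]
        u_id = engine.node_ids[p]
        # pieces already transformed to the junction nodes
        u_pieces, v_pieces = [], []
        for c in engine.children[p]:
            if c != v:
                u_pieces.append((
                    engine._transform(engine._down[c], engine.edge_len[c]),
                    engine._dscale[c],
                    engine.node_ids[c],
                    tree.side_leaves(u_id, engine.node_ids[c]),
                ))
        if engine.parent[p] >= 0:
            comp, cscale = engine._complement_at(p)
            u_pieces.append((
                engine._transform(comp, engine.edge_len[p]),
                cscale,
                engine.node_ids[engine.parent[p]],
                all_leaves - tree.side_leaves(engine.node_ids[engine.parent[p]],
                                              u_id),
            ))
        for c in engine.children[v]:
            v_pieces.append((
                engine._transform(engine._down[c], engine.edge_len[c]),
                engine._dscale[c],
                engine.node_ids[c],
                tree.side_leaves(v_id, engine.node_ids[c]),
            ))
        if len(u_pieces) != 2 or len(v_pieces) != 2:
            continue
        (t0, s0, n0, l0), (t1, s1, n1, l1) = u_pieces
        (t2, s2, n2, l2), (t3, s3, n3, l3) = v_pieces
        # exchange u-piece 1 with either v-piece
        for w_v, a, b, new_v_side in (
            (n2, ((t0, s0), (t2, s2)), ((t1, s1), (t3, s3)), l1 | l3),
            (n3, ((t0, s0), (t3, s3)), ((t1, s1), (t2, s2)), l1 | l2),
        ):
            score, t_opt = _central_edge_score(engine, a, b)
            side = new_v_side if anchor not in new_v_side else all_leaves - new_v_side
            yield score, t_opt, tuple(sorted(side)), u_id, v_id, n1, w_v


def _apply_nni(tree: Tree, u: int, v: int, w_u: int, w_v: int,
               central_t: float) -> Tree:
    t = tree.copy()
    lu = t.disconnect(u, w_u)
    lv = t.disconnect(v, w_v)
    t.connect(u, w_v, lv)
    t.connect(v, w_u, lu)
    t.set_length(u, v, max(central_t, MIN_BRANCH))
    return t


def ml_search(alignment: Alignment, model: ModelSpec,
              config: SearchConfig | None = None) -> SearchResult:
    """NJ start + NNI hill-climbing ML search; returns the local optimum."""
    if alignment.n_taxa < 4:
        raise ValueError("tree search needs at least 4 taxa")
    config = config or SearchConfig()
    start = nj_tree(jc_distance_matrix(alignment), alignment.labels)
    engine = PruningEngine(alignment, model)
    engine.set_tree(start)

    def interim_opt():
        return engine.optimize_all(joint_tol=config.interim_tol,
                                   xatol=1e-5, param_maxfev=80)

    ll = interim_opt()
    start_ll = ll
    rounds = 0
    for _ in range(config.max_rounds):
        # Rank all rearrangements by the cheap central-edge score, then
        # verify the leaders with a real optimization: in long-branch
        # regimes the fixed-outer-partials score can rank an improving
        # neighbor below the current tree because the remaining branch
        # lengths must shift substantially after the swap.
        cands = sorted(_nni_candidates(engine), key=lambda c: (-c[0], c[2]))
        prev_tree = engine.result_tree()
        prev_alpha, prev_pinv = engine.alpha, engine.p_inv
        accepted = False
        for cand in cands[: config.verify_top]:
            _score, t_opt, _key, u, v, w_u, w_v = cand
            engine.set_tree(_apply_nni(prev_tree, u, v, w_u, w_v, t_opt))
            new_ll = interim_opt()
            if new_ll - ll > config.move_tol:
                ll = new_ll
                rounds += 1
                accepted = True
                break
            engine.alpha, engine.p_inv = prev_alpha, prev_pinv
            engine._update_rates()
        if not accepted:
            engine.set_tree(prev_tree)
            break
    ll = engine.optimize_all(joint_tol=config.final_tol)
    return SearchResult(
        best_tree=engine.result_tree(),
        log_likelihood=ll,
        alpha=engine.alpha if model.asrv_mode != "none" else None,
        p_inv=engine.p_inv if model.asrv_mode == "gamma_inv" else None,
        n_rounds=rounds,
        start_log_likelihood=start_ll,
    )
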