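"""Maximum-likelihood machinery: JC transition math, discrete-gamma(+I)
mixtures, and the pruning (post-order dynamic programming) likelihood.

The substitution model is Jukes–Cantor throughout.  Among-site rate
variation is one of

* ``none`` — a single rate class of rate 1;
* ``gamma`` — ``n_categories`` equal-weight discrete-gamma classes whose
  rates are the means of the Gamma(alpha, mean 1) density over its
  inter-quantile intervals;
* ``gamma_inv`` — the gamma classes mixed with a zero-rate invariant class
  of weight ``p_inv``; the gamma rates are divided by (1 - p_inv) so the
  model's overall expected rate stays 1, mirroring the simulator's
  convention (branch lengths stay commensurable between truth and fit).

Likelihoods are computed on compressed site patterns with per-node
rescaling (accumulated log factors) so 100,000-site, long-branch cases do
not underflow.  A brute-force enumeration over ancestral states serves as
an independent oracle for small trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from . import _kernels
from .alignment import Alignment
from .trees import Tree

__all__ = [
    "ModelSpec",
    "LikelihoodResult",
    "jc_transition",
    "discrete_gamma_rates",
    "PruningEngine",
    "tree_log_likelihood",
    "brute_force_log_likelihood",
]

ESTIMATE = "estimate"

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0
ALPHA_BOUNDS = (0.01, 100.0)
PINV_BOUNDS = (0.0, 0.99)


@dataclass(frozen=True)
class ModelSpec:
    """ASRV configuration of a JC likelihood model.

    ``alpha`` / ``p_inv`` are numbers when fixed or the string
    ``"estimate"`` when free.  ``n_categories`` is the discrete-gamma
    resolution (the study uses 4).
    """

    asrv_mode: str = "none"
    alpha: float | str | None = None
    p_inv: float | str | None = None
    n_categories: int = 4

    def __post_init__(self):
        if self.asrv_mode not in ("none", "gamma", "gamma_inv"):
            raise ValueError(f"unknown asrv_mode {self.asrv_mode!r}")
        if self.asrv_mode == "none":
            if self.alpha is not None or self.p_inv is not None:
                raise ValueError("alpha/p_inv are meaningless with asrv_mode='none'")
        else:
            if self.alpha is None:
                raise ValueError("alpha required for gamma models")
            if self.alpha != ESTIMATE and not float(self.alpha) > 0:
                raise ValueError("fixed alpha must be > 0")
        if self.asrv_mode == "gamma_inv":
            if self.p_inv is None:
                raise ValueError("p_inv required for gamma_inv")
            if self.p_inv != ESTIMATE and not 0.0 <= float(self.p_inv) < 1.0:
                raise ValueError("fixed p_inv must be in [0, 1)")
        elif self.p_inv is not None and self.asrv_mode == "gamma":
            raise ValueError("p_inv is meaningful only with asrv_mode='gamma_inv'")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @property
    def estimates_alpha(self) -> bool:
        return self.alpha == ESTIMATE

    @property
    def estimates_p_inv(self) -> bool:
        return self.p_inv == ESTIMATE


@dataclass
class LikelihoodResult:
    """Total and per-site log-likelihoods plus fitted ASRV parameters."""

    log_likelihood: float
    per_site: np.ndarray
    alpha: float | None = None
    p_inv: float | None = None


def jc_transition(edge_length: float, rate: float = 1.0) -> np.ndarray:
    """JC transition probability matrix along one edge.

    Diagonal 1/4 + (3/4)e^(-4rt/3); off-diagonal 1/4 - (1/4)e^(-4rt/3).
    """
    if edge_length < 0 or rate < 0:
        raise ValueError("edge_length and rate must be >= 0")
    e = np.exp(-4.0 * rate * edge_length / 3.0)
    p = np.full((4, 4), 0.25 * (1.0 - e))
    np.fill_diagonal(p, 0.25 + 0.75 * e)
    return p


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Equal-weight discrete-gamma rate multipliers (interval means).

    Category k's rate is the mean of the Gamma(alpha, mean 1) density over
    the interval between the k/c and (k+1)/c quantiles; the weighted mean
    of the returned rates is exactly 1.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    c = int(n_categories)
    if c < 1:
        raise ValueError("n_categories must be >= 1")
    if c == 1:
        return np.array([1.0])
    bounds = gamma_dist.ppf(np.arange(1, c) / c, a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * bounds)
    cum = np.concatenate([[0.0], upper, [1.0]])
    rates = c * np.diff(cum)
    return rates / np.mean(rates)


def _compress(alignment: Alignment):
    patterns, inverse, counts = np.unique(
        alignment.data, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, inverse.ravel(), counts.astype(float)


class PruningEngine:
    """Felsenstein-pruning likelihood on compressed site patterns.

    The engine owns a rooted view of an unrooted tree (the calculation root
    is an arbitrary internal node; reversibility makes the choice
    irrelevant) and concrete values of the ASRV parameters.  It is the
    workhorse behind likelihood evaluation, branch-length optimization and
    the NNI search.
    """

    def __init__(self, alignment: Alignment, model: ModelSpec,
                 alpha: float | None = None, p_inv: float | None = None):
        self.alignment = alignment
        self.model = model
        self.patterns, self.site_to_pattern, self.counts = _compress(alignment)
        self.n_patterns = self.patterns.shape[1]
        self.constant = (self.patterns == self.patterns[0]).all(axis=0)
        eye = np.eye(4)
        self._leaf_cond = {
            lab: eye[self.patterns[i]] for i, lab in enumerate(alignment.labels)
        }
        self.alpha = self._resolve(model.alpha, alpha, default=1.0)
        self.p_inv = self._resolve(model.p_inv, p_inv, default=0.2)
        if model.asrv_mode != "gamma_inv":
            self.p_inv = 0.0
        self._update_rates()
        self.tree: Tree | None = None

    @staticmethod
    def _resolve(spec_value, override, default):
        if override is not None:
            return float(override)
        if spec_value is None or spec_value == ESTIMATE:
            return float(default)
        return float(spec_value)

    # -- model parameters ---------------------------------------------

    def set_parameters(self, alpha: float | None = None,
                       p_inv: float | None = None) -> None:
        if alpha is not None:
            self.alpha = float(alpha)
        if p_inv is not None:
            if self.model.asrv_mode != "gamma_inv":
                raise ValueError("p_inv applies only to gamma_inv models")
            self.p_inv = float(p_inv)
        self._update_rates()

    def _update_rates(self) -> None:
        mode = self.model.asrv_mode
        if mode == "none":
            rates = np.array([1.0])
        else:
            rates = discrete_gamma_rates(self.alpha, self.model.n_categories)
            if mode == "gamma_inv":
                rates = rates / (1.0 - self.p_inv)
        self.rates = rates
        self.n_cat = len(rates)
        self._stale = True  # partials no longer match the rate mixture

    # -- tree arrays ---------------------------------------------------

    def set_tree(self, tree: Tree) -> None:
        """Adopt (a copy of) ``tree``; taxa must match the alignment."""
        if tree.leaf_labels() != frozenset(self.alignment.labels):
            raise ValueError(
                "tree leaves do not match alignment taxa: "
                f"{sorted(tree.leaf_labels() ^ set(self.alignment.labels))}"
            )
        self.tree = tree.copy()
        t = self.tree
        internal = [v for v in t.nodes if not t.is_leaf(v)]
        root = max(internal, key=lambda v: (t.degree(v), -v)) if internal else t.nodes[0]
        order: list[int] = []
        parent_of: dict[int, int | None] = {root: None}
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            for w in t.neighbors(v):
                if w != parent_of[v]:
                    parent_of[w] = v
                    stack.append(w)
        order.reverse()  # postorder: children before parents, root last
        self.node_ids = order
        self._index = {nid: i for i, nid in enumerate(order)}
        n = len(order)
        self.parent = np.full(n, -1, dtype=int)
        self.edge_len = np.zeros(n)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.leaf_row: list[str | None] = [None] * n
        for i, nid in enumerate(order):
            p = parent_of[nid]
            if p is not None:
                self.parent[i] = self._index[p]
                self.children[self._index[p]].append(i)
                self.edge_len[i] = t.length(p, nid)
            if t.is_leaf(nid):
                self.leaf_row[i] = t.label_of(nid)
        self.root = n - 1
        self._down = [None] * n
        self._dscale = [None] * n
        zero_scale = np.zeros((self.n_cat, self.n_patterns))
        for i in range(n):
            if self.leaf_row[i] is not None:
                self._down[i] = self._leaf_down(i).copy()
                self._dscale[i] = zero_scale

    def _write_back(self) -> Tree:
        t = self.tree
        for i, nid in enumerate(self.node_ids):
            p = self.parent[i]
            if p >= 0:
                t.set_length(self.node_ids[p], nid, self.edge_len[i])
        return t

    def result_tree(self) -> Tree:
        return self._write_back().copy()

    # -- partials ------------------------------------------------------

    def _edge_decay(self, t: float) -> np.ndarray:
        return np.exp(-4.0 / 3.0 * self.rates * t)

    def _transform(self, arr: np.ndarray, t: float) -> np.ndarray:
        """Apply the per-category JC kernel across an edge of length t."""
        out = np.empty_like(arr)
        _kernels.transform(out, np.ascontiguousarray(arr), self._edge_decay(t))
        return out

    def _leaf_down(self, i: int) -> np.ndarray:
        return np.broadcast_to(
            self._leaf_cond[self.leaf_row[i]], (self.n_cat, self.n_patterns, 4)
        )

    @staticmethod
    def _rescale(prod: np.ndarray, scale: np.ndarray):
        """In-place per-(category, pattern) rescale; prod and scale must be
        freshly allocated by the caller."""
        _kernels.rescale_inplace(prod, scale)
        return prod, scale

    def _root_seed(self) -> np.ndarray:
        """Starting partial at the traversal root: all-ones for an internal
        root, the root's own one-hot observation when the tree has only two
        leaves and the root is itself a leaf."""
        if self.leaf_row[self.root] is not None:
            return self._leaf_down(self.root).copy()
        return np.ones((self.n_cat, self.n_patterns, 4))

    def _node_down_update(self, i: int) -> None:
        """Recompute node i's down partial from its (fresh) children.

        Childless leaf partials are one-hot observations, independent of
        edge lengths and rates; they are materialized once in
        :meth:`set_tree`.  A leaf acting as the traversal root (2-taxon
        trees) folds its own observation into the product.
        """
        if self.leaf_row[i] is not None and not self.children[i]:
            return
        prod = self._leaf_down(i).copy() if self.leaf_row[i] is not None else None
        scale = np.zeros((self.n_cat, self.n_patterns))
        for c in self.children[i]:
            if prod is None:
                prod = self._transform(self._down[c], self.edge_len[c])
            else:
                _kernels.transform_mult(prod, self._down[c],
                                        self._edge_decay(self.edge_len[c]))
            scale += self._dscale[c]
        self._down[i], self._dscale[i] = self._rescale(prod, scale)

    def _compute_down(self, only: set | None = None) -> None:
        for i in range(len(self.node_ids)):
            if only is None or i in only:
                self._node_down_update(i)
        if only is None:
            self._stale = False

    # -- likelihood ----------------------------------------------------

    def _mix(self, lk: np.ndarray, scale: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood from per-category scaled likelihoods."""
        smax = scale.max(axis=0)
        smax = np.where(np.isfinite(smax), smax, 0.0)
        var = np.sum(lk * np.exp(scale - smax[None, :]), axis=0) / self.n_cat
        with np.errstate(divide="ignore"):
            log_var = np.log((1.0 - self.p_inv) * var) + smax
            if self.p_inv > 0.0:
                log_inv = np.where(self.constant, np.log(self.p_inv * 0.25), -np.inf)
                return np.logaddexp(log_inv, log_var)
        return log_var

    def _pattern_loglik(self) -> np.ndarray:
        self._compute_down()
        root = self._down[self.root]
        lk = 0.25 * root.sum(axis=2)
        return self._mix(lk, self._dscale[self.root])

    def log_likelihood(self) -> float:
        return float(self.counts @ self._pattern_loglik())

    def result(self) -> LikelihoodResult:
        per_pattern = self._pattern_loglik()
        return LikelihoodResult(
            log_likelihood=float(self.counts @ per_pattern),
            per_site=per_pattern[self.site_to_pattern],
            alpha=self.alpha if self.model.asrv_mode != "none" else None,
            p_inv=self.p_inv if self.model.asrv_mode == "gamma_inv" else None,
        )

    # -- per-edge views (branch optimization, NNI scoring) --------------

    def _complement_at(self, i: int):
        """Partial likelihood at node i of everything outside subtree(i),
        not transformed across i's parent edge.  Returns (array, scale)."""
        path = []
        j = i
        while self.parent[j] >= 0:
            path.append(j)
            j = self.parent[j]
        path.reverse()  # root-side first; j is root
        comp = self._root_seed()
        scale = np.zeros((self.n_cat, self.n_patterns))
        node = self.root
        for nxt in path:
            for c in self.children[node]:
                if c != nxt:
                    comp = comp * self._transform(self._down[c], self.edge_len[c])
                    scale = scale + self._dscale[c]
            if nxt != i:
                comp, scale = self._rescale(
                    self._transform(comp, self.edge_len[nxt]), scale.copy()
                )
            node = nxt
        return comp, scale

    def _edge_loglik_fn(self, ab, asb, scale):
        """Log-likelihood as a function of one edge length given the fixed
        coefficients L_k(t) = e_k * ab + (1 - e_k) * asb of the two flanking
        partials.  Scale exponentials are hoisted out of the returned
        closure, which is evaluated many times inside Brent."""
        smax = scale.max(axis=0)
        smax = np.where(np.isfinite(smax), smax, 0.0)
        with np.errstate(divide="ignore"):
            weights = np.exp(scale - smax[None, :])
        exp_smax = np.exp(smax)
        inv_term = np.where(self.constant, self.p_inv * 0.25, 0.0)
        w_var = (1.0 - self.p_inv) / self.n_cat
        rate_factor = -4.0 / 3.0 * self.rates
        counts = self.counts

        def loglik(t: float) -> float:
            return _kernels.edge_loglik(ab, asb, weights, inv_term, exp_smax,
                                        counts, rate_factor, w_var, t)

        return loglik

    def _edge_coeff_arrays(self, a: np.ndarray, b: np.ndarray):
        ab = np.empty((self.n_cat, self.n_patterns))
        asb = np.empty((self.n_cat, self.n_patterns))
        _kernels.edge_coeffs(np.ascontiguousarray(a), np.ascontiguousarray(b),
                             ab, asb)
        return ab, asb

    def _brent_edge(self, fn, current_t: float, xatol: float = 1e-6):
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda t: -fn(t), bounds=(MIN_BRANCH, MAX_BRANCH),
            method="bounded", options={"xatol": xatol},
        )
        current = fn(current_t)
        if -res.fun > current:
            return float(res.x), float(-res.fun)
        return float(current_t), float(current)

    def sweep_branches(self, xatol: float = 1e-6) -> float:
        """One depth-first pass optimizing every edge once.

        Complement partials are carried down the traversal and each node's
        down partial is refreshed on the way back up, so every edge is
        optimized against exact, current partials at the cost of a few
        transforms per node.  Requires fresh down partials on entry and
        leaves them fresh on exit; returns the exact final log-likelihood.
        """
        if self._stale or self._down[self.root] is None:
            self._compute_down()
        zeros = np.zeros((self.n_cat, self.n_patterns))

        def visit(p: int, comp: np.ndarray, cscale: np.ndarray) -> float:
            ll_local = -np.inf
            cs = self.children[p]
            trans = {
                c: self._transform(self._down[c], self.edge_len[c]) for c in cs
            }
            for c in cs:
                a = comp
                s = cscale
                for sib in cs:
                    if sib != c:
                        a = a * trans[sib]
                        s = s + self._dscale[sib]
                ab, asb = self._edge_coeff_arrays(a, self._down[c])
                fn = self._edge_loglik_fn(ab, asb, s + self._dscale[c])
                self.edge_len[c], ll_local = self._brent_edge(
                    fn, self.edge_len[c], xatol
                )
                if self.leaf_row[c] is None:
                    comp_c, cscale_c = self._rescale(
                        self._transform(a, self.edge_len[c]), s
                    )
                    ll_local = visit(c, comp_c, cscale_c)
                    self._node_down_update(c)
                trans[c] = self._transform(self._down[c], self.edge_len[c])
            return ll_local

        ll = visit(self.root, self._root_seed(), zeros)
        self._node_down_update(self.root)
        return ll

    def optimize_branch_lengths(self, tol: float = 1e-6,
                                max_sweeps: int = 40,
                                xatol: float = 1e-6) -> float:
        """Sweeps until a full sweep improves the log-likelihood < ``tol``."""
        ll = self.log_likelihood()
        for _ in range(max_sweeps):
            new = self.sweep_branches(xatol)
            if new - ll < tol:
                return new
            ll = new
        return ll

    # -- free-parameter optimization ------------------------------------

    def _optimize_scalar(self, assign, bounds, log_scale=False, xatol=1e-4):
        from scipy.optimize import minimize_scalar

        def neg(x):
            assign(np.exp(x) if log_scale else x)
            return -self.log_likelihood()

        lo, hi = bounds
        if log_scale:
            lo, hi = np.log(lo), np.log(hi)
        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": xatol})
        best = np.exp(res.x) if log_scale else float(res.x)
        assign(best)
        return float(-res.fun)

    def optimize_parameters(self, maxfev: int = 200) -> float:
        """Optimize the free ASRV parameters at the current branch lengths.

        When both alpha and p_inv are free they are optimized jointly
        (Nelder–Mead on (log alpha, p_inv)): the two parameters form a
        ridge in the likelihood surface along which coordinate-wise
        optimization crawls.
        """
        ll = self.log_likelihood()
        if self.model.estimates_alpha and self.model.estimates_p_inv:
            from scipy.optimize import minimize

            lo_a, hi_a = ALPHA_BOUNDS
            lo_p, hi_p = PINV_BOUNDS

            def neg(x):
                a = float(np.clip(np.exp(x[0]), lo_a, hi_a))
                p = float(np.clip(x[1], lo_p, hi_p))
                self.set_parameters(alpha=a, p_inv=p)
                return -self.log_likelihood()

            res = minimize(
                neg, [np.log(self.alpha), self.p_inv], method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-6, "maxfev": maxfev},
            )
            return -neg(res.x)  # leave the engine at the optimum
        if self.model.estimates_alpha:
            ll = self._optimize_scalar(
                lambda a: self.set_parameters(alpha=a),
                ALPHA_BOUNDS, log_scale=True, xatol=1e-4,
            )
        if self.model.estimates_p_inv:
            lo, hi = PINV_BOUNDS
            ll = self._optimize_scalar(
                lambda p: self.set_parameters(p_inv=p),
                (lo + 1e-9, hi), xatol=1e-5,
            )
        return ll

    def optimize_all(self, joint_tol: float = 1e-4, max_rounds: int = 25,
                     xatol: float = 1e-6, param_maxfev: int = 200) -> float:
        """Alternate branch sweeps and parameter fits to joint convergence.

        A looser ``joint_tol`` (with matching ``xatol``/``param_maxfev``)
        gives the cheap interim optimization used while the topology is
        still moving during the NNI search.
        """
        has_free = self.model.estimates_alpha or self.model.estimates_p_inv
        sweep_tol = max(joint_tol / 10, 1e-6)
        if not has_free:
            return self.optimize_branch_lengths(tol=sweep_tol, xatol=xatol)
        ll = self.log_likelihood()
        for _ in range(max_rounds):
            new = self.optimize_branch_lengths(tol=sweep_tol, xatol=xatol)
            new = self.optimize_parameters(maxfev=param_maxfev)
            if new - ll < joint_tol:
                return new
            ll = new
        return ll


def tree_log_likelihood(tree: Tree, alignment: Alignment, model: ModelSpec,
                        alpha: float | None = None,
                        p_inv: float | None = None) -> LikelihoodResult:
    """Log-likelihood of ``alignment`` on ``tree`` under ``model``.

    Parameters marked ``"estimate"`` in the model must be supplied as
    concrete overrides here; use :func:`lbasim.search.estimate_rate_parameters`
    to fit them.
    """
    if model.estimates_alpha and alpha is None:
        raise ValueError("model estimates alpha: supply a concrete value")
    if model.estimates_p_inv and p_inv is None:
        raise ValueError("model estimates p_inv: supply a concrete value")
    engine = PruningEngine(alignment, model, alpha=alpha, p_inv=p_inv)
    engine.set_tree(tree)
    return engine.result()


def brute_force_log_likelihood(tree: Tree, alignment: Alignment,
                               model: ModelSpec,
                               alpha: float | None = None,
                               p_inv: float | None = None) -> float:
    """Likelihood by exhaustive summation over ancestral states.

    Test oracle: agrees with the pruning algorithm in exact arithmetic.
    Refuses trees with more than 8 internal nodes (4^n assignments).
    """
    engine = PruningEngine(alignment, model, alpha=alpha, p_inv=p_inv)
    engine.set_tree(tree)
    internal = [i for i, lab in enumerate(engine.leaf_row) if lab is None]
    if len(internal) > 8:
        raise ValueError("brute force refuses > 8 internal nodes")
    pos = {n: k for k, n in enumerate(internal)}
    m = engine.n_patterns
    lk = np.zeros((engine.n_cat, m))
    for k, rate in enumerate(engine.rates):
        pmats = {
            i: jc_transition(engine.edge_len[i], rate)
            for i in range(len(engine.node_ids)) if engine.parent[i] >= 0
        }
        for assign in itertools.product(range(4), repeat=len(internal)):
            w = 0.25  # uniform root prior
            per_pattern = np.full(m, w)
            for i in range(len(engine.node_ids)):
                p = engine.parent[i]
                if p < 0:
                    continue
                a_p = assign[pos[p]]
                if engine.leaf_row[i] is None:
                    per_pattern = per_pattern * pmats[i][a_p, assign[pos[i]]]
                else:
                    bases = engine.patterns[
                        engine.alignment.labels.index(engine.leaf_row[i])
                    ]
                    per_pattern = per_pattern * pmats[i][a_p, bases]
            lk[k] += per_pattern
    per_pattern_ll = engine._mix(lk, np.zeros((engine.n_cat, m)))
    return float(engine.counts @ per_pattern_ll)
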