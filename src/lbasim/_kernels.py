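"""Numba kernels for the pruning-likelihood hot loops.

All kernels exploit the rank-one-plus-identity structure of the JC
transition matrix: P(t) = e*I + (1-e)/4 * J with e = exp(-4rt/3), so a
matrix-vector product along an edge is e*v + (1-e)/4 * sum(v).  Shapes:
partials are (n_categories, n_patterns, 4) float64, per-category scale
logs are (n_categories, n_patterns).
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def transform(out, arr, e):
    """out[k,i,:] = P_k(t) @ arr[k,i,:] with e[k] = exp(-4 r_k t / 3)."""
    c, m, _ = arr.shape
    for k in range(c):
        ek = e[k]
        q = 0.25 * (1.0 - ek)
        for i in range(m):
            s = arr[k, i, 0] + arr[k, i, 1] + arr[k, i, 2] + arr[k, i, 3]
            base = q * s
            for x in range(4):
                out[k, i, x] = ek * arr[k, i, x] + base


@nb.njit(cache=True)
def transform_mult(prod, arr, e):
    """prod[k,i,:] *= P_k(t) @ arr[k,i,:] (fused transform-and-accumulate)."""
    c, m, _ = arr.shape
    for k in range(c):
        ek = e[k]
        q = 0.25 * (1.0 - ek)
        for i in range(m):
            s = arr[k, i, 0] + arr[k, i, 1] + arr[k, i, 2] + arr[k, i, 3]
            base = q * s
            for x in range(4):
                prod[k, i, x] *= ek * arr[k, i, x] + base


@nb.njit(cache=True)
def rescale_inplace(prod, scale):
    """Divide each (k,i) fibre by its max and add log(max) to ``scale``."""
    c, m, _ = prod.shape
    for k in range(c):
        for i in range(m):
            mx = prod[k, i, 0]
            for x in range(1, 4):
                if prod[k, i, x] > mx:
                    mx = prod[k, i, x]
            if mx > 0.0:
                inv = 1.0 / mx
                for x in range(4):
                    prod[k, i, x] *= inv
                scale[k, i] += np.log(mx)
            else:
                scale[k, i] = -np.inf


@nb.njit(cache=True)
def edge_coeffs(a, b, ab, asb):
    """ab = (1/4) a.b, asb = (1/16) sum(a) sum(b), per category/pattern."""
    c, m, _ = a.shape
    for k in range(c):
        for i in range(m):
            dot = 0.0
            sa = 0.0
            sb = 0.0
            for x in range(4):
                dot += a[k, i, x] * b[k, i, x]
                sa += a[k, i, x]
                sb += b[k, i, x]
            ab[k, i] = 0.25 * dot
            asb[k, i] = sa * sb / 16.0


@nb.njit(cache=True)
def edge_loglik(ab, asb, weights, inv_term, exp_smax, counts, rate_factor,
                w_var, t):
    """Log-likelihood as a function of one edge length t.

    L_k(t) = e_k*ab + (1-e_k)*asb per category; categories are combined
    with precomputed scale weights, the invariant-class term is added, and
    the pattern counts weight the final sum.
    """
    c, m = ab.shape
    e = np.empty(c)
    for k in range(c):
        e[k] = np.exp(rate_factor[k] * t)
    total = 0.0
    for i in range(m):
        var = 0.0
        for k in range(c):
            lk = e[k] * ab[k, i] + (1.0 - e[k]) * asb[k, i]
            var += lk * weights[k, i]
        total += counts[i] * np.log(inv_term[i] + w_var * var * exp_smax[i])
    return total
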