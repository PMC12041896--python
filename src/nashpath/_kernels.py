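"""Jitted inner loops for the selection dynamics.

The multi-replicator right-hand side is evaluated thousands of times per
trajectory; this module provides a compiled kernel (prefix/suffix product
contraction of the fitness tensor, identical mathematics to
``games._all_marginals``) with a pure-numpy fallback when numba is
unavailable.  A property test asserts the two paths agree.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (len(args) == 1 and callable(args[0])) else args[0]


@njit(cache=True)
def _marginals_flat(flat_w, dims, offsets, y, marg):  # pragma: no cover - jitted
    m = dims.size
    for i in range(m):
        n_i = dims[i]
        # prefix product over loci before i
        left = 1
        P = np.ones(1)
        for j in range(i):
            nj = dims[j]
            newP = np.empty(left * nj)
            for a in range(left):
                pa = P[a]
                for b in range(nj):
                    newP[a * nj + b] = pa * y[offsets[j] + b]
            P = newP
            left *= nj
        # suffix product over loci after i
        right = 1
        S = np.ones(1)
        for j in range(m - 1, i, -1):
            nj = dims[j]
            newS = np.empty(nj * right)
            for b in range(nj):
                vb = y[offsets[j] + b]
                for c in range(right):
                    newS[b * right + c] = vb * S[c]
            S = newS
            right *= nj
        for jj in range(n_i):
            acc = 0.0
            for a in range(left):
                pa = P[a]
                rowbase = (a * n_i + jj) * right
                for b in range(right):
                    acc += pa * flat_w[rowbase + b] * S[b]
            marg[offsets[i] + jj] = acc


@njit(cache=True)
def _sexual_field_flat(flat_w, dims, offsets, y, out):  # pragma: no cover - jitted
    marg = np.empty(y.size)
    _marginals_flat(flat_w, dims, offsets, y, marg)
    # mean fitness: contract locus 0's marginal with its frequencies
    w = 0.0
    for j in range(dims[0]):
        w += y[offsets[0] + j] * marg[offsets[0] + j]
    for k in range(y.size):
        out[k] = y[k] * (marg[k] - w)


def sexual_field_factory(tensor: np.ndarray, shape) -> "callable":
    """A fast ``f(y) -> dy`` for the multi-replicator field of one game."""
    flat_w = np.ascontiguousarray(tensor, dtype=np.float64).ravel()
    dims = np.asarray(shape, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(dims)]).astype(np.int64)

    if HAVE_NUMBA:

        def field(y: np.ndarray) -> np.ndarray:
            out = np.empty_like(y)
            _sexual_field_flat(flat_w, dims, offsets, y, out)
            return out

        return field

    from .games import _all_marginals, _split_sizes  # lazy; avoids cycle at import

    def field_numpy(y: np.ndarray) -> np.ndarray:
        vecs = _split_sizes(y, dims)
        margs = _all_marginals(tensor, vecs)
        out = np.empty_like(y)
        k = 0
        for v, marg in zip(vecs, margs):
            w = marg @ v
            out[k : k + v.size] = v * (marg - w)
            k += v.size
        return out

    return field_numpy
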