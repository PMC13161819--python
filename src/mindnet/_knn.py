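"""Compiled selection kernel for per-region k-th neighbour distances."""

import numpy as np
from numba import njit


@njit(cache=True)
def kth_sq_dists(d2, starts, counts, k):
    """k-th and (k+1)-th smallest entries of row segments of ``d2``.

    For every row i and region s, selects the k-th smallest squared
    distance in the segment ``d2[i, starts[s]:starts[s]+counts[s]]``
    (1-based k) into ``nu[i, s]``, and the (k+1)-th into ``rho[i]`` for the
    vertex's own region (whose segment contains the zero self-distance).
    Rows must be grouped by region in the same order as ``starts``.
    """
    n = d2.shape[0]
    n_reg = starts.shape[0]
    nu = np.empty((n, n_reg))
    rho = np.empty(n)
    buf = np.empty(k + 1)
    for i in range(n):
        # which region row i belongs to
        own = 0
        for s in range(n_reg):
            if starts[s] <= i < starts[s] + counts[s]:
                own = s
                break
        for s in range(n_reg):
            a = starts[s]
            w = counts[s]
            # maintain the k+1 smallest seen so far in sorted order
            m = 0
            for j in range(w):
                v = d2[i, a + j]
                if m < k + 1:
                    p = m
                    while p > 0 and buf[p - 1] > v:
                        buf[p] = buf[p - 1]
                        p -= 1
                    buf[p] = v
                    m += 1
                elif v < buf[k]:
                    p = k
                    while p > 0 and buf[p - 1] > v:
                        buf[p] = buf[p - 1]
                        p -= 1
                    buf[p] = v
            if s == own:
                nu[i, s] = buf[k - 1]
                rho[i] = buf[k]
            else:
                nu[i, s] = buf[k - 1]
    return nu, rho
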