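"""Numba kernel for the fixed–fixed (sequential swap) null model.

The chain state is a binary species × sites matrix.  One attempt picks a
random pair of rows and a random pair of columns; if the 2×2 submatrix is a
checkerboard it is swapped, otherwise the state is kept.  Counting failed
attempts as steps makes the proposal symmetric, so the stationary
distribution is uniform over the set of matrices sharing the source's row
and column totals.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ff_swap_chain(
    m: np.ndarray,
    n_samples: int,
    burn_in: int,
    thin: int,
    seed: int,
) -> tuple[np.ndarray, int]:
    """Run the swap chain in place on ``m``; return sampled matrices and the
    number of accepted swaps."""
    np.random.seed(seed)
    R, C = m.shape
    out = np.empty((n_samples, R, C), dtype=np.uint8)
    swaps = 0
    total = burn_in + n_samples * thin
    k = 0
    next_sample = burn_in + thin
    for it in range(1, total + 1):
        r1 = np.random.randint(R)
        r2 = np.random.randint(R)
        c1 = np.random.randint(C)
        c2 = np.random.randint(C)
        if r1 != r2 and c1 != c2:
            a = m[r1, c1]
            d = m[r2, c2]
            if a == d and m[r1, c2] == m[r2, c1] and a != m[r1, c2]:
                m[r1, c1] = 1 - a
                m[r2, c2] = 1 - a
                m[r1, c2] = a
                m[r2, c1] = a
                swaps += 1
        if it == next_sample and k < n_samples:
            out[k] = m
            k += 1
            next_sample += thin
    return out, swaps
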