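"""Numba kernels for the reference partition-function engine.

All interval arrays are 1-based with shape (n+2, n+2); the cell [i, j]
holds the quantity for the subsequence i..j inclusive, and [i, i-1] is the
empty interval. Per-base scaling by ``s`` keeps values inside double range:
an inside quantity of span L carries a factor s**-L, an outside quantity
s**-(n-L); the factors cancel in the final pair probabilities.

Model: a secondary structure is any non-crossing set of legal pairs with a
minimum hairpin loop of 3 unpaired bases. Its Boltzmann weight is the
product of one weight per pair (q, by pair type) and one stacking weight
(sigma) per pair whose inner neighbour (i+1, j-1) is also paired.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True)
def max_weight_log(logq: np.ndarray, logsigma: float) -> float:
    """Log-weight of the single best structure (for choosing the scale)."""
    n = logq.shape[0] - 2
    W = np.zeros((n + 2, n + 2))
    Wb = np.full((n + 2, n + 2), NEG_INF)
    for length in range(1, n + 1):
        for i in range(1, n - length + 2):
            j = i + length - 1
            if length >= 5 and logq[i, j] > NEG_INF:
                inner_np = W[i + 1, j - 1]
                inner_b = Wb[i + 1, j - 1]
                best_in = inner_np
                if inner_b + logsigma > best_in:
                    best_in = inner_b + logsigma
                Wb[i, j] = logq[i, j] + best_in
            best = W[i + 1, j] if length > 1 else 0.0
            for k in range(i + 4, j + 1):
                if Wb[i, k] > NEG_INF:
                    cand = Wb[i, k] + W[k + 1, j]
                    if cand > best:
                        best = cand
            W[i, j] = best
    return W[1, n]


@njit(cache=True)
def inside(q: np.ndarray, gu_strict: np.ndarray, sigma: float, s: float):
    """Inside pass: Z (all structures) and Zb ((i,j) paired) per interval.

    ``gu_strict[i, j]`` marks pairs that are only allowed when stacked on
    their inner neighbour (the helix-end G-U restriction).
    """
    n = q.shape[0] - 2
    Z = np.zeros((n + 2, n + 2))
    Zb = np.zeros((n + 2, n + 2))
    for i in range(1, n + 2):
        Z[i, i - 1] = 1.0
    for length in range(1, n + 1):
        for i in range(1, n - length + 2):
            j = i + length - 1
            if length >= 5 and q[i, j] > 0.0:
                zb_in = Zb[i + 1, j - 1]
                if gu_strict[i, j]:
                    Zb[i, j] = q[i, j] / (s * s) * sigma * zb_in
                else:
                    Zb[i, j] = q[i, j] / (s * s) * (
                        sigma * zb_in + Z[i + 1, j - 1] - zb_in
                    )
            acc = Z[i + 1, j] / s
            for k in range(i + 4, j + 1):
                if Zb[i, k] > 0.0:
                    acc += Zb[i, k] * Z[k + 1, j]
            Z[i, j] = acc
    return Z, Zb


@njit(cache=True)
def outside(
    q: np.ndarray,
    gu_strict: np.ndarray,
    sigma: float,
    s: float,
    Z: np.ndarray,
    Zb: np.ndarray,
):
    """Outside pass; returns bZ, bB so that P(i,j) = bB[i,j]*Zb[i,j]/Z[1,n]."""
    n = q.shape[0] - 2
    bZ = np.zeros((n + 2, n + 2))
    bB = np.zeros((n + 2, n + 2))
    bZ[1, n] = 1.0
    for length in range(n, 0, -1):
        for i in range(1, n - length + 2):
            j = i + length - 1
            acc = 0.0
            if i == 1 and j == n:
                acc = 1.0
            if i > 1:
                acc += bZ[i - 1, j] / s
                # contexts where i..j follows a closed pair (m, i-1)
                for m in range(1, i - 4):
                    if Zb[m, i - 1] > 0.0:
                        acc += bZ[m, j] * Zb[m, i - 1]
            if i > 1 and j < n and q[i - 1, j + 1] > 0.0 and not gu_strict[i - 1, j + 1]:
                # interior of pair (i-1, j+1), inner neighbour unpaired case
                acc += bB[i - 1, j + 1] * q[i - 1, j + 1] / (s * s)
            bZ[i, j] = acc
            if length >= 5 and q[i, j] > 0.0:
                accb = 0.0
                for jj in range(j, n + 1):
                    if bZ[i, jj] > 0.0:
                        accb += bZ[i, jj] * Z[j + 1, jj]
                if i > 1 and j < n and q[i - 1, j + 1] > 0.0:
                    coef = sigma if gu_strict[i - 1, j + 1] else sigma - 1.0
                    accb += bB[i - 1, j + 1] * q[i - 1, j + 1] / (s * s) * coef
                bB[i, j] = accb
    return bZ, bB
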