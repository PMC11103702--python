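"""Numba kernels for the hot paths of SARWS sampling.

All randomness is drawn from the caller's numpy Generator and passed in
as raw standard-normal arrays, so results are bit-reproducible and the
kernels are pure functions. Overlap checks exit early on the first
violating pair, which roughly halves the work at the observed rejection
rates.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def leaf_fill_kernel(rng, out: np.ndarray, bonds: np.ndarray, thr_sq: np.ndarray) -> None:
    """Fill ``out`` with self-avoiding short walks, first bead at origin.

    out: (count, n, 3) preallocated; bonds: (n-1,) consecutive-contact
    distances; thr_sq: (n, n) squared overlap thresholds with exempt
    pairs < 0. Walks are grown bead by bead and restarted on the first
    overlap — equivalent to full-walk rejection, since an early clash
    already decides rejection — drawing directions from ``rng`` as
    normalized standard-normal triples.
    """
    count, n, _ = out.shape
    for t in range(count):
        while True:
            out[t, 0, 0] = 0.0
            out[t, 0, 1] = 0.0
            out[t, 0, 2] = 0.0
            good = True
            for k in range(n - 1):
                x = rng.standard_normal()
                y = rng.standard_normal()
                z = rng.standard_normal()
                s = bonds[k] / np.sqrt(x * x + y * y + z * z)
                px = out[t, k, 0] + x * s
                py = out[t, k, 1] + y * s
                pz = out[t, k, 2] + z * s
                out[t, k + 1, 0] = px
                out[t, k + 1, 1] = py
                out[t, k + 1, 2] = pz
                # new bead k+1 against all j <= k-1 (|i - j| >= 2)
                for j in range(k):
                    dx = out[t, j, 0] - px
                    dy = out[t, j, 1] - py
                    dz = out[t, j, 2] - pz
                    if dx * dx + dy * dy + dz * dz < thr_sq[j, k + 1]:
                        good = False
                        break
                if not good:
                    break
            if good:
                break


@njit(cache=True, fastmath=True)
def join_kernel(
    left: np.ndarray,
    right: np.ndarray,
    jnormals: np.ndarray,
    bond: float,
    cross_thr_sq: np.ndarray,
):
    """Translate right halves onto the left ends and flag valid joins.

    left: (b, m1, 3); right: (b, m2, 3) in their own frame (first bead
    at origin) — translated IN PLACE; jnormals: (b, 3) standard normals
    for the junction directions; cross_thr_sq: (m1, m2) squared
    thresholds with the adjacent junction pair < 0. Returns ok mask.
    """
    b, m1, _ = left.shape
    m2 = right.shape[1]
    ok = np.ones(b, np.bool_)
    for t in range(b):
        x, y, z = jnormals[t, 0], jnormals[t, 1], jnormals[t, 2]
        inv = bond / np.sqrt(x * x + y * y + z * z)
        ox = left[t, m1 - 1, 0] + x * inv
        oy = left[t, m1 - 1, 1] + y * inv
        oz = left[t, m1 - 1, 2] + z * inv
        for j in range(m2):
            right[t, j, 0] += ox
            right[t, j, 1] += oy
            right[t, j, 2] += oz
        good = True
        # Beads adjacent to the junction are the most likely to clash:
        # scan right beads outward, left beads junction-first.
        for j in range(m2):
            rx, ry, rz = right[t, j, 0], right[t, j, 1], right[t, j, 2]
            for i in range(m1 - 1, -1, -1):
                dx = left[t, i, 0] - rx
                dy = left[t, i, 1] - ry
                dz = left[t, i, 2] - rz
                if dx * dx + dy * dy + dz * dz < cross_thr_sq[i, j]:
                    good = False
                    break
            if not good:
                break
        ok[t] = good
    return ok
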