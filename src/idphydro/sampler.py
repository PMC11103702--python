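"""Equilibrium sampling of bead-chain conformations.

Conformations are drawn from the self-avoiding random walk of spheres
(SARWS): consecutive beads touch exactly (bond length equals the sum of
their steric radii), bond directions are independent and uniformly
distributed on the sphere, and the walk is conditioned on the absence of
steric overlaps between non-adjacent beads.

Sampling uses recursive dimerization: the chain is split in half, each
half is drawn from its own SARWS distribution, and the halves are joined
with a fresh uniform junction direction; if any inter-half overlap
occurs, BOTH halves are redrawn. Rejecting the joint draw (not just the
junction) reproduces the exact conditional distribution and is far
faster than one-by-one growth with restarts for long chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._kernels import join_kernel, leaf_fill_kernel
from .bead_model import BeadChain


class SamplingFailure(RuntimeError):
    """Raised when the rejection budget is exhausted on a pathological chain."""


#: Chains of at most this many beads are sampled by one-shot rejection.
DIMERIZATION_BASE = 8
#: Rejection attempts allowed per recursion level before giving up.
MAX_ATTEMPTS = 10**6


@dataclass(frozen=True)
class Conformation:
    """Bead-center coordinates (A) of one chain conformation."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be an (n_beads, 3) array")
        object.__setattr__(self, "coordinates", coords)

    def __len__(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class Ensemble:
    """A seeded, reproducible collection of SARWS conformations."""

    chain: BeadChain
    conformations: tuple[Conformation, ...]
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "conformations", tuple(self.conformations))
        if not self.conformations:
            raise ValueError("ensemble must contain at least one conformation")
        n_beads = len(self.chain)
        for conf in self.conformations:
            if len(conf) != n_beads:
                raise ValueError("conformation size does not match chain")

    @property
    def n(self) -> int:
        return len(self.conformations)


def _uniform_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_auxiliary_walk(chain: BeadChain, rng: np.random.Generator) -> np.ndarray:
    """Draw one unconditioned random walk of touching spheres.

    Bead 1 sits at the origin; each subsequent center is displaced by the
    sum of the adjacent steric radii along an independent uniform
    direction. Self-avoidance is NOT enforced.
    """
    radii = chain.steric_radii
    n = len(radii)
    coords = np.zeros((n, 3))
    if n > 1:
        bond_lengths = radii[:-1] + radii[1:]
        steps = bond_lengths[:, None] * _uniform_unit_vectors(rng, n - 1)
        coords[1:] = np.cumsum(steps, axis=0)
    return coords


def _overlap_thresholds(radii: np.ndarray, tol: float) -> np.ndarray:
    """Matrix of contact distances scaled by (1 - tol); adjacent/self pairs zeroed."""
    thr = (radii[:, None] + radii[None, :]) * (1.0 - tol)
    n = len(radii)
    idx = np.arange(n)
    thr[idx, idx] = 0.0
    thr[idx[:-1], idx[:-1] + 1] = 0.0
    thr[idx[:-1] + 1, idx[:-1]] = 0.0
    return thr


def has_overlap(coordinates: np.ndarray, chain: BeadChain) -> bool:
    """True iff some non-adjacent bead pair overlaps sterically.

    Pairs (i, j) with |i - j| >= 2 overlap when their center distance
    falls below (steric_i + steric_j) * (1 - overlap_tolerance);
    consecutive pairs are exempt because they touch by construction.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.shape[0] != len(chain):
        raise ValueError("coordinate count does not match bead count")
    if coords.shape[0] < 3:
        return False
    dists = squareform(pdist(coords))
    thr = _overlap_thresholds(chain.steric_radii, chain.params.overlap_tolerance)
    return bool(np.any(dists < thr))


#: Cap on batch_size * n_beads for generated coordinate blocks (memory).
_COORD_ELEMENT_CAP = 5 * 10**6


class _SegmentPool:
    """Exact dimerization sampler with surplus reuse.

    Accepted segments for each (lo, hi) span are independent, identically
    distributed draws from that span's SARWS distribution, so surplus
    segments from one join attempt can be consumed by a later attempt
    without biasing the output — each segment is still generated from
    fresh random numbers and used exactly once. Pooling removes the
    multiplicative waste of discarding overshoot at every recursion
    level, which dominates the cost for long chains.
    """

    def __init__(self, radii: np.ndarray, thr_sq: np.ndarray, rng: np.random.Generator):
        self.radii = radii
        self.thr_sq = thr_sq
        self.rng = rng
        self._pools: dict[tuple[int, int], np.ndarray] = {}
        self._p_est: dict[tuple[int, int], float] = {}
        self._thr_cache: dict[tuple[int, int, int, int], np.ndarray] = {}

    def _thr_block(self, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
        key = (r0, r1, c0, c1)
        block = self._thr_cache.get(key)
        if block is None:
            block = np.ascontiguousarray(self.thr_sq[r0:r1, c0:c1])
            self._thr_cache[key] = block
        return block

    def take(self, lo: int, hi: int, count: int) -> np.ndarray:
        """Return ``count`` iid SARWS segments for beads lo..hi, (count, n, 3)."""
        n = hi - lo + 1
        if n == 1:
            return np.zeros((count, 1, 3))
        if n <= DIMERIZATION_BASE:
            # Leaf spans bypass the pool: the kernel produces exactly
            # `count` accepted walks with no surplus.
            out = np.empty((count, n, 3))
            bonds = self.radii[lo:hi] + self.radii[lo + 1 : hi + 1]
            leaf_fill_kernel(self.rng, out, bonds, self._thr_block(lo, hi + 1, lo, hi + 1))
            return out
        key = (lo, hi)
        pool = self._pools.get(key)
        attempts = 0
        while pool is None or pool.shape[0] < count:
            have = 0 if pool is None else pool.shape[0]
            fresh = self._generate(lo, hi, count - have)
            pool = fresh if pool is None else np.concatenate([pool, fresh])
            attempts += 1
            if attempts > MAX_ATTEMPTS:
                raise SamplingFailure(
                    f"segment pool for beads {lo}..{hi} exhausted "
                    f"{MAX_ATTEMPTS} generation rounds"
                )
        out, rest = pool[:count], pool[count:]
        self._pools[key] = rest
        return out

    def _generate(self, lo: int, hi: int, need: int) -> np.ndarray:
        """One batched join round; returns >= 0 accepted segments."""
        n = hi - lo + 1
        radii, rng = self.radii, self.rng
        mid = lo + n // 2 - 1  # last bead of the left half
        bond = radii[mid] + radii[mid + 1]
        p = self._p_est.get((lo, hi), 0.4)
        b = min(max(int(need / p) + 4, 8), max(_COORD_ELEMENT_CAP // n, 8))
        left = self.take(lo, mid, b)
        right = self.take(mid + 1, hi, b)
        jnormals = rng.standard_normal((b, 3))
        ok = join_kernel(
            left, right, jnormals, bond,
            self._thr_block(lo, mid + 1, mid + 1, hi + 1),
        )
        self._update_p((lo, hi), int(ok.sum()), b)
        if not ok.any():
            return np.empty((0, n, 3))
        return np.concatenate([left[ok], right[ok]], axis=1)

    def _update_p(self, key: tuple[int, int], n_ok: int, b: int) -> None:
        prev = self._p_est.get(key)
        obs = n_ok / b
        self._p_est[key] = max(
            obs if prev is None else 0.5 * prev + 0.5 * obs, 1e-3
        )


def _chain_thr_sq(chain: BeadChain) -> np.ndarray:
    # Exempt (self/adjacent) entries are set to -1 so that even a tiny
    # negative rounding error in the matmul-based squared distances can
    # never reject them.
    thr = _overlap_thresholds(chain.steric_radii, chain.params.overlap_tolerance)
    thr_sq = thr * thr
    thr_sq[thr == 0.0] = -1.0
    return thr_sq


def _sample_batch(chain: BeadChain, count: int, rng: np.random.Generator) -> np.ndarray:
    pool = _SegmentPool(chain.steric_radii, _chain_thr_sq(chain), rng)
    return pool.take(0, len(chain) - 1, count)


def sample_sarws(chain: BeadChain, rng: np.random.Generator) -> Conformation:
    """Draw one self-avoiding conformation of the chain.

    The returned sample follows the auxiliary-walk distribution
    conditioned on the absence of non-adjacent overlaps.
    """
    return Conformation(_sample_batch(chain, 1, rng)[0])


def sample_ensemble(chain: BeadChain, n: int, seed: int) -> Ensemble:
    """Draw ``n`` independent SARWS conformations from a seeded generator.

    All conformations of one ensemble are drawn through a shared segment
    pool (see :class:`_SegmentPool`); the draws remain independent and
    the whole ensemble is reproducible from (chain, n, seed).
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    rng = np.random.default_rng(seed)
    batch = _sample_batch(chain, n, rng)
    conformations = tuple(Conformation(batch[i]) for i in range(n))
    return Ensemble(chain=chain, conformations=conformations, seed=seed)
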