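"""Hydrodynamic radius estimators over SARWS ensembles.

Two families of estimators are provided:

* the Kirkwood(-Riseman) formulas, which average inverse inter-bead
  distances and correspond to the short-time diffusivity of the
  geometric center — the full form keeps the single-bead self terms
  1/a_i, the simplified form drops them (the large-N limit);

* the minimum dissipation approximation (MDA), which inverts the
  ensemble-averaged trace-contracted mobility matrix and corresponds to
  the short-time diffusivity of the diffusion center — the optimal
  tracking point — and is therefore the tightest short-time bound on
  the long-time diffusion coefficient.

Pair mobilities use the generalized Rotne-Prager-Yamakawa (GRPY)
approximation for polydisperse, possibly overlapping spheres. After
trace contraction and scaling by 2*pi*eta, the solvent viscosity cancels
and all quantities are purely geometric (units 1/A for the matrix A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.constants import Boltzmann
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist, squareform

from .bead_model import DisorderTrack, SegmentAnnotation, build_bead_chain
from .params import ModelParameters
from .sampler import Ensemble, sample_ensemble


logger = logging.getLogger(__name__)


class NumericalFailure(RuntimeError):
    """Raised when the mobility matrix is not positive definite."""


@dataclass(frozen=True)
class MobilityTraceMatrix:
    """Ensemble-averaged, trace-contracted GRPY mobility (units 1/A).

    Entry (i, j) is 2*pi*eta*Tr<mu_ij> averaged over the ensemble; the
    diagonal holds the self terms 1/a_i. Symmetric and positive definite
    by construction of the GRPY approximation.
    """

    A: np.ndarray
    n_conformers_averaged: int

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be a square matrix")
        if not np.allclose(A, A.T, rtol=1e-12, atol=0.0):
            raise ValueError("A must be symmetric")
        object.__setattr__(self, "A", A)


@dataclass(frozen=True)
class HydroResult:
    """All hydrodynamic-radius estimates for one prediction run."""

    rh_mda: float
    rh_kirkwood_full: float
    rh_kirkwood_simplified: float
    sem_rh_mda: float
    diffusion_center_weights: np.ndarray
    n_conformers: int
    seed: int


def pair_trace(a_i: float, a_j: float, r: float) -> float:
    """Trace-contracted, 2*pi*eta-scaled GRPY pair mobility (1/A).

    Branches of the polydisperse Rotne-Prager-Yamakawa closed form:

    * ``r >= a_i + a_j`` (separated): ``1/r`` — the Oseen-level result;
      the finite-size corrections are traceless and drop out.
    * ``|a_i - a_j| < r < a_i + a_j`` (partial overlap):
      ``(a_i + a_j)/(2 a_i a_j) - ((a_i - a_j)^2 + r^2)/(4 a_i a_j r)``.
    * ``r <= |a_i - a_j|`` (full containment): ``1/max(a_i, a_j)`` — the
      pair moves with the self-mobility of the enclosing sphere.

    Continuous at both branch boundaries.
    """
    if a_i <= 0 or a_j <= 0:
        raise ValueError("bead radii must be strictly positive")
    if r < 0:
        raise ValueError("distance must be non-negative")
    if r >= a_i + a_j:
        return 1.0 / r
    if r <= abs(a_i - a_j):
        return 1.0 / max(a_i, a_j)
    return (a_i + a_j) / (2.0 * a_i * a_j) - ((a_i - a_j) ** 2 + r * r) / (
        4.0 * a_i * a_j * r
    )


def _pair_trace_matrix(radii: np.ndarray, dists: np.ndarray) -> np.ndarray:
    """Vectorized ``pair_trace`` over all bead pairs of one conformation."""
    a_i = radii[:, None]
    a_j = radii[None, :]
    sum_r = a_i + a_j
    diff_r = np.abs(a_i - a_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        far = 1.0 / dists
        overlap = sum_r / (2.0 * a_i * a_j) - (diff_r**2 + dists**2) / (
            4.0 * a_i * a_j * dists
        )
    contained = 1.0 / np.maximum(a_i, a_j)
    out = np.where(dists >= sum_r, far, np.where(dists <= diff_r, contained, overlap))
    np.fill_diagonal(out, 0.0)
    return out


def build_A(ensemble: Ensemble) -> MobilityTraceMatrix:
    """Ensemble-averaged trace mobility matrix.

    The average sits INSIDE the matrix: off-diagonal entries are the
    mean of the GRPY pair trace over conformations, and the single
    inversion happens downstream in :func:`mda_rh`.
    """
    radii = ensemble.chain.hydro_radii
    n = len(radii)
    acc = np.zeros((n, n))
    for conf in ensemble.conformations:
        dists = squareform(pdist(conf.coordinates))
        acc += _pair_trace_matrix(radii, dists)
    A = acc / ensemble.n
    np.fill_diagonal(A, 1.0 / radii)
    return MobilityTraceMatrix(A=A, n_conformers_averaged=ensemble.n)


def kirkwood_rh(ensemble: Ensemble, variant: Literal["full", "simplified"] = "full",
                use_grpy_overlap: bool = False) -> float:
    """Kirkwood estimate of the hydrodynamic radius (A).

    full:        1/R_h = N^-2 (sum_i 1/a_i + sum_{i!=j} <1/r_ij>)
    simplified:  1/R_h = N^-2  sum_{i!=j} <1/r_ij>

    The inter-bead term uses the bare inverse distance even for
    overlapping beads; set ``use_grpy_overlap`` to substitute the GRPY
    overlap-regularized pair trace for sensitivity analysis.
    """
    radii = ensemble.chain.hydro_radii
    n = len(radii)
    if variant not in ("full", "simplified"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "simplified" and n < 2:
        raise ValueError("simplified Kirkwood formula requires at least 2 beads")

    pair_sum = 0.0
    if n > 1:
        for conf in ensemble.conformations:
            dists = squareform(pdist(conf.coordinates))
            if use_grpy_overlap:
                m = _pair_trace_matrix(radii, dists)
            else:
                with np.errstate(divide="ignore"):
                    m = 1.0 / dists
                np.fill_diagonal(m, 0.0)
            pair_sum += m.sum()
        pair_sum /= ensemble.n

    total = pair_sum
    if variant == "full":
        total += np.sum(1.0 / radii)
    return n * n / total


def mda_rh(A: MobilityTraceMatrix) -> tuple[float, np.ndarray]:
    """Minimum dissipation approximation: R_h and diffusion-center weights.

    With B = A^-1:  R_h = sum_ij B_ij and x_i = sum_j B_ij / sum_kj B_kj.
    Equivalently R_h is the reciprocal of the minimum of x^T A x over
    weight vectors summing to one, attained at x.
    """
    try:
        factor = cho_factor(A.A, lower=True)
    except np.linalg.LinAlgError as exc:
        eigmin = float(np.linalg.eigvalsh(A.A)[0])
        raise NumericalFailure(
            f"mobility matrix not positive definite (smallest eigenvalue {eigmin:.3e})"
        ) from exc
    ones = np.ones(A.A.shape[0])
    row_sums = cho_solve(factor, ones)  # B @ 1
    rh = float(ones @ row_sums)
    weights = row_sums / rh
    return rh, weights


def _batch_slices(n: int, n_batches: int) -> list[slice]:
    edges = np.linspace(0, n, n_batches + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def mda_rh_sem(ensemble: Ensemble, n_batches: int = 4) -> float:
    """Batch-means standard error of the MDA estimate.

    Per-conformer MDA values do not exist (one inversion per ensemble),
    so the ensemble is split into disjoint batches, build_A + mda_rh is
    re-run per batch, and the standard error of the batch estimates is
    returned. Degenerate for single-conformer ensembles (returns 0).
    """
    if n_batches < 4:
        raise ValueError("need at least 4 batches for a usable SEM")
    if ensemble.n < n_batches:
        return 0.0
    estimates = []
    for sl in _batch_slices(ensemble.n, n_batches):
        sub = Ensemble(
            chain=ensemble.chain,
            conformations=ensemble.conformations[sl],
            seed=ensemble.seed,
        )
        rh, _ = mda_rh(build_A(sub))
        estimates.append(rh)
    return float(np.std(estimates, ddof=1) / np.sqrt(len(estimates)))


def predict_rh(
    track: DisorderTrack,
    annotation: SegmentAnnotation,
    params: ModelParameters | None = None,
    n: int = 100,
    seed: int = 0,
) -> HydroResult:
    """End-to-end prediction: bead chain -> ensemble -> all estimators."""
    params = params or ModelParameters()
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    chain = build_bead_chain(track, annotation, params)
    logger.info(
        "predict_rh: N_residues=%d n_beads=%d n_conformers=%d seed=%d params=%s",
        len(track), len(chain), n, seed, params,
    )
    ensemble = sample_ensemble(chain, n, seed)
    A = build_A(ensemble)
    rh_mda, weights = mda_rh(A)
    rh_full = kirkwood_rh(ensemble, "full")
    rh_simplified = kirkwood_rh(ensemble, "simplified") if len(chain) > 1 else rh_full
    sem = mda_rh_sem(ensemble) if ensemble.n >= 4 else 0.0
    return HydroResult(
        rh_mda=rh_mda,
        rh_kirkwood_full=rh_full,
        rh_kirkwood_simplified=rh_simplified,
        sem_rh_mda=sem,
        diffusion_center_weights=weights,
        n_conformers=n,
        seed=seed,
    )


def stokes_einstein(rh: float, temperature: float, viscosity: float) -> float:
    """Translational diffusion coefficient (m^2/s) from R_h (A).

    D = k_B T / (6 pi eta R_h), with R_h converted from angstroms.
    """
    if rh <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("all inputs must be strictly positive")
    return Boltzmann * temperature / (6.0 * np.pi * viscosity * rh * 1e-10)
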