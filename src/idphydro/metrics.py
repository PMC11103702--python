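"""Benchmark scoring: error statistics and power-law baselines.

The error statistics follow the benchmarking conventions of the
hydrodynamic-radius prediction literature: RMSD and the third quartile
of the absolute error (in A), RMSRD and the third quartile of the
relative error (in %, relative to experiment), and the coefficient of
determination R^2 about the experimental mean — which can be negative
for predictors worse than the mean, unlike a squared correlation —
together with its adjustment for the number of fitting parameters.

Power-law baselines R_h = R_0 * N^gamma are fitted by ordinary least
squares in log-log space and scored under leave-one-out cross-validation
so that fitted and simulation-based (zero-parameter) methods are
compared on equal footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .bead_model import (
    DisorderTrack,
    annotation_from_domains,
    build_bead_chain,
    fully_disordered_annotation,
    merge_loops,
    segments_from_track,
)
from .hydrodynamics import kirkwood_rh, mda_rh, build_A
from .params import ModelParameters
from .sampler import sample_ensemble
from . import io as _io

logger = logging.getLogger(__name__)

ZIMM_EXPONENT = 0.588  # excluded-volume chain scaling exponent

MethodName = Literal[
    "mda_glm", "mda_glm_nd", "kr_glm", "kr_glm_nd", "power_law_1", "power_law_2"
]

#: Number of fitting parameters charged to each method in adjusted R^2.
METHOD_N_FP: dict[str, int] = {
    "mda_glm": 0,
    "mda_glm_nd": 0,
    "kr_glm": 0,
    "kr_glm_nd": 0,
    "power_law_1": 1,
    "power_law_2": 2,
}


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark protein: experiment plus pointers to its inputs."""

    id: str
    name: str
    n_residues: int
    experimental_rh: float
    method: str
    sequence_source: str
    annotation_source: str
    experimental_uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.experimental_rh <= 0:
            raise ValueError(f"record {self.id}: experimental R_h must be positive")
        if self.n_residues < 1:
            raise ValueError(f"record {self.id}: n_residues must be >= 1")


@dataclass(frozen=True)
class MetricsReport:
    """The six benchmark error statistics."""

    rmsd: float
    rmsrd: float
    r2: float
    r2_adj: float
    q3_ae: float
    q3_re: float
    n_fp: int
    n_proteins: int


@dataclass(frozen=True)
class PowerLawFit:
    """R_h = prefactor * N^gamma."""

    prefactor: float
    gamma: float
    fixed_gamma: bool

    def predict(self, n_residues) -> np.ndarray:
        return self.prefactor * np.asarray(n_residues, dtype=float) ** self.gamma


def error_stats(
    predicted: Sequence[float],
    experimental: Sequence[float],
    n_fp: int = 0,
    quartile_method: str = "linear",
) -> MetricsReport:
    """Compute the six error statistics for paired predictions.

    rmsd  = sqrt(mean (p - e)^2)                       [A]
    rmsrd = 100 * sqrt(mean ((p - e)/e)^2)             [%]
    r2    = 1 - sum (p - e)^2 / sum (e - mean(e))^2    (determination)
    r2adj = 1 - (1 - r2)(n - 1)/(n - n_fp - 1)
    q3_ae = third quartile of |p - e|                  [A]
    q3_re = 100 * third quartile of |p - e| / e        [%]
    """
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if p.shape != e.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and experimental must be equal-length 1-D arrays")
    if np.any(e <= 0):
        raise ValueError("experimental values must be strictly positive")
    n = p.size
    if n <= n_fp + 1:
        raise ValueError(
            f"adjusted R^2 undefined: n = {n} <= n_fp + 1 = {n_fp + 1}"
        )
    resid = p - e
    rmsd = float(np.sqrt(np.mean(resid**2)))
    rmsrd = float(100.0 * np.sqrt(np.mean((resid / e) ** 2)))
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_fp - 1)
    q3_ae = float(np.quantile(np.abs(resid), 0.75, method=quartile_method))
    q3_re = float(100.0 * np.quantile(np.abs(resid) / e, 0.75, method=quartile_method))
    return MetricsReport(
        rmsd=rmsd, rmsrd=rmsrd, r2=r2, r2_adj=r2_adj,
        q3_ae=q3_ae, q3_re=q3_re, n_fp=n_fp, n_proteins=n,
    )


def _fit_power_law_ols(
    n_residues: np.ndarray, rh: np.ndarray, n_params: int, fixed_gamma: float
) -> PowerLawFit:
    log_n = np.log(n_residues)
    log_r = np.log(rh)
    if n_params == 2:
        if np.ptp(log_n) == 0:
            raise ValueError("degenerate design: all records have the same length N")
        slope, intercept = np.polyfit(log_n, log_r, 1)
        return PowerLawFit(prefactor=float(np.exp(intercept)), gamma=float(slope),
                           fixed_gamma=False)
    # One free parameter: gamma pinned, prefactor from the mean log ratio
    # (the OLS solution of log R - gamma log N = log R_0).
    intercept = np.mean(log_r - fixed_gamma * log_n)
    return PowerLawFit(prefactor=float(np.exp(intercept)), gamma=fixed_gamma,
                       fixed_gamma=True)


def fit_power_law(
    records: Sequence[BenchmarkRecord],
    n_params: Literal[1, 2] = 2,
    fixed_gamma: float = ZIMM_EXPONENT,
) -> tuple[np.ndarray, PowerLawFit]:
    """Leave-one-out power-law predictions plus the full-data fit.

    Each record's prediction comes from the fit that excludes it;
    the returned :class:`PowerLawFit` is fitted on all records (for
    reporting the coefficients, not for scoring).
    """
    if len(records) < 3:
        raise ValueError("power-law fitting requires at least 3 records")
    if n_params not in (1, 2):
        raise ValueError("n_params must be 1 or 2")
    n_arr = np.array([r.n_residues for r in records], dtype=float)
    rh_arr = np.array([r.experimental_rh for r in records], dtype=float)
    loo = np.empty(len(records))
    for i in range(len(records)):
        mask = np.ones(len(records), dtype=bool)
        mask[i] = False
        fit_i = _fit_power_law_ols(n_arr[mask], rh_arr[mask], n_params, fixed_gamma)
        loo[i] = fit_i.predict(n_arr[i])
    full_fit = _fit_power_law_ols(n_arr, rh_arr, n_params, fixed_gamma)
    return loo, full_fit


def _predict_one(
    record: BenchmarkRecord,
    method: str,
    params: ModelParameters,
    n: int,
    seed: int,
) -> float:
    sequence = _io.read_fasta(record.sequence_source, record_id=record.id)
    if method.endswith("_nd"):
        # No-domain variant: ignore the annotation entirely.
        track = DisorderTrack(sequence, np.full(len(sequence), 0.9))
        annotation = fully_disordered_annotation(len(sequence))
    elif Path(record.annotation_source).suffix.lower() in (".tsv", ".domains"):
        domains = _io.read_domain_tsv(record.annotation_source)
        annotation = annotation_from_domains(domains, len(sequence))
        track = DisorderTrack(sequence, np.full(len(sequence), 0.9))
    else:
        track = _io.read_disorder_track(record.annotation_source, sequence=sequence)
        annotation = merge_loops(segments_from_track(track, params), params)
    chain = build_bead_chain(track, annotation, params)
    ensemble = sample_ensemble(chain, n, seed)
    if method.startswith("mda"):
        rh, _ = mda_rh(build_A(ensemble))
    else:  # Kirkwood rows use the simplified (large-N) formula
        if len(chain) == 1:
            rh = float(chain.hydro_radii[0])
        else:
            rh = kirkwood_rh(ensemble, "simplified")
    return rh


def run_benchmark(
    records: Sequence[BenchmarkRecord],
    methods: Iterable[str] = ("mda_glm",),
    params: ModelParameters | None = None,
    n: int = 100,
    seed: int = 0,
) -> tuple[dict[str, MetricsReport], pd.DataFrame]:
    """Score prediction methods against experimental radii.

    GLM methods use the record's annotation; ``_nd`` variants ignore it
    and treat the whole chain as disordered. ``kr_*`` methods use the
    simplified Kirkwood formula, ``mda_*`` the minimum dissipation
    approximation. ``power_law_1`` (fixed exponent) and ``power_law_2``
    (free exponent) are scored under leave-one-out cross-validation.

    Returns a per-method :class:`MetricsReport` dict and a per-protein
    prediction table. Records whose inputs cannot be resolved are
    excluded with a logged warning.
    """
    params = params or ModelParameters()
    methods = list(methods)
    unknown = set(methods) - set(METHOD_N_FP)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    rows: list[dict] = []
    reports: dict[str, MetricsReport] = {}
    for method in methods:
        if method.startswith("power_law"):
            n_params = 1 if method.endswith("_1") else 2
            loo, _ = fit_power_law(records, n_params)
            preds = {rec.id: float(p) for rec, p in zip(records, loo)}
            kept = list(records)
        else:
            preds = {}
            kept = []
            for i, rec in enumerate(records):
                try:
                    preds[rec.id] = _predict_one(rec, method, params, n, seed + i)
                    kept.append(rec)
                except (OSError, ValueError) as exc:
                    logger.warning("record %s skipped for %s: %s", rec.id, method, exc)
        if kept:
            exp = [r.experimental_rh for r in kept]
            pred = [preds[r.id] for r in kept]
            if len(kept) > METHOD_N_FP[method] + 1:
                reports[method] = error_stats(pred, exp, n_fp=METHOD_N_FP[method])
            else:
                logger.warning(
                    "method %s: %d record(s) too few for error statistics",
                    method, len(kept),
                )
            for rec, p in zip(kept, pred):
                rows.append(
                    {
                        "id": rec.id, "name": rec.name, "method": method,
                        "n_residues": rec.n_residues,
                        "experimental_rh_A": rec.experimental_rh,
                        "predicted_rh_A": p,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["id", "name", "method", "n_residues",
                 "experimental_rh_A", "predicted_rh_A"],
    )
    return reports, table
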