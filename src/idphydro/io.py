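"""Readers and writers for the plain-text formats the package consumes.

Conventions: coordinates and radii are always in angstroms; residue
intervals are 1-based inclusive everywhere. Every reader validates
against the in-memory type invariants and reports the file, line and
field of the first offending value — no silent coercion.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .bead_model import DisorderTrack
from .sampler import Ensemble


class FormatError(ValueError):
    """Malformed input file; message names file, line and field."""


def read_fasta(path, record_id: str | None = None) -> str:
    """Read one protein sequence from a FASTA file.

    With ``record_id`` the matching record is selected from a multi-record
    file; without it the file must contain exactly one record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if len(matches) == 1:
            return str(matches[0].seq).upper()
        if not matches and len(records) == 1:
            return str(records[0].seq).upper()
        raise FormatError(
            f"{path}: record {record_id!r} not found; available ids: "
            f"{[r.id for r in records]}"
        )
    if len(records) > 1:
        raise FormatError(
            f"{path}: expected a single record, found ids {[r.id for r in records]}"
        )
    return str(records[0].seq).upper()


def read_disorder_track(path, sequence: str | None = None) -> DisorderTrack:
    """Parse a DISOPRED3-style disorder track.

    Whitespace-separated columns ``index residue mark probability``;
    lines starting with '#' are comments; indices are 1-based and must
    be consecutive. When ``sequence`` is given it is cross-checked
    against the residue column.
    """
    residues: list[str] = []
    probs: list[float] = []
    expected_index = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns "
                    f"(index residue mark probability), got {len(parts)}"
                )
            try:
                idx = int(parts[0])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: index field {parts[0]!r} not an integer")
            if idx != expected_index:
                raise FormatError(
                    f"{path}:{lineno}: index {idx}, expected {expected_index} "
                    "(indices must be consecutive from 1)"
                )
            try:
                p = float(parts[3])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: probability field {parts[3]!r} not a number"
                )
            if not 0.0 <= p <= 1.0:
                raise FormatError(f"{path}:{lineno}: probability {p} outside [0, 1]")
            residues.append(parts[1])
            probs.append(p)
            expected_index += 1
    if not residues:
        raise FormatError(f"{path}: no data lines found")
    track_seq = "".join(residues).upper()
    if sequence is not None and sequence.upper() != track_seq:
        raise FormatError(
            f"{path}: residue column disagrees with the supplied sequence "
            f"(lengths {len(track_seq)} vs {len(sequence)})"
        )
    return DisorderTrack(track_seq, np.array(probs))


def read_domain_tsv(path) -> list[tuple[int, int]]:
    """Read folded-domain intervals: TSV with ``start end``, 1-based inclusive."""
    domains: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns (start end), got {len(parts)}"
                )
            try:
                s, e = int(parts[0]), int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: interval fields must be integers")
            if s < 1 or e < s:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval ({s}, {e}); need 1 <= start <= end"
                )
            domains.append((s, e))
    return domains


BENCHMARK_COLUMNS = [
    "id", "name", "n_residues", "experimental_rh_A",
    "experimental_uncertainty_A", "method", "fasta_path", "annotation_path",
]


def read_benchmark_csv(path):
    """Read a benchmark table into :class:`~idphydro.metrics.BenchmarkRecord` list."""
    from .metrics import BenchmarkRecord

    df = pd.read_csv(path)
    missing = set(BENCHMARK_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    base = Path(path).parent
    records = []
    for i, row in df.iterrows():
        unc = row["experimental_uncertainty_A"]
        try:
            records.append(
                BenchmarkRecord(
                    id=str(row["id"]),
                    name=str(row["name"]),
                    n_residues=int(row["n_residues"]),
                    experimental_rh=float(row["experimental_rh_A"]),
                    experimental_uncertainty=None if pd.isna(unc) else float(unc),
                    method=str(row["method"]),
                    sequence_source=str(base / row["fasta_path"]),
                    annotation_source=str(base / row["annotation_path"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
    return records


RESULT_COLUMNS = [
    "id", "N_residues", "n_beads", "n_conformers", "seed",
    "rh_mda_A", "sem_rh_mda_A", "rh_kirkwood_full_A", "rh_kirkwood_simplified_A",
]


def write_results_csv(path, rows: Iterable[dict]) -> None:
    """Write prediction results, one row per protein."""
    df = pd.DataFrame(list(rows), columns=RESULT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_results_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_xyz(path, ensemble: Ensemble) -> None:
    """Write an ensemble as extended XYZ, one frame per conformation.

    Columns: kind x y z steric_radius hydro_radius. The comment line
    carries the seed and frame index so any frame can be regenerated.
    """
    chain = ensemble.chain
    kinds = [b.kind for b in chain.beads]
    steric = chain.steric_radii
    hydro = chain.hydro_radii
    with open(path, "w") as fh:
        for frame, conf in enumerate(ensemble.conformations):
            fh.write(f"{len(chain)}\n")
            fh.write(
                f'seed={ensemble.seed} frame={frame} '
                f'Properties=species:S:1:pos:R:3:steric_radius:R:1:hydro_radius:R:1\n'
            )
            for kind, (x, y, z), s, h in zip(kinds, conf.coordinates, steric, hydro):
                fh.write(f"{kind} {x:.10g} {y:.10g} {z:.10g} {s:.10g} {h:.10g}\n")


def read_xyz_frames(path) -> list[np.ndarray]:
    """Read back the coordinate frames of an extended XYZ file."""
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: line {i + 1}: expected an atom count")
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    return frames


def write_weights_json(path, result, params) -> None:
    """Optional sidecar: diffusion-center weights plus the parameters used."""
    import json
    from dataclasses import asdict

    payload = {
        "seed": result.seed,
        "n_conformers": result.n_conformers,
        "rh_mda_A": result.rh_mda,
        "diffusion_center_weights": list(map(float, result.diffusion_center_weights)),
        "parameters": asdict(params),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
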