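"""Coarse-grained globule-linker model (GLM) construction.

A protein sequence with per-residue disorder annotation is reduced to a
chain of spheres: each folded domain becomes one large globule bead whose
radius follows from its mass and the bulk density of folded protein, and
each disordered residue becomes one small linker bead. Linker beads carry
two radii: a steric radius (half the C-alpha--C-alpha spacing) used for
excluded-volume sampling, and a larger hydrodynamic radius used when
mobilities are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from Bio.Data.IUPACData import protein_weights

from .params import ModelParameters

WATER_MASS = 18.01528  # Da, average

STANDARD_AA_CODES = "ACDEFGHIKLMNPQRSTVWY"

#: Average residue (monomer minus water) masses of the 20 standard amino
#: acids, Da.
RESIDUE_MASSES: dict[str, float] = {
    aa: protein_weights[aa] - WATER_MASS for aa in STANDARD_AA_CODES
}
#: Mean over the 20 standard residues; fallback for ambiguity codes.
MEAN_RESIDUE_MASS: float = float(np.mean(list(RESIDUE_MASSES.values())))

STANDARD_AA = set(RESIDUE_MASSES)
AMBIGUOUS_AA = set("XBZU")

SegmentKind = Literal["ordered", "disordered"]


@dataclass(frozen=True)
class DisorderTrack:
    """Amino-acid sequence with per-residue disorder probabilities."""

    sequence: str
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        if len(self.sequence) == 0:
            raise ValueError("sequence must be non-empty")
        if probs.ndim != 1 or probs.shape[0] != len(self.sequence):
            raise ValueError(
                f"probability track length {probs.shape} does not match "
                f"sequence length {len(self.sequence)}"
            )
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("disorder probabilities must lie in [0, 1]")
        bad = set(self.sequence) - STANDARD_AA - AMBIGUOUS_AA
        if bad:
            raise ValueError(f"unknown residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SegmentAnnotation:
    """Ordered/disordered partition of residues 1..N (1-based inclusive)."""

    segments: tuple[tuple[int, int, SegmentKind], ...]

    def __post_init__(self) -> None:
        segs = tuple((int(s), int(e), k) for s, e, k in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("annotation must contain at least one segment")
        if segs[0][0] != 1:
            raise ValueError("first segment must start at residue 1")
        for (s, e, k) in segs:
            if e < s:
                raise ValueError(f"segment ({s}, {e}) has end < start")
            if k not in ("ordered", "disordered"):
                raise ValueError(f"unknown segment kind {k!r}")
        for (s0, e0, k0), (s1, e1, k1) in zip(segs, segs[1:]):
            if s1 != e0 + 1:
                raise ValueError("segments must be contiguous and non-overlapping")
            if k0 == k1:
                raise ValueError("adjacent segments must alternate kinds")

    @property
    def n_residues(self) -> int:
        return self.segments[-1][1]

    def ordered_segments(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, k in self.segments if k == "ordered"]


@dataclass(frozen=True)
class Bead:
    """One sphere of the coarse-grained chain.

    ``steric_radius`` governs excluded volume and bond lengths during
    sampling; ``hydro_radius`` enters the mobility matrix. For globules
    the two coincide; for linker beads the hydrodynamic radius is
    inflated to the median single-residue value.
    """

    kind: Literal["globule", "linker"]
    steric_radius: float
    hydro_radius: float
    residue_span: tuple[int, int]
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.steric_radius <= 0 or self.hydro_radius <= 0:
            raise ValueError("bead radii must be strictly positive")
        s, e = self.residue_span
        if self.kind == "linker" and e != s:
            raise ValueError("linker beads must span exactly one residue")


@dataclass(frozen=True)
class BeadChain:
    """Ordered bead chain with the parameters that produced it."""

    beads: tuple[Bead, ...]
    params: ModelParameters

    def __post_init__(self) -> None:
        object.__setattr__(self, "beads", tuple(self.beads))
        if not self.beads:
            raise ValueError("bead chain must contain at least one bead")
        pos = 1
        for bead in self.beads:
            s, e = bead.residue_span
            if s != pos:
                raise ValueError("bead residue spans must partition the sequence")
            pos = e + 1

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def n_residues(self) -> int:
        return self.beads[-1].residue_span[1]

    @property
    def steric_radii(self) -> np.ndarray:
        return np.array([b.steric_radius for b in self.beads])

    @property
    def hydro_radii(self) -> np.ndarray:
        return np.array([b.hydro_radius for b in self.beads])


def segments_from_track(
    track: DisorderTrack, params: ModelParameters | None = None
) -> SegmentAnnotation:
    """Annotate ordered/disordered segments from a disorder-probability track.

    A maximal run of residues with disorder probability strictly below
    ``params.disorder_threshold`` counts as ordered only if it spans at
    least ``params.min_ordered_run`` residues; every other residue is
    disordered. Ties at the threshold are disordered.
    """
    params = params or ModelParameters()
    probs = track.probabilities
    below = probs < params.disorder_threshold

    ordered_mask = np.zeros(len(track), dtype=bool)
    i = 0
    n = len(track)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= params.min_ordered_run:
                ordered_mask[i:j] = True
            i = j
        else:
            i += 1
    return _annotation_from_mask(ordered_mask)


def _annotation_from_mask(ordered_mask: np.ndarray) -> SegmentAnnotation:
    segments: list[tuple[int, int, SegmentKind]] = []
    n = len(ordered_mask)
    i = 0
    while i < n:
        j = i
        while j < n and ordered_mask[j] == ordered_mask[i]:
            j += 1
        kind: SegmentKind = "ordered" if ordered_mask[i] else "disordered"
        segments.append((i + 1, j, kind))
        i = j
    return SegmentAnnotation(tuple(segments))


def merge_loops(
    annotation: SegmentAnnotation, params: ModelParameters | None = None
) -> SegmentAnnotation:
    """Absorb short disordered loops into flanking ordered segments.

    A disordered segment of length <= ``params.max_loop`` flanked by
    ordered segments on both sides is fused with its neighbours into a
    single ordered segment (one folded domain). Merging proceeds
    left-to-right and is repeated until a fixed point is reached;
    terminal disordered tails are never absorbed.
    """
    params = params or ModelParameters()
    segs = list(annotation.segments)
    changed = True
    while changed:
        changed = False
        i = 1
        while i < len(segs) - 1:
            s, e, kind = segs[i]
            if (
                kind == "disordered"
                and e - s + 1 <= params.max_loop
                and segs[i - 1][2] == "ordered"
                and segs[i + 1][2] == "ordered"
            ):
                fused = (segs[i - 1][0], segs[i + 1][1], "ordered")
                segs[i - 1 : i + 2] = [fused]
                changed = True
            else:
                i += 1
    return SegmentAnnotation(tuple(segs))


def fragment_mass(sequence_fragment: str, strict: bool = False) -> float:
    """Average mass (Da) of a residue run interior to a chain.

    Sums average residue masses (monomer minus water); no terminal water
    is added because the fragment is flanked by peptide bonds. Ambiguity
    codes X/B/Z/U map to the mean standard-residue mass unless
    ``strict`` is set.
    """
    if not sequence_fragment:
        raise ValueError("sequence fragment must be non-empty")
    total = 0.0
    for aa in sequence_fragment:
        if aa in RESIDUE_MASSES:
            total += RESIDUE_MASSES[aa]
        elif aa in AMBIGUOUS_AA and not strict:
            total += MEAN_RESIDUE_MASS
        else:
            raise ValueError(f"unknown residue code {aa!r}")
    return total


def globule_radius(mass: float, params: ModelParameters | None = None) -> float:
    """Hydrodynamic radius (A) of a folded domain of the given mass (Da).

    The domain is modeled as a compact sphere of bulk protein density
    plus one hydration layer:  R = (3 m / 4 pi rho)^(1/3) + a_hydration.
    """
    params = params or ModelParameters()
    if mass <= 0:
        raise ValueError("domain mass must be strictly positive")
    return (3.0 * mass / (4.0 * np.pi * params.rho_globular)) ** (1.0 / 3.0) + params.a_hydration


def build_bead_chain(
    track: DisorderTrack,
    annotation: SegmentAnnotation,
    params: ModelParameters | None = None,
) -> BeadChain:
    """Assemble the globule-linker bead chain from sequence and annotation.

    Each ordered segment becomes one globule bead (steric radius ==
    hydrodynamic radius, from its mass); each disordered residue becomes
    one linker bead with steric radius ``ca_ca_distance / 2`` and
    hydrodynamic radius ``r_disordered``.
    """
    params = params or ModelParameters()
    if annotation.n_residues != len(track):
        raise ValueError(
            f"annotation covers {annotation.n_residues} residues but track "
            f"has {len(track)}"
        )
    beads: list[Bead] = []
    for s, e, kind in annotation.segments:
        if kind == "ordered":
            mass = fragment_mass(track.sequence[s - 1 : e])
            radius = globule_radius(mass, params)
            beads.append(
                Bead(
                    kind="globule",
                    steric_radius=radius,
                    hydro_radius=radius,
                    residue_span=(s, e),
                    mass=mass,
                )
            )
        else:
            for res in range(s, e + 1):
                beads.append(
                    Bead(
                        kind="linker",
                        steric_radius=params.ca_ca_distance / 2.0,
                        hydro_radius=params.r_disordered,
                        residue_span=(res, res),
                    )
                )
    return BeadChain(tuple(beads), params)


def fully_disordered_annotation(n_residues: int) -> SegmentAnnotation:
    """Annotation treating the whole chain as disordered (the 'ND' mode)."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    return SegmentAnnotation(((1, n_residues, "disordered"),))


def annotation_from_domains(
    domains: Iterable[tuple[int, int]], n_residues: int
) -> SegmentAnnotation:
    """Build an annotation from explicit folded-domain intervals.

    ``domains`` are 1-based inclusive ``(start, end)`` pairs; residues
    outside all domains are disordered. This bypasses the probability
    thresholding and loop-merging entirely.
    """
    ordered_mask = np.zeros(n_residues, dtype=bool)
    for s, e in domains:
        if not (1 <= s <= e <= n_residues):
            raise ValueError(f"domain ({s}, {e}) outside sequence of length {n_residues}")
        if ordered_mask[s - 1 : e].any():
            raise ValueError(f"domain ({s}, {e}) overlaps a previous domain")
        ordered_mask[s - 1 : e] = True
    return _annotation_from_mask(ordered_mask)
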