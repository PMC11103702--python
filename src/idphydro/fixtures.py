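"""Synthetic-protein fixture generator.

Emits a random sequence, a disorder-probability track consistent with a
stated ordered/disordered layout, and the ground-truth annotation, so
that every downstream stage can be tested without external predictions
or downloads. Disordered residues receive probabilities centered at 0.9
and ordered ones at 0.1, with uniform jitter small enough that no
residue can cross the 0.5 decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .bead_model import (
    STANDARD_AA_CODES,
    DisorderTrack,
    SegmentAnnotation,
    fragment_mass,
)

#: Alphabet used for random sequences: the 20 standard amino acids.
FIXTURE_ALPHABET = STANDARD_AA_CODES

DISORDERED_CENTER = 0.9
ORDERED_CENTER = 0.1


@dataclass(frozen=True)
class FixtureSpec:
    """Layout of a synthetic protein: ordered/disordered blocks plus noise."""

    layout: tuple[tuple[Literal["ordered", "disordered"], int], ...]
    seed: int = 0
    disorder_noise: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "layout", tuple((k, int(n)) for k, n in self.layout))
        if not self.layout:
            raise ValueError("layout must contain at least one block")
        for kind, length in self.layout:
            if kind not in ("ordered", "disordered"):
                raise ValueError(f"unknown block kind {kind!r}")
            if length < 1:
                raise ValueError("block lengths must be >= 1")
        if not 0.0 <= self.disorder_noise <= 0.4:
            raise ValueError("disorder_noise must lie in [0, 0.4]")

    @property
    def n_residues(self) -> int:
        return sum(n for _, n in self.layout)


@dataclass(frozen=True)
class Fixture:
    """A generated synthetic protein with its ground truth."""

    sequence: str
    track: DisorderTrack
    annotation: SegmentAnnotation
    domain_masses: tuple[float, ...]

    def fasta(self, record_id: str = "fixture") -> str:
        lines = [f">{record_id}"]
        for i in range(0, len(self.sequence), 60):
            lines.append(self.sequence[i : i + 60])
        return "\n".join(lines) + "\n"

    def disorder_track_text(self) -> str:
        """DISOPRED3-style column rendering of the track."""
        lines = ["# index residue mark probability"]
        for i, (aa, p) in enumerate(
            zip(self.track.sequence, self.track.probabilities), start=1
        ):
            mark = "*" if p >= 0.5 else "."
            lines.append(f"{i:5d} {aa} {mark} {p:.3f}")
        return "\n".join(lines) + "\n"


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a synthetic protein matching the stated layout.

    The emitted annotation is the ground truth the probability track
    encodes: thresholding the track at 0.5 recovers the layout exactly
    (blocks alternate in kind by merging adjacent same-kind blocks).
    Reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    alphabet = np.array(list(FIXTURE_ALPHABET))
    sequence = "".join(rng.choice(alphabet, size=n))

    probs = np.empty(n)
    segments: list[tuple[int, int, str]] = []
    pos = 0
    for kind, length in spec.layout:
        center = ORDERED_CENTER if kind == "ordered" else DISORDERED_CENTER
        jitter = rng.uniform(-spec.disorder_noise, spec.disorder_noise, size=length)
        probs[pos : pos + length] = np.clip(center + jitter, 0.0, 1.0)
        if segments and segments[-1][2] == kind:
            s, _, _ = segments[-1]
            segments[-1] = (s, pos + length, kind)
        else:
            segments.append((pos + 1, pos + length, kind))
        pos += length

    track = DisorderTrack(sequence, probs)
    annotation = SegmentAnnotation(tuple(segments))
    masses = tuple(
        fragment_mass(sequence[s - 1 : e]) for s, e in annotation.ordered_segments()
    )
    return Fixture(sequence=sequence, track=track, annotation=annotation,
                   domain_masses=masses)
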