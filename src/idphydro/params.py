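"""Physical constants and tunable parameters of the globule-linker model.

All lengths are in angstroms, masses in daltons, and densities in Da/A^3
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the globule-linker bead model.

    Attributes
    ----------
    rho_globular : float
        Bulk mass density of folded protein, Da/A^3. Sets globule radii
        through the compact-sphere relation.
    a_hydration : float
        Thickness of a single hydration layer added to globule radii, A.
    r_disordered : float
        Hydrodynamic radius assigned to each disordered-residue bead, A
        (median single-residue hydrodynamic radius).
    ca_ca_distance : float
        Trans-peptide C-alpha--C-alpha spacing, A; the steric diameter of
        linker beads, and hence the bond length between consecutive
        linker beads.
    disorder_threshold : float
        Disorder probability below which a residue counts as ordered.
    min_ordered_run : int
        Minimum number of consecutive sub-threshold residues that
        constitutes an ordered segment.
    max_loop : int
        Maximum length (residues) of a disordered loop absorbed into a
        folded domain when flanked by ordered segments.
    overlap_tolerance : float
        Relative tolerance used when testing bead pairs for steric
        overlap; guards against floating-point false positives for
        exactly touching spheres.
    """

    rho_globular: float = 0.52
    a_hydration: float = 3.0
    r_disordered: float = 4.2
    ca_ca_distance: float = 3.8
    disorder_threshold: float = 0.5
    min_ordered_run: int = 3
    max_loop: int = 14
    overlap_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("rho_globular", "a_hydration", "r_disordered", "ca_ca_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.disorder_threshold < 1.0:
            raise ValueError("disorder_threshold must lie in (0, 1)")
        if self.min_ordered_run < 1:
            raise ValueError("min_ordered_run must be >= 1")
        if self.max_loop < 0:
            raise ValueError("max_loop must be >= 0")
        if not 0.0 <= self.overlap_tolerance < 1.0:
            raise ValueError("overlap_tolerance must lie in [0, 1)")

    @classmethod
    def from_file(cls, path) -> "ModelParameters":
        """Read ``key = value`` lines, '#' comments allowed, unknown keys rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                caster = int if key in ("min_ordered_run", "max_loop") else float
                kwargs[key] = caster(value)
        return cls(**kwargs)
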