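import numpy as np
import pytest

from idphydro import Bead, BeadChain, Conformation, Ensemble, ModelParameters


@pytest.fixture
def params():
    return ModelParameters()


def rigid_chain(radii, params=None):
    """Bead chain with steric == hydro radii, one residue per bead."""
    params = params or ModelParameters()
    beads = tuple(
        Bead(kind="linker", steric_radius=float(r), hydro_radius=float(r),
             residue_span=(i + 1, i + 1))
        for i, r in enumerate(radii)
    )
    return BeadChain(beads, params)


def rigid_ensemble(radii, coords_frames, params=None):
    """Ensemble of explicit rigid configurations (no sampling)."""
    chain = rigid_chain(radii, params)
    confs = tuple(Conformation(np.asarray(c, dtype=float)) for c in coords_frames)
    return Ensemble(chain=chain, conformations=confs, seed=0)
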