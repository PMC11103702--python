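"""Excluded-volume scaling of R_h with chain length (quick version).

Fully disordered chains obey R_h ~ N^nu with the Zimm/Flory exponent
nu ~ 0.588; ideal (non-self-avoiding) chains give nu = 0.5. This script
demonstrates the effect on short chains in under a minute; the
acceptance script runs the full N <= 800 version.
"""

import numpy as np

from idphydro import (
    DisorderTrack, build_A, build_bead_chain, fully_disordered_annotation,
    mda_rh, sample_ensemble,
)

lengths = [50, 100, 200, 400]
rh_values = []
for i, n_res in enumerate(lengths):
    track = DisorderTrack("A" * n_res, np.full(n_res, 0.9))
    chain = build_bead_chain(track, fully_disordered_annotation(n_res))
    ens = sample_ensemble(chain, 100, seed=10 + i)
    rh, _ = mda_rh(build_A(ens))
    rh_values.append(rh)
    print(f"N = {n_res:4d}: mean MDA R_h = {rh:6.2f} A")

slope = np.polyfit(np.log(lengths), np.log(rh_values), 1)[0]
print(f"\nfitted exponent nu = {slope:.3f}  (Zimm: 0.588, ideal chain: 0.5)")
print("Self-avoidance swells the chain: the exponent sits clearly above")
print("0.5 and approaches 0.588 as finite-size effects fade with length.")
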