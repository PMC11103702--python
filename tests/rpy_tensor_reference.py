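"""Independent reference: full 3x3 Rotne-Prager-Yamakawa pair mobilities.

Builds the complete polydisperse RPY translational mobility tensors
(separated, partially overlapping, and fully contained branches) and
contracts the trace numerically. Serves as an independent route to the
closed-form scalar pair trace used by the package: the package computes
the trace analytically, this module assembles the tensor from the
published isotropic/dyadic decomposition and traces it numerically.
"""

import numpy as np


def rpy_pair_mobility(a_i: float, a_j: float, r_vec: np.ndarray, eta: float = 1.0) -> np.ndarray:
    """3x3 translational mobility coupling two spheres, any separation."""
    r = float(np.linalg.norm(r_vec))
    eye = np.eye(3)
    if r == 0.0 and a_i == a_j:
        return eye / (6.0 * np.pi * eta * a_i)
    rhat = r_vec / r
    outer = np.outer(rhat, rhat)
    if r >= a_i + a_j:
        iso = (1.0 + (a_i**2 + a_j**2) / (3.0 * r**2)) / (8.0 * np.pi * eta * r)
        dyad = (1.0 - (a_i**2 + a_j**2) / r**2) / (8.0 * np.pi * eta * r)
        return iso * eye + dyad * outer
    if r <= abs(a_i - a_j):
        return eye / (6.0 * np.pi * eta * max(a_i, a_j))
    d = a_i - a_j
    pref = 1.0 / (6.0 * np.pi * eta * a_i * a_j)
    iso = pref * (16.0 * r**3 * (a_i + a_j) - (d**2 + 3.0 * r**2) ** 2) / (32.0 * r**3)
    dyad = pref * 3.0 * (d**2 - r**2) ** 2 / (32.0 * r**3)
    return iso * eye + dyad * outer


def rpy_trace_matrix(radii: np.ndarray, coords: np.ndarray, eta: float = 1.0) -> np.ndarray:
    """Matrix of 2*pi*eta*Tr(mu_ij) for a rigid bead configuration."""
    n = len(radii)
    A = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                mu = np.eye(3) / (6.0 * np.pi * eta * radii[i])
            else:
                mu = rpy_pair_mobility(radii[i], radii[j], coords[j] - coords[i], eta)
            A[i, j] = 2.0 * np.pi * eta * np.trace(mu)
    return A
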