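"""Independent small-scale oracles used by the test suite.

The first-order (delta-method) RMS prediction is computed from a
finite-difference gradient of the reconstruction formula with respect to
the six fiducial coordinates.  It deliberately shares no code with the
Monte Carlo engine: reconstruction is re-expressed here directly from the
two z formulas, and the gradient is numerical, so agreement between the
simulated RMS and this prediction cross-checks both the forward models and
the noise propagation.
"""

from __future__ import annotations

import math

import numpy as np

from stereoloc.localizers import (
    FiducialTriplet,
    SectionPose,
    n_forward_fiducials,
    sp_forward_fiducials,
)


def _zhat_from_coords(coords: np.ndarray, localizer: str) -> float:
    ua, va, ub, vb, uc, vc = coords
    if localizer == "n":
        d_bc = math.hypot(ub - uc, vb - vc)
        d_ac = math.hypot(ua - uc, va - vc)
        return 140.0 * d_bc / d_ac
    d_ab = math.hypot(ua - ub, va - vb)
    d_bc = math.hypot(ub - uc, vb - vc)
    return 4.0 * d_ab * d_bc / math.sqrt((d_bc + d_ab) ** 2 + 4.0 * (d_bc - d_ab) ** 2)


def delta_method_rms(localizer: str, pose: SectionPose, epsilon: float,
                     h: float = 1e-6) -> float:
    """First-order RMS z-error for iid uniform(-eps, eps) coordinate noise.

    Linearizes z_hat in the six fiducial coordinates at the unperturbed
    triplet via central finite differences; each coordinate contributes
    variance eps^2 / 3, so rms ~= ||grad|| * eps / sqrt(3).
    """
    trip: FiducialTriplet = (
        n_forward_fiducials(pose) if localizer == "n" else sp_forward_fiducials(pose)
    )
    base = np.array([trip.a[0], trip.a[1], trip.b[0], trip.b[1], trip.c[0], trip.c[1]])
    grad = np.empty(6)
    for i in range(6):
        up = base.copy()
        dn = base.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (_zhat_from_coords(up, localizer) - _zhat_from_coords(dn, localizer)) / (2 * h)
    return float(np.linalg.norm(grad) * epsilon / math.sqrt(3.0))
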