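"""Forward and inverse geometry of stereotactic fiducial localizers.

Two localizer designs are modelled:

* The **N-localizer**: two vertical rods (A, C) joined by one diagonal rod
  (B), forming an "N".  The position of the diagonal rod's fiducial between
  the two vertical-rod fiducials encodes the height ``z`` of the tomographic
  section by linear interpolation.  The reconstruction uses only the
  dimensionless ratio of two inter-fiducial distances, so it is independent
  of the image pixel size.

* The **Sturm-Pastyr localizer**: two diagonal rods (A, C) meeting a vertical
  rod (B) in a "V".  Each diagonal rod makes the manufactured angle
  ``upsilon = arctan(1/2)`` with the vertical rod.  The height ``z`` is
  recovered from the two inter-fiducial distances by a non-linear formula
  whose output carries the *units of the measured distances* — the caller
  must therefore supply distances already converted to millimetres via the
  image pixel size.

All public interfaces take angles in degrees and lengths in millimetres.
The forward models place the three fiducials on the image u-axis; this is
one of many rigid placements and any other placement yields identical
inter-fiducial distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "UPSILON_DEG",
    "BETA_MAX_N_DEG",
    "BETA_MAX_SP_DEG",
    "NLocalizerSpec",
    "SturmPastyrSpec",
    "SectionPose",
    "FiducialTriplet",
    "DistancePair",
    "DegenerateGeometryError",
    "euclidean_distance",
    "n_localizer_z",
    "sturm_pastyr_z",
    "n_forward_fiducials",
    "sp_forward_distances",
    "sp_forward_fiducials",
]

#: Manufactured angle between each diagonal rod and the vertical rod of the
#: Sturm-Pastyr localizer: arctan(1/2) = 26.565... degrees.
UPSILON_DEG: float = math.degrees(math.atan(0.5))

#: Hard tilt limit for the N-localizer.  cos(beta) -> 0 as beta -> 90 deg;
#: 85 deg keeps the forward model comfortably away from the blow-up.
BETA_MAX_N_DEG: float = 85.0

#: Hard tilt limit for the Sturm-Pastyr localizer, strictly below the
#: geometric singularity at 90 - upsilon = 63.435 deg where the B-C
#: fiducial distance diverges.
BETA_MAX_SP_DEG: float = 60.0


class DegenerateGeometryError(ValueError):
    """Raised when a fiducial configuration admits no z reconstruction."""


class FiducialTriplet(NamedTuple):
    """Image-plane (u, v) centres, in mm, of the three rod fiducials."""

    a: tuple[float, float]
    b: tuple[float, float]
    c: tuple[float, float]

    def distances(self) -> "DistancePair":
        """Inter-fiducial distances computed with the Pythagorean formula."""
        return DistancePair(
            d_ab=euclidean_distance(self.a, self.b),
            d_bc=euclidean_distance(self.b, self.c),
            d_ac=euclidean_distance(self.a, self.c),
        )


class DistancePair(NamedTuple):
    """Inter-fiducial distances in mm.

    ``d_ac`` is meaningful for the N-localizer only; the Sturm-Pastyr
    reconstruction uses ``d_ab`` and ``d_bc``.
    """

    d_ab: float
    d_bc: float
    d_ac: float = 0.0


@dataclass(frozen=True)
class NLocalizerSpec:
    """Design constants of an N-localizer.

    Parameters
    ----------
    z_top : float
        z-coordinate (mm) of the top of vertical rod A.
    z_bottom : float
        z-coordinate (mm) of the bottom of vertical rod C.
    rod_spacing : float
        Horizontal separation (mm) between the two vertical rods.

    Defaults follow the common frame geometry of 140 mm rods 140 mm apart
    with the frame base at z = 0; real frames differ, so all three are
    configurable.
    """

    z_top: float = 140.0
    z_bottom: float = 0.0
    rod_spacing: float = 140.0

    def __post_init__(self) -> None:
        if not (self.z_top > self.z_bottom):
            raise ValueError(f"z_top ({self.z_top}) must exceed z_bottom ({self.z_bottom})")
        if not (self.rod_spacing > 0):
            raise ValueError(f"rod_spacing must be positive, got {self.rod_spacing}")


@dataclass(frozen=True)
class SturmPastyrSpec:
    """Design constant of a Sturm-Pastyr (V-shaped) localizer.

    ``upsilon`` is the angle, in degrees, between each diagonal rod and the
    central vertical rod.  The manufactured value is arctan(1/2).
    """

    upsilon: float = UPSILON_DEG

    def __post_init__(self) -> None:
        if not (0.0 < self.upsilon < 90.0):
            raise ValueError(f"upsilon must lie in (0, 90) degrees, got {self.upsilon}")

    @property
    def beta_singularity(self) -> float:
        """Tilt angle (deg) at which d_BC diverges: 90 - upsilon."""
        return 90.0 - self.upsilon


@dataclass(frozen=True)
class SectionPose:
    """Pose of an idealized (infinitely thin) tomographic section.

    Parameters
    ----------
    z : float
        Height (mm) above the frame base at which the section crosses the
        axis of rod B.
    beta : float
        Tilt (degrees) of the section relative to the frame base.
    """

    z: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.z) or self.z < 0:
            raise ValueError(f"z must be finite and >= 0, got {self.z}")
        if not math.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")


def euclidean_distance(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Pythagorean distance between two image-plane points, in mm."""
    pu, pv = p
    qu, qv = q
    if not all(map(math.isfinite, (pu, pv, qu, qv))):
        raise ValueError(f"non-finite coordinate in {p!r}, {q!r}")
    return math.hypot(pu - qu, pv - qv)


def n_localizer_z(d_bc: float, d_ac: float, spec: NLocalizerSpec | None = None) -> float:
    """Reconstruct z from N-localizer fiducial distances.

    Linear interpolation between the ends of the diagonal rod:

        z = z_C + (d_BC / d_AC) * (z_A - z_C)

    The ratio d_BC/d_AC is dimensionless, so the distances may be in any
    common unit (pixels included) and the result carries the units of the
    frame constants in ``spec``.
    """
    if spec is None:
        spec = NLocalizerSpec()
    if d_bc < 0 or d_ac < 0 or not (math.isfinite(d_bc) and math.isfinite(d_ac)):
        raise ValueError(f"distances must be finite and >= 0, got d_bc={d_bc}, d_ac={d_ac}")
    if d_ac == 0:
        raise DegenerateGeometryError("d_ac = 0: fiducials A and C coincide")
    return spec.z_bottom + (d_bc / d_ac) * (spec.z_top - spec.z_bottom)


def sturm_pastyr_z(d_ab: float, d_bc: float) -> float:
    """Reconstruct z from Sturm-Pastyr fiducial distances.

        z = 4 d_AB d_BC / sqrt((d_BC + d_AB)^2 + 4 (d_BC - d_AB)^2)

    Unlike the N-localizer formula, the result carries the units of the
    input distances, so pixel measurements must be converted to mm *before*
    calling this function.  When the section is parallel to the frame base
    (d_AB = d_BC = d) this reduces to z = 2d.

    Both distances zero corresponds to the apex of the V, where z = 0 by
    construction; the 0/0 limit along any approach ray is 0, so 0 is
    returned rather than NaN.
    """
    if d_ab < 0 or d_bc < 0 or not (math.isfinite(d_ab) and math.isfinite(d_bc)):
        raise ValueError(f"distances must be finite and >= 0, got d_ab={d_ab}, d_bc={d_bc}")
    if d_ab == 0.0 and d_bc == 0.0:
        return 0.0
    num = 4.0 * d_ab * d_bc
    den = math.sqrt((d_bc + d_ab) ** 2 + 4.0 * (d_bc - d_ab) ** 2)
    return num / den


def n_forward_fiducials(pose: SectionPose, spec: NLocalizerSpec | None = None) -> FiducialTriplet:
    """Unperturbed fiducial positions for a section crossing an N-localizer.

    The section at height z tilted by beta cuts the rods at in-plane
    distances stretched by 1/cos(beta); placing C at the origin and the
    triplet along the u-axis gives

        C = (0, 0),  B = (z / cos beta, 0),  A = (spacing / cos beta, 0).
    """
    if spec is None:
        spec = NLocalizerSpec()
    if pose.beta > BETA_MAX_N_DEG:
        raise ValueError(f"beta={pose.beta} deg exceeds N-localizer limit {BETA_MAX_N_DEG} deg")
    height = spec.z_top - spec.z_bottom
    if pose.z > height:
        raise ValueError(f"z={pose.z} mm is above the top of the localizer ({height} mm)")
    cos_b = math.cos(math.radians(pose.beta))
    return FiducialTriplet(
        a=(spec.rod_spacing / cos_b, 0.0),
        b=(pose.z / cos_b, 0.0),
        c=(0.0, 0.0),
    )


def sp_forward_distances(pose: SectionPose, spec: SturmPastyrSpec | None = None) -> DistancePair:
    """Unperturbed fiducial distances for the Sturm-Pastyr localizer.

    From the rod geometry (law of sines in the triangles formed by the
    section, the vertical rod and each diagonal rod):

        d_AB = z sin(upsilon) / sin(pi/2 + beta - upsilon)
        d_BC = z sin(upsilon) / sin(pi/2 - beta - upsilon)

    d_BC diverges as beta approaches 90 - upsilon; poses beyond
    ``BETA_MAX_SP_DEG`` are rejected.
    """
    if spec is None:
        spec = SturmPastyrSpec()
    if pose.beta > BETA_MAX_SP_DEG or pose.beta >= spec.beta_singularity:
        raise ValueError(
            f"beta={pose.beta} deg out of range for the Sturm-Pastyr localizer "
            f"(limit {min(BETA_MAX_SP_DEG, spec.beta_singularity)} deg; "
            f"d_BC diverges at {spec.beta_singularity:.3f} deg)"
        )
    ups = math.radians(spec.upsilon)
    beta = math.radians(pose.beta)
    sin_u = math.sin(ups)
    d_ab = pose.z * sin_u / math.sin(math.pi / 2 + beta - ups)
    d_bc = pose.z * sin_u / math.sin(math.pi / 2 - beta - ups)
    return DistancePair(d_ab=d_ab, d_bc=d_bc, d_ac=d_ab + d_bc)


def sp_forward_fiducials(pose: SectionPose, spec: SturmPastyrSpec | None = None) -> FiducialTriplet:
    """Unperturbed fiducial positions for the Sturm-Pastyr localizer.

    With B (the vertical rod) at the origin and the triplet along the
    u-axis:  A = (-d_AB, 0),  B = (0, 0),  C = (d_BC, 0).
    """
    d = sp_forward_distances(pose, spec)
    return FiducialTriplet(a=(-d.d_ab, 0.0), b=(0.0, 0.0), c=(d.d_bc, 0.0))
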