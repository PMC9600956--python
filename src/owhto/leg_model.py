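"""Parametric coronal-plane model of a lower limb.

The limb is reduced to its frontal-plane skeleton: hip, knee and ankle
centres plus the medial and lateral edge points of the tibial plateau,
all in millimetres.  Two alignment measures are derived from it:

* the mechanical femorotibial angle (mFTA) -- the signed angle between
  the femoral mechanical axis (hip to knee) and the tibial mechanical
  axis (knee to ankle), positive for varus (ankle deviated medially);
* the weight-bearing-line (WBL) fraction -- where the Mikulicz line
  (hip centre to ankle centre) crosses the joint line, expressed as a
  fraction of the plateau width measured from the medial edge (0 =
  medial edge, 0.5 = centre, 1 = lateral edge).

The canonical embedding produced by :func:`make_leg` puts the knee at
the origin with a horizontal joint line and a vertical femoral axis,
and places the entire varus deformity in the proximal tibia (deformity
apex at the knee): the femur is modelled neutral, which is the relevant
situation for a tibial valgising osteotomy.  All measures are, however,
computed from the labelled landmarks only, so they are invariant under
rigid motion and left/right mirroring of the whole construct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LegGeometry",
    "InvalidLegError",
    "DegenerateGeometryError",
    "make_leg",
    "mfta",
    "wbl_fraction",
    "mirrored",
    "transformed",
]


class InvalidLegError(ValueError):
    """Raised for parameters that cannot describe a physical limb."""


class DegenerateGeometryError(ValueError):
    """Raised when an alignment measure is undefined (parallel/zero-length)."""


def _pt(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise InvalidLegError(f"expected a 2D point, got shape {a.shape}")
    return a


def _cross(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


@dataclass(frozen=True)
class LegGeometry:
    """Frontal-plane landmark set for one lower limb (all coordinates in mm).

    ``plateau_medial`` and ``plateau_lateral`` must lie on a straight joint
    line with ``knee_center`` at their midpoint; this is validated on
    construction.
    """

    side: str
    hip_center: np.ndarray
    knee_center: np.ndarray
    ankle_center: np.ndarray
    plateau_medial: np.ndarray
    plateau_lateral: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise InvalidLegError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in ("hip_center", "knee_center", "ankle_center",
                     "plateau_medial", "plateau_lateral"):
            object.__setattr__(self, name, _pt(getattr(self, name)))
        if self.plateau_width <= 0:
            raise InvalidLegError("plateau width must be positive")
        if self.femoral_length <= 0 or self.tibial_length <= 0:
            raise InvalidLegError("bone lengths must be positive")
        mid = 0.5 * (self.plateau_medial + self.plateau_lateral)
        if np.linalg.norm(mid - self.knee_center) > 1e-6 * self.plateau_width:
            raise InvalidLegError("knee_center must be the plateau midpoint")

    # -- derived scalars ------------------------------------------------

    @property
    def plateau_width(self) -> float:
        return float(np.linalg.norm(self.plateau_lateral - self.plateau_medial))

    @property
    def femoral_length(self) -> float:
        return float(np.linalg.norm(self.hip_center - self.knee_center))

    @property
    def tibial_length(self) -> float:
        return float(np.linalg.norm(self.ankle_center - self.knee_center))

    @property
    def varus_angle(self) -> float:
        """Signed mFTA in degrees (varus positive)."""
        return mfta(self)

    # -- derived unit directions ----------------------------------------

    @property
    def lateral_dir(self) -> np.ndarray:
        """Unit vector along the joint line, pointing laterally."""
        return (self.plateau_lateral - self.plateau_medial) / self.plateau_width

    @property
    def medial_dir(self) -> np.ndarray:
        return -self.lateral_dir

    @property
    def distal_dir(self) -> np.ndarray:
        """Unit normal of the joint line pointing toward the ankle."""
        lat = self.lateral_dir
        n = np.array([-lat[1], lat[0]])
        if float(np.dot(n, self.ankle_center - self.knee_center)) < 0:
            n = -n
        return n


def make_leg(varus_angle: float, femoral_length: float, tibial_length: float,
             plateau_width: float, side: str = "right") -> LegGeometry:
    """Embed printed descriptors into canonical coordinates.

    Knee at the origin, joint line horizontal, femoral mechanical axis
    vertical (hip straight above the knee).  The ankle sits at
    ``tibial_length`` from the knee, rotated medially from vertical by
    ``varus_angle`` so that for varus > 0 the Mikulicz line crosses the
    plateau medial of its centre.  For a right leg +x is lateral; a left
    leg is the mirror image (+x medial), so mirrored anatomy round-trips
    through the same code paths.
    """
    if femoral_length <= 0 or tibial_length <= 0 or plateau_width <= 0:
        raise InvalidLegError("lengths and plateau width must be positive")
    if abs(varus_angle) >= 45.0:
        raise InvalidLegError("|varus_angle| must be < 45 degrees")

    lat = 1.0 if side == "right" else -1.0
    v = math.radians(varus_angle)
    leg = LegGeometry(
        side=side,
        hip_center=np.array([0.0, femoral_length]),
        knee_center=np.array([0.0, 0.0]),
        # medial is -x*lat; varus tilts the ankle medially
        ankle_center=np.array([-lat * tibial_length * math.sin(v),
                               -tibial_length * math.cos(v)]),
        plateau_medial=np.array([-lat * plateau_width / 2.0, 0.0]),
        plateau_lateral=np.array([lat * plateau_width / 2.0, 0.0]),
    )
    return leg


def mfta(leg: LegGeometry) -> float:
    """Mechanical femorotibial angle in degrees, varus positive.

    Unsigned angle between the hip->knee and knee->ankle axes, signed by
    whether the tibial axis deviates medially (varus) or laterally
    (valgus) from the femoral axis extension.
    """
    u = leg.knee_center - leg.hip_center
    w = leg.ankle_center - leg.knee_center
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise DegenerateGeometryError("zero-length mechanical axis")
    ang = math.degrees(math.atan2(abs(_cross(u, w)), float(np.dot(u, w))))
    # component of the tibial axis perpendicular to the femoral axis
    perp = w - u * (float(np.dot(w, u)) / float(np.dot(u, u)))
    s = float(np.dot(perp, leg.medial_dir))
    if abs(s) < 1e-12 * nw:
        return 0.0 if ang < 1e-9 else ang  # collinear (or exactly in-plane)
    return math.copysign(ang, s)


def wbl_fraction(leg: LegGeometry) -> float:
    """Fraction of plateau width at which the Mikulicz line crosses the joint line.

    The hip-to-ankle line is intersected with the *infinite* joint line;
    the parameter is 0 at the medial edge and 1 at the lateral edge and
    may fall outside [0, 1] in severe deformity.
    """
    d = leg.plateau_lateral - leg.plateau_medial          # joint line direction
    m = leg.ankle_center - leg.hip_center                 # Mikulicz direction
    denom = _cross(d, m)
    if abs(denom) < 1e-12 * np.linalg.norm(d) * max(np.linalg.norm(m), 1.0):
        raise DegenerateGeometryError("Mikulicz line parallel to the joint line")
    t = _cross(leg.hip_center - leg.plateau_medial, m) / denom
    return float(t)


def mirrored(leg: LegGeometry) -> LegGeometry:
    """Mirror the limb about the vertical axis (left <-> right)."""
    flip = np.array([-1.0, 1.0])
    return replace(
        leg,
        side="left" if leg.side == "right" else "right",
        hip_center=leg.hip_center * flip,
        knee_center=leg.knee_center * flip,
        ankle_center=leg.ankle_center * flip,
        plateau_medial=leg.plateau_medial * flip,
        plateau_lateral=leg.plateau_lateral * flip,
    )


def transformed(leg: LegGeometry, rotation_deg: float = 0.0,
                translation=(0.0, 0.0)) -> LegGeometry:
    """Apply a rigid rotation (about the origin) plus translation.

    Alignment measures are invariant under this map; it exists so that
    invariance is testable, and to re-pose a limb for plotting.
    """
    th = math.radians(rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    tr = _pt(translation)

    def f(p: np.ndarray) -> np.ndarray:
        return rot @ p + tr

    return replace(
        leg,
        hip_center=f(leg.hip_center),
        knee_center=f(leg.knee_center),
        ankle_center=f(leg.ankle_center),
        plateau_medial=f(leg.plateau_medial),
        plateau_lateral=f(leg.plateau_lateral),
    )
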