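"""Opening-wedge osteotomy planning core.

Planning one knee proceeds exactly as on a digital long-leg radiograph:

1. pick the medial entry (saw) point on the medial cortex, 3 or 4 cm
   distal to the medial plateau edge;
2. pick the lateral hinge 5/10/15 mm medial to the lateral cortical
   wall, at the level of the proximal tibiofibular joint (modelled as a
   fixed, configurable depth below the joint line);
3. rotate the distal fragment -- in this model, the ankle centre, the
   only distal landmark that matters for alignment -- rigidly about the
   hinge until the weight-bearing line crosses the plateau at the target
   fraction (default 55% from the medial edge, the classic slight
   lateral overcorrection target);
4. read off the wedge: the medial opening is the chord swept by the
   entry point, ``w = 2 L sin(alpha/2)`` with ``L`` the osteotomy length
   (entry to hinge) and ``alpha`` the correction angle.

The correction angle is solved by bracketing/bisection (Brent) on the
post-rotation WBL fraction; every emitted plan is re-checked to satisfy
the fixed point ``wbl_fraction(rotated leg) == target`` to 1e-8.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .leg_model import (
    DegenerateGeometryError,
    LegGeometry,
    wbl_fraction,
)

__all__ = [
    "PlannerConfig",
    "OsteotomyPlan",
    "PlanningError",
    "NoSolutionError",
    "AlreadyCorrectedWarning",
    "hinge_point",
    "medial_entry",
    "rotate_about",
    "rotate_distal",
    "solve_correction_angle",
    "wedge_width",
    "plan_osteotomy",
    "apply_wedge",
    "condition_label",
]

HINGE_LETTER = {5.0: "A", 10.0: "B", 15.0: "C"}


class PlanningError(RuntimeError):
    """Base class for planning failures."""


class NoSolutionError(PlanningError):
    """No correction angle in the search bracket reaches the target."""


class AlreadyCorrectedWarning(UserWarning):
    """The limb is already at or lateral to the target fraction."""


@dataclass(frozen=True)
class PlannerConfig:
    """Tunable planning parameters.

    target_fraction   WBL target as fraction of plateau width from medial.
    hinge_depth_mm    hinge level below the joint line; stands in for the
                      tip of the fibular head.  Results are first-order
                      insensitive to it (enters L at < 2%).
    cortex_flare_deg  inclination of the modelled medial cortex; 0 keeps
                      it parallel to the tibial mechanical axis.
    saw_kerf_mm       additive allowance for the saw cut; 0 = ignored.
    solver_tol_rad    bisection tolerance on the correction angle.
    max_angle_deg     upper bracket for the correction angle search.
    strict            raise instead of warn when no varus is left to correct.
    """

    target_fraction: float = 0.55
    hinge_depth_mm: float = 15.0
    cortex_flare_deg: float = 0.0
    saw_kerf_mm: float = 0.0
    solver_tol_rad: float = 1e-13
    max_angle_deg: float = 45.0
    strict: bool = False


@dataclass(frozen=True)
class OsteotomyPlan:
    """One planning solution for one knee and one condition."""

    entry_point: np.ndarray
    hinge_point: np.ndarray
    osteotomy_length: float          # L, mm
    correction_angle: float          # alpha, degrees (>= 0 for valgisation)
    wedge_width: float               # w, mm (chord + optional kerf)
    target_fraction: float
    achieved_fraction: float
    condition_label: str


def hinge_point(leg: LegGeometry, dist_from_lateral: float,
                hinge_depth: float = 15.0) -> np.ndarray:
    """Hinge location: ``dist_from_lateral`` medial to the lateral cortical
    wall, ``hinge_depth`` below the joint line."""
    if not 0.0 < dist_from_lateral < leg.plateau_width:
        raise PlanningError(
            f"hinge offset {dist_from_lateral} mm outside the plateau "
            f"(width {leg.plateau_width:.1f} mm)")
    if hinge_depth < 0:
        raise PlanningError("hinge depth must be >= 0")
    return (leg.plateau_lateral
            + dist_from_lateral * leg.medial_dir
            + hinge_depth * leg.distal_dir)


def medial_entry(leg: LegGeometry, height_below_plateau: float,
                 cortex_flare_deg: float = 0.0) -> np.ndarray:
    """Saw entry point on the medial cortex, ``height_below_plateau`` distal
    to the medial plateau edge.  A positive flare angle tilts the modelled
    cortex outward (medially) as it descends."""
    if height_below_plateau <= 0:
        raise PlanningError("osteotomy height must be > 0")
    medial_shift = height_below_plateau * math.tan(math.radians(cortex_flare_deg))
    return (leg.plateau_medial
            + height_below_plateau * leg.distal_dir
            + medial_shift * leg.medial_dir)


def rotate_about(point: np.ndarray, center: np.ndarray,
                 angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    d = point - center
    return center + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def _valgus_sign(leg: LegGeometry, hinge: np.ndarray) -> float:
    """Rotation sense (about ``hinge``) that lateralises the WBL crossing."""
    eps = 1e-6
    base = wbl_fraction(leg)
    up = wbl_fraction(rotate_distal(leg, hinge, eps))
    return 1.0 if up > base else -1.0


def rotate_distal(leg: LegGeometry, hinge: np.ndarray,
                  angle_rad: float) -> LegGeometry:
    """Rigidly rotate the distal fragment (ankle centre) about the hinge."""
    return replace(leg, ankle_center=rotate_about(leg.ankle_center, hinge, angle_rad))


def solve_correction_angle(leg: LegGeometry, hinge: np.ndarray,
                           target_fraction: float = 0.55,
                           config: PlannerConfig | None = None) -> float:
    """Correction angle (degrees) putting the WBL at ``target_fraction``.

    Unique alpha in [0, max_angle] such that after rigid rotation of the
    distal fragment about the hinge the Mikulicz line crosses the joint
    line at the target.  Bracketing/bisection (Brent) on the fraction
    residual; monotone in alpha over the bracket for any varus limb.
    """
    cfg = config or PlannerConfig()
    sgn = _valgus_sign(leg, hinge)

    def resid(alpha_rad: float) -> float:
        return wbl_fraction(rotate_distal(leg, hinge, sgn * alpha_rad)) - target_fraction

    f0 = resid(0.0)
    if f0 >= 0.0:
        msg = (f"WBL already at fraction {f0 + target_fraction:.3f} >= target "
               f"{target_fraction}; no valgisation needed")
        if cfg.strict:
            raise PlanningError(msg)
        if f0 > 0.0:
            warnings.warn(msg, AlreadyCorrectedWarning)
        return 0.0
    hi = math.radians(cfg.max_angle_deg)
    if resid(hi) < 0.0:
        raise NoSolutionError(
            f"no correction angle in [0, {cfg.max_angle_deg}] deg reaches "
            f"fraction {target_fraction}")
    alpha = brentq(resid, 0.0, hi, xtol=cfg.solver_tol_rad, maxiter=200)
    return math.degrees(alpha)


def wedge_width(L: float, alpha_deg: float) -> float:
    """Chord opening at the medial entry: ``2 L sin(alpha/2)``."""
    if L < 0:
        raise PlanningError("osteotomy length must be >= 0")
    if not 0.0 <= alpha_deg < 180.0:
        raise PlanningError("correction angle must be in [0, 180) degrees")
    return 2.0 * L * math.sin(math.radians(alpha_deg) / 2.0)


def condition_label(height_mm: float, dist_from_lateral: float) -> str:
    letter = HINGE_LETTER.get(float(dist_from_lateral))
    if letter is not None and float(height_mm) in (30.0, 40.0):
        return f"{height_mm / 10:g}cm-{letter}"
    return f"h{height_mm:g}mm-d{dist_from_lateral:g}mm"


def plan_osteotomy(leg: LegGeometry, height_below_plateau: float,
                   dist_from_lateral: float,
                   config: PlannerConfig | None = None) -> OsteotomyPlan:
    """Full planning pipeline for one knee under one condition."""
    cfg = config or PlannerConfig()
    entry = medial_entry(leg, height_below_plateau, cfg.cortex_flare_deg)
    hinge = hinge_point(leg, dist_from_lateral, cfg.hinge_depth_mm)
    alpha = solve_correction_angle(leg, hinge, cfg.target_fraction, cfg)
    L = float(np.linalg.norm(entry - hinge))
    w = wedge_width(L, alpha) + cfg.saw_kerf_mm

    sgn = _valgus_sign(leg, hinge)
    achieved = wbl_fraction(rotate_distal(leg, hinge, sgn * math.radians(alpha)))
    if alpha > 0.0 and abs(achieved - cfg.target_fraction) > 1e-8:
        raise PlanningError(
            f"solver fixed-point violated: achieved {achieved!r}, "
            f"target {cfg.target_fraction}")
    return OsteotomyPlan(
        entry_point=entry,
        hinge_point=hinge,
        osteotomy_length=L,
        correction_angle=alpha,
        wedge_width=w,
        target_fraction=cfg.target_fraction,
        achieved_fraction=achieved,
        condition_label=condition_label(height_below_plateau, dist_from_lateral),
    )


def apply_wedge(leg: LegGeometry, height_below_plateau: float,
                dist_from_lateral: float, wedge_mm: float,
                config: PlannerConfig | None = None) -> dict:
    """Execute a *given* wedge width at a (possibly different) hinge.

    Emulates the intraoperative situation where the wedge size from the
    plan is opened at another hinge position: the chord identity is
    inverted to get the achieved angle, the distal fragment is rotated,
    and the achieved WBL fraction and mFTA are reported.
    """
    from .leg_model import mfta as _mfta

    cfg = config or PlannerConfig()
    entry = medial_entry(leg, height_below_plateau, cfg.cortex_flare_deg)
    hinge = hinge_point(leg, dist_from_lateral, cfg.hinge_depth_mm)
    L = float(np.linalg.norm(entry - hinge))
    if wedge_mm < 0 or wedge_mm > 2 * L:
        raise PlanningError("wedge width must be in [0, 2L]")
    alpha = 2.0 * math.asin(wedge_mm / (2.0 * L))
    sgn = _valgus_sign(leg, hinge)
    rotated = rotate_distal(leg, hinge, sgn * alpha)
    return {
        "osteotomy_length": L,
        "correction_angle": math.degrees(alpha),
        "achieved_fraction": wbl_fraction(rotated),
        "achieved_mfta": _mfta(rotated),
    }
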