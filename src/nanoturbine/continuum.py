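"""Continuum electro-hydrodynamic model of a tilted rod in a pore.

A turbine blade is idealized as a rigid cylindrical DNA rod held at an
angle theta from the pore (z) axis in an axial field E_z. Both its
hydrodynamic mobility (velocity per force) and its electrophoretic
mobility (velocity per field) are anisotropic, with ratios

    h = M_h_perp / M_h_par      (slender rod: -> 1/2)
    e = M_el_perp / M_el_par    (0 < e <= ~1, salt dependent)

The in-plane velocity component, obtained by balancing the axial
constraint force so the rod has no net axial motion, is

    v_x = [ (1/2) M_el_par E_z sin(2 theta) / (cos^2 theta + h sin^2 theta) ] (h - e)

so the sign of v_x — the rotation direction — is set by sign(sin 2theta)
times sign(h - e). Because e grows with ionic strength (≈0.38 at 4 mM up
to ≈1 at 2.6 M NaCl) while h stays at 1/2, raising the salt concentration
past the e = h crossover reverses the rotation direction of a turbine of
fixed chirality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "MobilitySet",
    "RodConfiguration",
    "BladeGeometry",
    "in_plane_velocity",
    "oracle_velocity",
    "rotation_direction",
    "crossover_anisotropy",
    "slender_rod_mobility_ratio",
    "interp_e_ratio",
    "predict_reversal_salt",
    "blade_angle_from_twist",
    "DEFAULT_E_ANCHORS",
]

#: (ionic strength mol/L, e ratio) anchors: e ≈ 0.38 at 4 mM, ≈ 1 at 2.6 M NaCl
DEFAULT_E_ANCHORS: tuple[tuple[float, float], ...] = ((0.004, 0.38), (2.6, 1.0))


@dataclass(frozen=True)
class MobilitySet:
    """The four rod mobilities in any self-consistent unit system."""

    M_h_par: float = 2.0
    M_h_perp: float = 1.0
    M_el_par: float = 1.0
    M_el_perp: float = 0.38

    def __post_init__(self) -> None:
        if min(self.M_h_par, self.M_h_perp, self.M_el_par, self.M_el_perp) <= 0:
            raise ValueError("all mobilities must be positive")

    @property
    def h(self) -> float:
        """Hydrodynamic anisotropy ratio M_h_perp/M_h_par (slender rod: 0.5)."""
        return self.M_h_perp / self.M_h_par

    @property
    def e(self) -> float:
        """Electrophoretic anisotropy ratio M_el_perp/M_el_par."""
        return self.M_el_perp / self.M_el_par

    @staticmethod
    def from_ratios(h: float = 0.5, e: float = 0.38, M_el_par: float = 1.0) -> "MobilitySet":
        return MobilitySet(M_h_par=1.0, M_h_perp=h, M_el_par=M_el_par, M_el_perp=e * M_el_par)


@dataclass(frozen=True)
class RodConfiguration:
    """Tilt theta (rad, from the z axis, |theta| <= pi/2) and axial field."""

    theta: float
    E_z: float = 1.0

    def __post_init__(self) -> None:
        if not (-math.pi / 2 <= self.theta <= math.pi / 2):
            raise ValueError("theta must lie in [-pi/2, pi/2]")


@dataclass(frozen=True)
class BladeGeometry:
    """Blade helix geometry: signed twist density (deg/bp), helical rise
    (nm/bp) and the outer radius (nm) at which the blade edge runs."""

    twist_per_bp: float
    outer_radius: float = 12.5
    rise_per_bp: float = 0.34

    def __post_init__(self) -> None:
        if self.rise_per_bp <= 0:
            raise ValueError("rise_per_bp must be positive")
        if self.outer_radius <= 0:
            raise ValueError("outer_radius must be positive")


def in_plane_velocity(config: RodConfiguration, mob: MobilitySet) -> float:
    """Closed-form in-plane velocity of the constrained tilted rod.

    Returned in units of M_el_par * E_z (the expression is scale-free in
    the remaining mobilities).
    """
    th = config.theta
    h = mob.h
    denom = math.cos(th) ** 2 + h * math.sin(th) ** 2
    return (
        0.5 * mob.M_el_par * config.E_z * math.sin(2.0 * th) / denom * (h - mob.e)
    )


def oracle_velocity(config: RodConfiguration, mob: MobilitySet) -> float:
    """Independent force-balance evaluation of the same quantity.

    Builds the full mobility tensors M = M_par u u^T + M_perp (I - u u^T)
    with u = (sin theta, 0, cos theta), applies the axial field, and
    solves for the axial constraint force F = F z_hat that makes v_z = 0
    (the rod is held at fixed height, free to move in x). Used as a test
    oracle for ``in_plane_velocity``; kept deliberately tensor-form.
    """
    th = config.theta
    u = np.array([math.sin(th), 0.0, math.cos(th)])
    eye = np.eye(3)
    uu = np.outer(u, u)
    M_h = mob.M_h_par * uu + mob.M_h_perp * (eye - uu)
    M_el = mob.M_el_par * uu + mob.M_el_perp * (eye - uu)
    E = np.array([0.0, 0.0, config.E_z])
    if M_h[2, 2] == 0.0:
        raise ValueError("singular axial constraint (no axial hydrodynamic mobility)")
    F_z = -(M_el @ E)[2] / M_h[2, 2]
    v = M_el @ E + M_h @ np.array([0.0, 0.0, F_z])
    return float(v[0])


def rotation_direction(blade_angle_sign: float, mob: MobilitySet) -> str:
    """Predicted rotation direction, viewed from the cis side.

    The blade-angle sign is identified with the sign of the rod tilt
    theta; a representative |theta| = 35 deg is used (the result only
    depends on the signs). Returns "anticlockwise", "clockwise" or
    "none" (exact crossover e = h or untilted blades).
    """
    s = np.sign(blade_angle_sign)
    if s == 0:
        return "none"
    v = in_plane_velocity(
        RodConfiguration(theta=float(s) * math.radians(35.0)), mob
    )
    if v > 0:
        return "anticlockwise"
    if v < 0:
        return "clockwise"
    return "none"


def crossover_anisotropy(mob: MobilitySet | None = None) -> float:
    """The electrophoretic anisotropy e* at which v_x changes sign: e* = h."""
    return (mob or MobilitySet()).h


def _tirado_translation_corrections(p: float) -> tuple[float, float]:
    # end-correction terms of the slender-rod translational drag
    nu_par = -0.207 + 0.980 / p - 0.133 / p**2
    nu_perp = 0.839 + 0.185 / p + 0.233 / p**2
    return nu_par, nu_perp


def slender_rod_mobility_ratio(aspect_ratio: float) -> float:
    """Hydrodynamic anisotropy h = M_h_perp/M_h_par of a rod of aspect
    ratio p = L/d, from the slender-rod translational drag coefficients
    with end corrections:

        gamma_par  = 2 pi eta L / (ln p + nu_par(p))
        gamma_perp = 4 pi eta L / (ln p + nu_perp(p))

    so h = gamma_par/gamma_perp = (ln p + nu_perp) / (2 (ln p + nu_par)),
    which tends to 1/2 from above as p -> infinity ("a rod moves twice as
    fast along its length as perpendicular to it").
    """
    p = float(aspect_ratio)
    if p <= 1:
        raise ValueError("aspect ratio must exceed 1")
    nu_par, nu_perp = _tirado_translation_corrections(p)
    num = math.log(p) + nu_perp
    den = math.log(p) + nu_par
    if den <= 0:
        raise ValueError("aspect ratio too small for the slender-rod expansion")
    return num / (2.0 * den)


def _log_interpolator(anchors) -> PchipInterpolator:
    arr = np.asarray(anchors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need at least 2 (ionic strength, e) anchors")
    I, e = arr[:, 0], arr[:, 1]
    if np.any(I <= 0):
        raise ValueError("ionic strengths must be positive")
    if np.any(np.diff(I) <= 0):
        raise ValueError("anchors must have strictly increasing ionic strength")
    return PchipInterpolator(np.log(I), e, extrapolate=False)


def interp_e_ratio(I: float, anchors=DEFAULT_E_ANCHORS) -> float:
    """Electrophoretic anisotropy e at ionic strength I (mol/L).

    Monotone (PCHIP) interpolation in log(I) through the anchor table,
    clamped to the end values outside the anchor range. The default
    anchors are the two measured points (0.38 at 4 mM, 1.0 at 2.6 M).
    """
    if I <= 0:
        raise ValueError("ionic strength must be positive")
    arr = np.asarray(anchors, dtype=float)
    interp = _log_interpolator(arr)
    lo, hi = arr[0], arr[-1]
    if I <= lo[0]:
        return float(lo[1])
    if I >= hi[0]:
        return float(hi[1])
    return float(interp(math.log(I)))


def predict_reversal_salt(anchors=DEFAULT_E_ANCHORS, h: float = 0.5) -> float:
    """Ionic strength (mol/L) at which e(I) crosses h, i.e. where the
    predicted rotation direction reverses. Root of the same interpolant
    used by interp_e_ratio; raises if e - h does not change sign over
    the anchor range."""
    arr = np.asarray(anchors, dtype=float)
    _ = _log_interpolator(arr)  # validates
    f = lambda logI: interp_e_ratio(math.exp(logI), anchors) - h
    a, b = math.log(arr[0, 0]), math.log(arr[-1, 0])
    fa, fb = f(a), f(b)
    if fa == 0:
        return float(arr[0, 0])
    if fb == 0:
        return float(arr[-1, 0])
    if fa * fb > 0:
        raise ValueError("e(I) does not cross h within the anchor range")
    return float(math.exp(brentq(f, a, b, xtol=1e-12)))


def blade_angle_from_twist(geom: BladeGeometry) -> float:
    """Outer blade angle (deg, signed) from the twist density.

    One base pair advances the helix by rise_per_bp along the axis while
    the outer edge moves outer_radius * twist (rad) azimuthally; the
    blade angle to the helical axis is the arctangent of their ratio.
    A right-handed (negative) twist gives a negative blade angle.
    """
    twist_rad = math.radians(geom.twist_per_bp)
    return math.degrees(
        math.atan(geom.outer_radius * twist_rad / geom.rise_per_bp)
    )
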