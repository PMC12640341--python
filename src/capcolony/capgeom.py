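"""Spherical-cap geometry of the colony.

The colony is modelled as a spherical cap sitting on the plate: the
intersection of a sphere of radius ``R`` (the "greater sphere") with the plane
``z = 0``, characterized by the circle-of-intersection radius ``r_base`` and
the apex height ``h``. A single pair of formulas covers both flat (h ≤ r_base)
and bulging (h > r_base) caps:

    V = (π/6)·(h³ + 3·h·r_base²)
    R = (r_base² + h²)/(2h)

These are algebraically identical to the piecewise minor/major-cap expressions
(the major-cap branch is the full sphere minus the complementary minor cap);
the unified form avoids a branch discontinuity at h = r_base.

Cell counts map to geometry through packing efficiencies: the basal layer of
``N_L1`` cells is a circle of area ``N_L1·F_2D·π·r_C²``, and ``N_TOT`` cells
occupy volume ``N_TOT·F_3D·(4/3)π·r_C³`` with ``F_3D = F_2D^(3/2)`` unless
overridden.

Shape observables: Ω = h/R (1 = hemisphere, → 2 = detached sphere) and the
receding contact angle θ between plate and colony edge (degrees).

Units are fixed package-wide: μm, min, degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import SolverError

__all__ = [
    "PackingModel",
    "SphericalCap",
    "layer_radius",
    "colony_volume",
    "cap_volume",
    "cap_sphere_radius",
    "solve_cap_height",
    "cap_base_from_sphere",
    "upper_cap",
    "interior_cap",
    "shape_parameter",
    "contact_angle",
    "midsection_profile",
]


@dataclass(frozen=True)
class PackingModel:
    """Cell radius and packing efficiencies.

    ``f_3d`` defaults to ``f_2d**1.5`` (close-packing geometry of imperfectly
    packed spheres); pass it explicitly to override.
    """

    r_c: float = 1.0
    f_2d: float = 1.2
    f_3d: Optional[float] = None

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError(f"r_c must be positive, got {self.r_c}")
        if self.f_2d <= 0:
            raise ValueError(f"f_2d must be positive, got {self.f_2d}")
        if self.f_3d is None:
            object.__setattr__(self, "f_3d", self.f_2d ** 1.5)
        elif self.f_3d <= 0:
            raise ValueError(f"f_3d must be positive, got {self.f_3d}")

    @property
    def cell_volume(self) -> float:
        """Effective volume one cell occupies in the colony, μm³."""
        return self.f_3d * (4.0 / 3.0) * math.pi * self.r_c ** 3

    @property
    def layer_thickness(self) -> float:
        """Height of one packed cell layer, ``2·r_C·√F_2D``, μm."""
        return 2.0 * self.r_c * math.sqrt(self.f_2d)


@dataclass(frozen=True)
class SphericalCap:
    """A resolved spherical cap: base radius, height, and derived quantities."""

    r_base: float
    h: float
    R: float = field(init=False)
    V: float = field(init=False)

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"cap height must be positive, got {self.h}")
        if self.r_base < 0:
            raise ValueError(f"r_base must be non-negative, got {self.r_base}")
        object.__setattr__(self, "R", cap_sphere_radius(self.h, self.r_base))
        object.__setattr__(self, "V", cap_volume(self.h, self.r_base))

    @property
    def omega(self) -> float:
        """Composite shape parameter Ω = h/R."""
        return shape_parameter(self)

    @property
    def theta_deg(self) -> float:
        """Receding contact angle θ in degrees."""
        return contact_angle(self)


def layer_radius(n_l1: float, packing: PackingModel) -> float:
    """Radius of the basal-layer circle holding ``n_l1`` cells, μm.

    The layer area is ``π·r_L1² = N_L1·F_2D·π·r_C²``, hence
    ``r_L1 = r_C·√(N_L1·F_2D)``.
    """
    if n_l1 <= 0:
        raise ValueError(f"n_l1 must be positive, got {n_l1}")
    return packing.r_c * math.sqrt(n_l1 * packing.f_2d)


def colony_volume(n_tot: float, packing: PackingModel) -> float:
    """Total colony volume ``N_TOT·F_3D·(4/3)π·r_C³``, μm³."""
    if n_tot <= 0:
        raise ValueError(f"n_tot must be positive, got {n_tot}")
    return n_tot * packing.cell_volume


def cap_volume(h: float, r_base: float) -> float:
    """Volume of a spherical cap of height ``h`` and base radius ``r_base``.

    Single expression ``(π/6)(h³ + 3·h·r_base²)``, valid for minor and major
    caps alike.
    """
    if h < 0 or r_base < 0:
        raise ValueError("cap dimensions must be non-negative")
    return (math.pi / 6.0) * (h ** 3 + 3.0 * h * r_base ** 2)


def cap_sphere_radius(h: float, r_base: float) -> float:
    """Greater-sphere radius ``R = (r_base² + h²)/(2h)`` (chord relation)."""
    if h < 0 or r_base < 0:
        raise ValueError("cap dimensions must be non-negative")
    if h == 0:
        raise ValueError("undefined curvature: cap height is zero")
    return (r_base ** 2 + h ** 2) / (2.0 * h)


def solve_cap_height(V: float, r_base: float, *, rtol: float = 1e-12,
                     max_iter: int = 200) -> float:
    """Invert :func:`cap_volume` for the height at fixed base radius.

    ``(π/6)(h³ + 3hr²)`` is strictly increasing in ``h``, so the root is
    unique. Safeguarded Newton iteration on the monotone cubic with a
    bisection fallback; bracket ``[0, (6V/π)^(1/3) + 2r]``.
    """
    if V <= 0:
        raise ValueError(f"V must be positive, got {V}")
    if r_base <= 0:
        raise ValueError(f"r_base must be positive, got {r_base}")

    c = 6.0 * V / math.pi  # solve h³ + 3r²h = c
    r2 = r_base * r_base
    lo, hi = 0.0, c ** (1.0 / 3.0) + 2.0 * r_base
    # start from whichever single-term limit dominates
    h = min(c ** (1.0 / 3.0), c / (3.0 * r2))
    for _ in range(max_iter):
        f = h * (h * h + 3.0 * r2) - c
        if f > 0:
            hi = h
        else:
            lo = h
        df = 3.0 * (h * h + r2)
        step = f / df
        h_new = h - step
        if not lo < h_new < hi:  # Newton left the bracket: bisect
            h_new = 0.5 * (lo + hi)
        if abs(h_new - h) <= rtol * max(abs(h_new), 1e-300):
            return h_new
        h = h_new
    raise SolverError(
        "cap height inversion did not converge",
        V=V, r_base=r_base, last_h=h, bracket=(lo, hi), max_iter=max_iter,
    )


def cap_base_from_sphere(R: float, h: float) -> float:
    """Base radius ``√(R² − (R − h)²)`` of a cap of height ``h`` cut from a sphere of radius ``R``."""
    if R <= 0:
        raise ValueError(f"R must be positive, got {R}")
    if not 0.0 < h <= 2.0 * R:
        raise ValueError(f"h must lie in (0, 2R], got h={h} with R={R}")
    return math.sqrt(max(R * R - (R - h) ** 2, 0.0))


def upper_cap(colony: SphericalCap, packing: PackingModel) -> Optional[SphericalCap]:
    """Geometric upper sub-cap: the colony above the basal cell layer.

    The basal layer is one packed cell layer thick (``2·r_C·√F_2D``); the
    upper cap is cut from the same greater sphere at the reduced height
    ``h′ = h_COL − 2·r_C·√F_2D`` with base radius ``r′ = √(R² − (R − h′)²)``.
    Returns ``None`` for monolayer colonies (``h′ ≤ 0``), a well-defined empty
    cap so the monolayer→multilayer transition stays continuous.
    """
    h_red = colony.h - packing.layer_thickness
    if h_red <= 0.0:
        return None
    r_red = cap_base_from_sphere(colony.R, h_red)
    return SphericalCap(r_base=r_red, h=h_red)


def interior_cap(colony: SphericalCap, packing: PackingModel) -> Optional[SphericalCap]:
    """Interior sub-cap of the upper cap: eroded by one cell radius on all sides.

    Reduced height ``h″ = h_COL − 2·r_C·√F_2D − r_C`` on a shrunken sphere
    ``R″ = R − r_C``; ``None`` when the colony is too thin or small to hold
    any fully-interior upper-cap cells.
    """
    h_red = colony.h - packing.layer_thickness - packing.r_c
    R_red = colony.R - packing.r_c
    if h_red <= 0.0 or R_red <= 0.0:
        return None
    h_red = min(h_red, 2.0 * R_red)  # erosion cannot exceed the shrunken sphere
    r_red = cap_base_from_sphere(R_red, h_red)
    return SphericalCap(r_base=r_red, h=h_red)


def shape_parameter(cap: SphericalCap) -> float:
    """Ω = h/R; 1 for a hemisphere, approaching 2 for a near-detached sphere."""
    return cap.h / cap.R


def contact_angle(cap: SphericalCap) -> float:
    """Receding contact angle θ in degrees between plate and colony edge.

    θ = 90° − asin((R − h)/R) for flat caps (h ≤ R) and
    θ = 90° + acos(r_base/R) for bulging caps (h > R); both give 90° at the
    hemisphere so the function is continuous and increasing in h.
    """
    if cap.h <= cap.R:
        arg = min(max((cap.R - cap.h) / cap.R, -1.0), 1.0)
        return 90.0 - math.degrees(math.asin(arg))
    arg = min(max(cap.r_base / cap.R, -1.0), 1.0)
    return 90.0 + math.degrees(math.acos(arg))


def midsection_profile(cap: SphericalCap, n_points: int) -> np.ndarray:
    """Central midsection outline of the cap as an ``(n_points, 2)`` array of (x, z), μm.

    The outline is the circular arc of radius ``R`` centred at ``(0, h − R)``,
    sampled uniformly in arc angle from one base point ``(−r_base, 0)`` over
    the apex ``(0, h)`` to the other ``(+r_base, 0)``. Angle sampling (rather
    than sampling in x) keeps bulging caps (h > R) single-valued along the
    arc and pins the endpoints to the plate.
    """
    if n_points < 3:
        raise ValueError(f"n_points must be at least 3, got {n_points}")
    z_centre = cap.h - cap.R
    # base points sit at polar angle ±alpha from the +z axis of the centre
    alpha = math.acos(min(max(-z_centre / cap.R, -1.0), 1.0))
    angles = np.linspace(-alpha, alpha, n_points)
    x = cap.R * np.sin(angles)
    z = z_centre + cap.R * np.cos(angles)
    z[0] = z[-1] = 0.0  # endpoints on the plate exactly
    np.clip(z, 0.0, None, out=z)
    return np.column_stack([x, z])
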