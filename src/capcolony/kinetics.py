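"""Division/growth kinetics: the lumped rate constant and its directional split.

An isolated cell divides and matures as a first-order process with lumped rate
constant ``k`` (min⁻¹), so a dilute population grows as ``N(t) = N0·exp(k·t)``.
On a plate the rate is partitioned by unitless directional fractions
``f_x = f_y`` (in-plane) and ``f_z`` (vertical), giving aggregate constants

    k_par  = (f_x + f_y)·k        (parallel to the surface)
    k_perp = f_z·k                (perpendicular to the surface)

Contact inhibition enters through the transition parameter ``gamma``: internal
(crowded) cells divide at rate ``gamma·k`` while free-perimeter cells divide at
the full rate. ``gamma = 0`` is complete inhibition, ``gamma = 1`` none; the
complementary inhibition extent is ``beta = 1 − gamma``.

The degree of growth anisotropy is ``Γ = 0.5·k_par/k_perp``: Γ = 1 is
isotropic, Γ > 1 laterally favored, Γ < 1 vertically favored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GrowthRates",
    "build_rates",
    "anisotropy_degree",
    "rate_from_doubling_time",
]

_FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class GrowthRates:
    """Lumped rate constant with its directional decomposition.

    Attributes
    ----------
    k : float
        Lumped division/growth rate constant, min⁻¹.
    f_x, f_y, f_z : float
        Unitless directional fractions; ``f_x = f_y`` and the three sum to 1.
    k_par, k_perp : float
        Aggregate rates parallel / perpendicular to the surface, min⁻¹.
    gamma : float
        Contact-inhibition transition parameter in [0, 1] (1 = no inhibition).
    beta : float
        Complementary inhibition extent, ``1 − gamma``.
    anisotropy : float
        Degree of anisotropy ``Γ = 0.5·k_par/k_perp``; NaN when ``f_z = 0``
        (no vertical growth, curvature of the ratio undefined).
    """

    k: float
    f_x: float
    f_y: float
    f_z: float
    k_par: float
    k_perp: float
    gamma: float
    beta: float
    anisotropy: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        for name in ("f_x", "f_y", "f_z"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if abs(self.f_x - self.f_y) > _FRACTION_TOL:
            raise ValueError(
                f"f_x and f_y must be equal (in-plane symmetry), got {self.f_x} != {self.f_y}"
            )
        if abs(self.f_x + self.f_y + self.f_z - 1.0) > _FRACTION_TOL:
            raise ValueError("directional fractions must sum to 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")


def build_rates(k: float, f_z: float, gamma: float) -> GrowthRates:
    """Construct :class:`GrowthRates` from the lumped rate and vertical fraction.

    Parameters
    ----------
    k : float
        Lumped rate constant, min⁻¹; must be positive.
    f_z : float
        Fraction of the rate directed vertically, in [0, 1]; the in-plane
        fractions are ``f_x = f_y = (1 − f_z)/2``.
    gamma : float
        Contact-inhibition transition parameter in [0, 1].
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not 0.0 <= f_z <= 1.0:
        raise ValueError(f"f_z must lie in [0, 1], got {f_z}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    f_xy = (1.0 - f_z) / 2.0
    k_par = (1.0 - f_z) * k
    k_perp = f_z * k
    aniso = 0.5 * k_par / k_perp if k_perp > 0 else math.nan
    return GrowthRates(
        k=k,
        f_x=f_xy,
        f_y=f_xy,
        f_z=f_z,
        k_par=k_par,
        k_perp=k_perp,
        gamma=gamma,
        beta=1.0 - gamma,
        anisotropy=aniso,
    )


def anisotropy_degree(k_par: float, k_perp: float) -> float:
    """Degree of growth anisotropy ``Γ = 0.5·k_par/k_perp``.

    Raises
    ------
    ValueError
        If ``k_perp`` is zero (anisotropy undefined for purely lateral growth)
        or either rate is negative.
    """
    if k_par < 0 or k_perp < 0:
        raise ValueError("rate constants must be non-negative")
    if k_perp == 0:
        raise ValueError("undefined anisotropy: k_perp is zero")
    return 0.5 * k_par / k_perp


def rate_from_doubling_time(t_double: float) -> float:
    """Lumped rate constant ``k = ln 2 / t_double`` (min⁻¹) from a doubling time in min."""
    if t_double <= 0:
        raise ValueError(f"t_double must be positive, got {t_double}")
    return math.log(2.0) / t_double
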