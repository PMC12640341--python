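"""Perimeter/internal partition of the continuous cell populations.

Contact inhibition acts on cells by class: perimeter cells (free boundary)
divide at the full rate, internal cells at the ``gamma``-scaled rate. Three
partitions are needed:

* **basal, in-plane** — annulus estimate from the circle model: of ``N_L1``
  basal cells, roughly ``(2·√(F_2D·N_L1) − 1)/F_2D`` sit in the outermost
  one-cell-wide ring and grow laterally unhindered;
* **basal, vertical** — governed by how much of layer one is covered by layer
  two, through the coverage parameter ``η = 1 − N_L1/N_TOT``: perimeter
  ``(N_L1/2)(1 − η)``, internal ``(N_L1/2)(1 + η)``;
* **upper cap** — interior cells counted from the eroded interior cap volume,
  perimeter cells as the remainder of the upper-cap population.

All counts are continuous (continuum model); no rounding anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .capgeom import PackingModel, SphericalCap, interior_cap, upper_cap

__all__ = [
    "PopulationSplit",
    "basal_inplane_split",
    "basal_vertical_split",
    "upper_cap_split",
]


@dataclass(frozen=True)
class PopulationSplit:
    """A parent population divided into perimeter and internal classes.

    ``eta`` is populated only for the basal vertical split, where it is the
    layer-two coverage parameter in [0, 1].
    """

    per: float
    int_: float
    eta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.per < 0 or self.int_ < 0:
            raise ValueError("population counts must be non-negative")
        if self.eta is not None and not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")

    @property
    def total(self) -> float:
        return self.per + self.int_


def basal_inplane_split(n_l1: float, f_2d: float) -> PopulationSplit:
    """Perimeter/internal partition of the basal layer for lateral growth.

    The one-cell-wide outer annulus of the basal circle holds approximately
    ``(2·√(F_2D·N_L1) − 1)/F_2D`` cells. The estimate is geometric, not an
    exact count, so it is clamped to ``[0, N_L1]``.
    """
    if n_l1 <= 0:
        raise ValueError(f"n_l1 must be positive, got {n_l1}")
    per = (2.0 * (f_2d * n_l1) ** 0.5 - 1.0) / f_2d
    per = min(max(per, 0.0), n_l1)
    return PopulationSplit(per=per, int_=n_l1 - per)


def basal_vertical_split(n_l1: float, n_tot: float) -> PopulationSplit:
    """Perimeter/internal partition of the basal layer for vertical growth.

    A basal cell counts as vertical-perimeter to the extent it is uncovered
    by the layer above: with coverage ``η = 1 − N_L1/N_TOT``,
    ``per = (N_L1/2)(1 − η)`` and ``int = (N_L1/2)(1 + η)``. At zero coverage
    (monolayer, η = 0) the split is exactly half/half.
    """
    if n_l1 <= 0:
        raise ValueError(f"n_l1 must be positive, got {n_l1}")
    if n_l1 > n_tot:
        raise ValueError(f"n_l1 ({n_l1}) exceeds n_tot ({n_tot})")
    eta = 1.0 - n_l1 / n_tot
    eta = min(max(eta, 0.0), 1.0)
    per = 0.5 * n_l1 * (1.0 - eta)
    int_ = 0.5 * n_l1 * (1.0 + eta)
    return PopulationSplit(per=per, int_=int_, eta=eta)


def upper_cap_split(
    colony: SphericalCap,
    packing: PackingModel,
    n_upper: Optional[float] = None,
) -> PopulationSplit:
    """Perimeter/internal partition of the upper-cap population.

    Internal cells are those inside the interior cap (the upper cap eroded by
    one cell radius), counted as its volume over the effective cell volume
    ``(4/3)π·F_3D·r_C³``. Perimeter cells are the remainder of the upper-cap
    population, clamped at zero.

    Parameters
    ----------
    n_upper : float, optional
        Total upper-cap cell count to partition. By default it is derived
        from the geometric reduced-cap volume; the simulator instead passes
        ``N_TOT − N_L1`` so that the partition conserves the bookkeeping
        volume split ``V_COL = V_L1 + V_UC`` exactly (see docs/methods.md).
    """
    cell_vol = packing.cell_volume
    if n_upper is None:
        uc = upper_cap(colony, packing)
        n_upper = uc.V / cell_vol if uc is not None else 0.0
    if n_upper <= 0.0:
        return PopulationSplit(per=0.0, int_=0.0)
    inner = interior_cap(colony, packing)
    n_int = inner.V / cell_vol if inner is not None else 0.0
    n_int = min(n_int, n_upper)
    return PopulationSplit(per=n_upper - n_int, int_=n_int)
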