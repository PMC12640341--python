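"""Deterministic fixture generation for tests and cross-checks.

Emits, into a target directory:

* ``caps.csv`` — random resolved spherical caps (seeded) with their closed-form
  volume and an independently computed brute-force disc-integration volume;
* ``grid/*.yaml`` — the 15 reference run configurations (3 anisotropy regimes
  × 5 contact-inhibition extents).

The disc-integration oracle evaluates ``V = ∫₀ʰ π·(R² − (R − h + z)²) dz``
numerically and is deliberately independent of the closed-form cap formulas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import quad

from .capgeom import cap_sphere_radius, cap_volume
from .simulate import GRID_GAMMAS, GRID_REGIMES

__all__ = ["disc_integral_volume", "random_caps", "make_fixtures"]


def disc_integral_volume(h: float, r_base: float) -> float:
    """Brute-force cap volume by numerical integration of horizontal discs."""
    R = cap_sphere_radius(h, r_base)

    def disc_area(z: float) -> float:
        return np.pi * (R * R - (R - h + z) ** 2)

    value, _ = quad(disc_area, 0.0, h, epsabs=0.0, epsrel=1e-12, limit=200)
    return value


def random_caps(n: int, seed: int = 0) -> pd.DataFrame:
    """``n`` seeded random caps spanning minor and major shapes and 6 decades of scale."""
    rng = np.random.default_rng(seed)
    r_base = 10.0 ** rng.uniform(-3, 3, n)
    # height-to-base ratio spans flat pancakes to near-closed spheres
    h = r_base * 10.0 ** rng.uniform(-2, 2, n)
    rows = []
    for hi, ri in zip(h, r_base):
        rows.append({
            "h_um": hi,
            "r_base_um": ri,
            "R_um": cap_sphere_radius(hi, ri),
            "V_um3": cap_volume(hi, ri),
            "V_disc_integral_um3": disc_integral_volume(hi, ri),
        })
    return pd.DataFrame(rows)


def make_fixtures(out_dir: Union[str, Path], n_caps: int = 200, seed: int = 0) -> Path:
    """Write the fixture set; returns the output directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    random_caps(n_caps, seed=seed).to_csv(out / "caps.csv", index=False)

    grid_dir = out / "grid"
    grid_dir.mkdir(exist_ok=True)
    for regime, f_z in GRID_REGIMES.items():
        for gamma in GRID_GAMMAS:
            cfg = {
                "r_c_um": 1.0,
                "f_2d": 1.2,
                "t_double_min": 90.0,
                "f_z": f_z,
                "gamma": gamma,
                "t_end_min": 3000.0,
                "dt_min": 0.5,
            }
            name = f"{regime}_gamma{gamma:.2f}.yaml"
            (grid_dir / name).write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out
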