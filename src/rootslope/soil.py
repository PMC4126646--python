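"""Soil physical traits: gravimetric water contents, bulk density, shear strength.

Gravimetric properties come from the classical mass balance on a soil
sample weighed fresh (``m_i``), saturated (``m_s``) and oven-dry (``m_d``),
with its volume ``v`` measured by displacement:

    w_i   = 100 (m_i - m_d) / m_d      initial water content, % of dry mass
    w_s   = 100 (m_s - m_d) / m_d      saturated water content, %
    rho_d = m_d / v                    dry bulk density, g cm^-3

Shear strength follows the Mohr-Coulomb failure criterion
``tau = c + sigma tan(phi)``: direct-shear box runs at several normal loads
give (normal stress, peak shear stress) pairs; ordinary least squares on
those points yields the cohesion ``c`` (intercept, kPa) and the angle of
internal friction ``phi`` (degrees, from the slope). The standard shear box
here is 60 mm x 60 mm, so e.g. normal loads of 200/300/500 N map to normal
stresses of 55.56/83.33/138.89 kPa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SoilSample",
    "SoilPhysical",
    "ShearTest",
    "MohrCoulombFit",
    "DEFAULT_BOX_AREA_M2",
    "gravimetric_properties",
    "mohr_coulomb_fit",
    "descriptive_summary",
]

#: Standard direct-shear box footprint: 60 mm x 60 mm.
DEFAULT_BOX_AREA_M2 = 0.06 * 0.06


@dataclass
class SoilSample:
    """Masses (g) of one soil sample (fresh, saturated, dry) and volume (cm³)."""

    m_i: float
    m_s: float
    m_d: float
    v: float

    def __post_init__(self) -> None:
        if self.m_d <= 0:
            raise ValueError("dry mass m_d must be > 0")
        if self.m_i < self.m_d:
            raise ValueError(f"fresh mass m_i ({self.m_i}) < dry mass m_d ({self.m_d})")
        if self.m_s < self.m_i:
            raise ValueError(
                f"saturated mass m_s ({self.m_s}) < fresh mass m_i ({self.m_i})"
            )
        if self.v <= 0:
            raise ValueError("sample volume v must be > 0")


@dataclass
class SoilPhysical:
    w_i: float  # %, initial gravimetric water content
    w_s: float  # %, saturated gravimetric water content
    rho_d: float  # g cm^-3, dry bulk density


def gravimetric_properties(sample: SoilSample) -> SoilPhysical:
    """Initial/saturated gravimetric water content (%) and dry bulk density."""
    return SoilPhysical(
        w_i=100.0 * (sample.m_i - sample.m_d) / sample.m_d,
        w_s=100.0 * (sample.m_s - sample.m_d) / sample.m_d,
        rho_d=sample.m_d / sample.v,
    )


@dataclass
class ShearTest:
    """One direct-shear box run."""

    normal_load: float  # N
    peak_shear_force: float  # N
    box_area: float = DEFAULT_BOX_AREA_M2  # m^2
    site: str = "hotspot"
    horizon: str = "A"

    def __post_init__(self) -> None:
        if min(self.normal_load, self.peak_shear_force, self.box_area) <= 0:
            raise ValueError("normal load, peak shear force and box area must be > 0")

    @property
    def normal_stress_kpa(self) -> float:
        return self.normal_load / self.box_area / 1e3  # N/m^2 -> kPa

    @property
    def shear_stress_kpa(self) -> float:
        return self.peak_shear_force / self.box_area / 1e3


@dataclass
class MohrCoulombFit:
    cohesion: float  # c, kPa
    friction_angle: float  # phi, degrees
    r_squared: float
    n: int

    def predict(self, normal_stress_kpa: float | np.ndarray) -> np.ndarray:
        return self.cohesion + np.asarray(normal_stress_kpa) * math.tan(
            math.radians(self.friction_angle)
        )


def mohr_coulomb_fit(tests: Iterable[ShearTest]) -> MohrCoulombFit:
    """OLS Mohr-Coulomb envelope over (normal stress, peak shear stress) pairs.

    Requires at least two distinct normal stresses. A negative intercept
    (cohesion) is reported as-is with a warning rather than clipped to
    zero, so the caller sees the raw regression.
    """
    tests = list(tests)
    sigma = np.array([t.normal_stress_kpa for t in tests])
    tau = np.array([t.shear_stress_kpa for t in tests])
    if np.unique(sigma).size < 2:
        raise ValueError("Mohr-Coulomb fit needs >= 2 distinct normal stresses")
    res = stats.linregress(sigma, tau)
    phi = math.degrees(math.atan(res.slope))
    if res.intercept < 0:
        warnings.warn(
            f"negative fitted cohesion ({res.intercept:.3g} kPa) reported as-is",
            stacklevel=2,
        )
    return MohrCoulombFit(
        cohesion=float(res.intercept),
        friction_angle=float(phi),
        r_squared=float(res.rvalue**2),
        n=len(tests),
    )


def descriptive_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error, for in-situ vane/penetrometer readings.

    These field readings are descriptive only (no model is fitted to them);
    the pair (mean, s.e.) is what summary tables report.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
    return float(arr.mean()), se
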