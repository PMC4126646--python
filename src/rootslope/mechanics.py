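"""Root mechanical traits from tensile and three-point bending records.

Tensile tests yield the maximal tensile stress ``T_max`` (breaking force /
root cross-sectional area), the ultimate strain ``eps_ult`` (clamp
displacement at break / initial gauge length, in %) and a tensile modulus
from the elastic region of the stress-strain curve.  Across roots of one
species, strength follows a power law in diameter, ``T_max = alpha *
D**-beta``, fitted by ordinary least squares in log-log space so that the
reported R² matches the log-axis presentation conventional in the field.
Positive ``beta`` means thin roots are disproportionately strong; a few
species show the inverse trend (negative ``beta``).

Bending tests on thick roots ("soil nails") yield the flexural modulus E
from the initial load-deflection slope via the three-point relation
``F = 48 E I δ / L³`` and the bending rigidity ``EI = E · I`` with
``I = π w d³ / 64`` for an elliptical section of depth diameter d and width
diameter w.

Specimen validity is enforced throughout: tensile tests must fail in the
middle third of the root without clamp slippage and satisfy a gauge-length
to diameter ratio of at least 30; bending spans must be long relative to
the depth diameter to keep shear contributions negligible. Invalid results
never enter the power-law fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

__all__ = [
    "TensileTest",
    "TensileResult",
    "BendingTest",
    "BendingResult",
    "PowerLawFit",
    "MechanicsConfig",
    "tensile_curve_metrics",
    "fit_tmax_power_law",
    "second_moment_of_inertia",
    "bending_metrics",
]


@dataclass
class MechanicsConfig:
    """Knobs for curve analysis and validity screening.

    elastic_window
        Fraction-of-peak-force band over which the elastic slope is sought.
    drop_fraction
        A break is recognised when force drops below
        ``(1 - drop_fraction) * peak`` after the global maximum.
    tensile_span_ratio_min
        Minimum gauge length / mean diameter (dimensionless); 30 per the
        standard span-test requirement for root tension.
    bending_span_ratio_min
        Minimum span / depth diameter to keep shear deformation negligible
        in three-point bending.
    """

    elastic_window: tuple[float, float] = (0.10, 0.40)
    drop_fraction: float = 0.30
    tensile_span_ratio_min: float = 30.0
    bending_span_ratio_min: float = 20.0


DEFAULT_CONFIG = MechanicsConfig()


@dataclass
class TensileTest:
    """One tensile force-displacement record with specimen metadata.

    ``diameters`` are the three calliper readings (mm) along the root;
    ``curve`` is an (n, 2) array of (displacement mm, force N) with strictly
    increasing displacement.
    """

    root_id: str
    species: str
    diameters: tuple[float, float, float]
    gauge_length: float
    curve: np.ndarray
    site: str = "hotspot"
    depth_layer: int = 0
    sector: str = "up"
    failure_location: str = "middle_third"  # middle_third | outer_third | clamp
    slipped: bool = False
    season_label: str = ""

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.ndim != 2 or self.curve.shape[1] != 2:
            raise ValueError(f"{self.root_id}: curve must be (n, 2)")
        if np.any(np.diff(self.curve[:, 0]) <= 0):
            raise ValueError(f"{self.root_id}: displacement must be strictly increasing")
        if np.any(self.curve[:, 1] < 0):
            raise ValueError(f"{self.root_id}: negative forces")
        if any(d <= 0 for d in self.diameters):
            raise ValueError(f"{self.root_id}: non-positive diameter reading")
        if self.gauge_length <= 0:
            raise ValueError(f"{self.root_id}: non-positive gauge length")

    @property
    def mean_diameter(self) -> float:
        return float(np.mean(self.diameters))


@dataclass
class TensileResult:
    root_id: str
    species: str
    t_max: float  # MPa
    eps_ult: float  # %
    tensile_modulus: float  # MPa (nan if elastic region not resolvable)
    csa: float  # mm^2
    mean_diameter: float  # mm
    valid: bool
    invalid_reasons: frozenset[str] = field(default_factory=frozenset)
    depth_layer: int = 0
    sector: str = "up"
    site: str = "hotspot"


@dataclass
class PowerLawFit:
    """``T_max = alpha * D**-beta`` fitted by log-log OLS."""

    alpha: float  # MPa * mm^beta
    beta: float  # positive: strength decreases with diameter
    r_squared: float
    n: int

    def predict(self, diameter: float | np.ndarray) -> np.ndarray:
        return self.alpha * np.asarray(diameter, dtype=float) ** (-self.beta)


@dataclass
class BendingTest:
    """One three-point bending record: (deflection mm, force N) curve."""

    root_id: str
    species: str
    depth_diameter: float  # d, mm (vertical, along the load)
    width_diameter: float  # w, mm
    span: float  # mm
    curve: np.ndarray
    site: str = "hotspot"
    depth_layer: int = 0
    sector: str = "up"

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.ndim != 2 or self.curve.shape[1] != 2:
            raise ValueError(f"{self.root_id}: curve must be (n, 2)")
        if np.any(np.diff(self.curve[:, 0]) <= 0):
            raise ValueError(f"{self.root_id}: deflection must be strictly increasing")
        if min(self.depth_diameter, self.width_diameter, self.span) <= 0:
            raise ValueError(f"{self.root_id}: non-positive geometry")


@dataclass
class BendingResult:
    root_id: str
    species: str
    second_moment: float  # mm^4
    bending_modulus: float  # MPa
    rigidity: float  # EI, kN*mm^2
    span_ratio: float
    valid: bool
    invalid_reasons: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Curve analysis helpers
# ---------------------------------------------------------------------------


def _find_break(force: np.ndarray, drop_fraction: float) -> int | None:
    """Index of the breaking point, or None when no break is detectable.

    The break is the global force maximum, accepted only when the force
    subsequently drops by at least ``drop_fraction`` of the peak. A record
    that ends while still ascending (or never shows the drop) carries no
    detectable failure.
    """
    i_peak = int(np.argmax(force))
    peak = force[i_peak]
    if peak <= 0:
        return None
    after = force[i_peak + 1 :]
    if after.size and np.min(after) <= (1.0 - drop_fraction) * peak:
        return i_peak
    return None


def _best_linear_slope(
    x: np.ndarray, y: np.ndarray, window: tuple[float, float]
) -> float:
    """Slope of the best-R² linear stretch inside a fraction-of-peak band.

    Candidate points are those with y between ``window[0]`` and
    ``window[1]`` of the global peak, up to and including the peak. A
    sliding window (length between 3 points and the whole band) is scanned
    and the segment with the highest R² wins; perfect fits prefer the
    longest segment.
    """
    i_peak = int(np.argmax(y))
    peak = y[i_peak]
    lo, hi = window[0] * peak, window[1] * peak
    idx = np.flatnonzero((y[: i_peak + 1] >= lo) & (y[: i_peak + 1] <= hi))
    if idx.size < 2:
        return math.nan
    xs, ys = x[idx], y[idx]
    if idx.size == 2:
        return float((ys[1] - ys[0]) / (xs[1] - xs[0]))
    # windowed OLS via prefix sums, vectorized over start positions
    m = idx.size
    csx = np.concatenate(([0.0], np.cumsum(xs)))
    csy = np.concatenate(([0.0], np.cumsum(ys)))
    csxx = np.concatenate(([0.0], np.cumsum(xs * xs)))
    csyy = np.concatenate(([0.0], np.cumsum(ys * ys)))
    csxy = np.concatenate(([0.0], np.cumsum(xs * ys)))
    best_r2, best_len, best_slope = -np.inf, -1, math.nan
    for wlen in range(3, m + 1):
        s = np.arange(0, m - wlen + 1)
        e = s + wlen
        n = float(wlen)
        sx, sy = csx[e] - csx[s], csy[e] - csy[s]
        sxx, syy, sxy = csxx[e] - csxx[s], csyy[e] - csyy[s], csxy[e] - csxy[s]
        vxx = sxx - sx * sx / n
        vyy = syy - sy * sy / n
        vxy = sxy - sx * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = vxy / vxx
            r2 = np.where(vyy > 0, vxy * vxy / (vxx * vyy), 1.0)
        r2 = np.where(vxx > 0, r2, -np.inf)
        j = int(np.argmax(r2))
        # prefer longer windows on (near-)ties so exact lines use all points
        if r2[j] > best_r2 + 1e-12 or (r2[j] > best_r2 - 1e-12 and wlen > best_len):
            best_r2, best_len, best_slope = float(r2[j]), wlen, float(slope[j])
    return best_slope


# ---------------------------------------------------------------------------
# Tension
# ---------------------------------------------------------------------------


def tensile_curve_metrics(
    test: TensileTest, config: MechanicsConfig = DEFAULT_CONFIG
) -> TensileResult:
    """Extract T_max, eps_ult and the tensile modulus from one record.

    The cross-sectional area uses the mean of the three diameter readings
    under a circular-section assumption. Validity flags record clamp or
    outer-third failures, clamp slippage, an insufficient gauge-length to
    diameter ratio, and undetectable breaks; the metrics are still reported
    (at the global force peak) for inspection.
    """
    if len(test.curve) < 3:
        raise ValueError(f"{test.root_id}: curve needs at least 3 points")
    d = test.mean_diameter
    csa = math.pi * d**2 / 4.0
    disp, force = test.curve[:, 0], test.curve[:, 1]

    reasons: set[str] = set()
    i_break = _find_break(force, config.drop_fraction)
    if i_break is None:
        reasons.add("no_break_detected")
        i_break = int(np.argmax(force))
    if test.failure_location != "middle_third":
        reasons.add(f"failure_{test.failure_location}")
    if test.slipped:
        reasons.add("clamp_slippage")
    if test.gauge_length / d < config.tensile_span_ratio_min:
        reasons.add("span_ratio_below_minimum")

    t_max = force[i_break] / csa  # N / mm^2 = MPa
    eps_ult = 100.0 * disp[i_break] / test.gauge_length

    stress = force / csa
    strain = disp / test.gauge_length  # dimensionless
    modulus = _best_linear_slope(strain, stress, config.elastic_window)

    return TensileResult(
        root_id=test.root_id,
        species=test.species,
        t_max=float(t_max),
        eps_ult=float(eps_ult),
        tensile_modulus=float(modulus),
        csa=float(csa),
        mean_diameter=float(d),
        valid=not reasons,
        invalid_reasons=frozenset(reasons),
        depth_layer=test.depth_layer,
        sector=test.sector,
        site=test.site,
    )


def fit_tmax_power_law(results: Iterable[TensileResult]) -> PowerLawFit:
    """Fit ``T_max = alpha * D**-beta`` over the valid results.

    OLS on (log D, log T_max); ``alpha = exp(intercept)``,
    ``beta = -slope`` so that positive beta means strength decreasing with
    diameter. Invalid results are excluded before fitting.
    """
    kept = [r for r in results if r.valid]
    if len(kept) < 3:
        raise ValueError(f"power-law fit needs >= 3 valid results, got {len(kept)}")
    d = np.array([r.mean_diameter for r in kept])
    t = np.array([r.t_max for r in kept])
    if np.any(d <= 0) or np.any(t <= 0):
        raise ValueError("power-law fit requires positive diameters and stresses")
    if np.unique(d).size < 3:
        raise ValueError("power-law fit needs >= 3 distinct diameters")
    res = stats.linregress(np.log(d), np.log(t))
    return PowerLawFit(
        alpha=float(np.exp(res.intercept)),
        beta=float(-res.slope),
        r_squared=float(res.rvalue**2),
        n=len(kept),
    )


# ---------------------------------------------------------------------------
# Bending
# ---------------------------------------------------------------------------


def second_moment_of_inertia(d: float, w: float) -> float:
    """Axial second moment of an elliptical root section, mm^4.

    ``I = pi * w * d**3 / 64`` with d the depth diameter (along the load)
    and w the width diameter; reduces to the circular ``pi d^4/64`` when
    d == w.
    """
    if d < 0 or w < 0:
        raise ValueError("diameters must be non-negative")
    return math.pi * w * d**3 / 64.0


def bending_metrics(
    test: BendingTest, config: MechanicsConfig = DEFAULT_CONFIG
) -> BendingResult:
    """Flexural modulus E and rigidity EI from one three-point bending record.

    The stiffness k (N/mm) is the slope of the initial linear region of the
    load-deflection curve, selected by the same best-R² window as in
    tension; then ``E = k L³ / (48 I)`` (MPa) and ``EI = E·I`` reported in
    kN·mm². A span-to-depth ratio below the configured threshold marks the
    result invalid (shear contamination), as does an unresolvable or
    non-positive initial slope.
    """
    if len(test.curve) < 3:
        raise ValueError(f"{test.root_id}: curve needs at least 3 points")
    inertia = second_moment_of_inertia(test.depth_diameter, test.width_diameter)
    deflection, force = test.curve[:, 0], test.curve[:, 1]

    reasons: set[str] = set()
    span_ratio = test.span / test.depth_diameter
    if span_ratio < config.bending_span_ratio_min:
        reasons.add("span_ratio_below_minimum")

    k = _best_linear_slope(deflection, force, config.elastic_window)
    if not math.isfinite(k) or k <= 0:
        reasons.add("initial_slope_unresolvable")
        modulus = math.nan
        rigidity = math.nan
    else:
        modulus = k * test.span**3 / (48.0 * inertia)  # N/mm^2 = MPa
        rigidity = modulus * inertia / 1e3  # N*mm^2 -> kN*mm^2

    return BendingResult(
        root_id=test.root_id,
        species=test.species,
        second_moment=float(inertia),
        bending_modulus=float(modulus),
        rigidity=float(rigidity),
        span_ratio=float(span_ratio),
        valid=not reasons,
        invalid_reasons=frozenset(reasons),
    )
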