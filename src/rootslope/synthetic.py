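"""Synthetic field records with the statistical structure the analysis assumes.

No raw data from the Yunnan field campaign were published, so every input
record type consumed by the trait pipeline can be simulated here: root
systems bucketed into 10-cm depth layers and up/downslope sectors, tensile
and three-point-bending force-displacement curves, direct-shear box runs,
soil gravimetric samples, quadrat stem counts and per-root chemistry.

Nine species archetypes are shipped, parameterized *qualitatively* from the
study's root-system descriptions (e.g. the deep, densely branched taproot
of Pueraria stricta; the tufted shallow system of Chloris anomala; the
linear underground stem of Agave americana). Their numeric defaults are
fixtures for testing the pipeline, not claims about the real populations.

Statistical choices: root diameters are lognormal (positive, heavy-tailed,
matching log-axis strength plots); tensile strength is a power law in
diameter with multiplicative lognormal noise (log-log residuals
homoskedastic); tensile curves are piecewise — toe (stretching), linear
elastic, linear plastic to break, then a post-break force drop; shear
strength follows Mohr-Coulomb with additive Gaussian noise; quadrat counts
are Poisson.  All generators are deterministic given the config seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .architecture import RootSegment, RootSystem
from .mechanics import BendingTest, TensileTest, second_moment_of_inertia
from .soil import DEFAULT_BOX_AREA_M2, ShearTest, SoilSample

__all__ = [
    "SpeciesArchetype",
    "GeneratorConfig",
    "QuadratRecord",
    "RootChemistryRecord",
    "DEFAULT_ARCHETYPES",
    "generate_root_system",
    "generate_tensile_tests",
    "generate_bending_tests",
    "generate_shear_tests",
    "generate_soil_samples",
    "generate_quadrat_survey",
    "generate_root_chemistry",
]

GROWTH_FORMS = ("herb", "shrub", "creeper", "climber", "tree")


@dataclass(frozen=True)
class SpeciesArchetype:
    """Qualitative per-species generator parameters.

    ``tmax_alpha``/``tmax_beta`` parameterize the strength-diameter power
    law ``T_max = alpha * D**-beta`` (MPa, mm); beta may be negative for
    species whose thick roots are the strong ones. Depth/radius ranges in
    m, diameters lognormal in mm (``diameter_mu`` is the mean of log mm).
    """

    name: str
    growth_form: str
    root_layout: str  # radial | linear
    max_depth_range: tuple[float, float]
    max_radius_range: tuple[float, float]
    diameter_mu: float
    diameter_sigma: float
    tmax_alpha: float
    tmax_beta: float
    eps_ult_mean: float  # %
    n_concentration_mean: float  # % dry mass
    cellulose_mean: float  # % dry mass
    bending_modulus_mean: float = 500.0  # MPa

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(f"{self.name}: unknown growth form {self.growth_form!r}")
        if self.root_layout not in ("radial", "linear"):
            raise ValueError(f"{self.name}: unknown root layout {self.root_layout!r}")
        for rng_ in (self.max_depth_range, self.max_radius_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValueError(f"{self.name}: invalid extent range {rng_}")
        if self.root_layout == "linear" and self.growth_form != "creeper":
            raise ValueError(
                f"{self.name}: linear root layout is reserved for creeping / "
                "underground-stem growth forms"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings; identical configs give identical output."""

    seed: int
    n_plants: int = 6
    n_tensile: int = 50
    n_bending: int = 15
    n_shear: int = 8
    noise_cv: float = 0.2
    site_label: str = "hotspot"  # hotspot | stable
    invalid_fraction: float = 0.0  # fraction of deliberately flawed specimens

    def __post_init__(self) -> None:
        if min(self.n_plants, self.n_tensile, self.n_bending, self.n_shear) < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.site_label not in ("hotspot", "stable"):
            raise ValueError(f"unknown site label {self.site_label!r}")


#: Nine species of the reference study; numeric values are test fixtures
#: chosen to mirror the described root-system morphologies and strength
#: trends, not measurements.
DEFAULT_ARCHETYPES: dict[str, SpeciesArchetype] = {
    a.name: a
    for a in [
        SpeciesArchetype(  # thin roots off a linear underground stem
            "Agave americana", "creeper", "linear", (0.10, 0.30), (0.30, 0.80),
            math.log(1.5), 0.6, 25.0, 0.30, 12.0, 0.8, 15.0, 400.0,
        ),
        SpeciesArchetype(  # a few thin roots from the collar
            "Arthraxon hispidus", "herb", "radial", (0.05, 0.15), (0.05, 0.15),
            math.log(0.3), 0.4, 30.0, 0.70, 20.0, 0.9, 18.0, 200.0,
        ),
        SpeciesArchetype(  # long laterals turning downward
            "Artemisia codonocephala", "herb", "radial", (0.10, 0.30), (0.20, 0.50),
            math.log(0.5), 0.5, 45.0, 0.80, 12.0, 2.2, 25.0, 350.0,
        ),
        SpeciesArchetype(  # long deep densely branched liana roots
            "Bauhinia championii", "climber", "radial", (0.30, 0.60), (0.30, 0.80),
            math.log(1.0), 0.7, 25.0, 0.60, 18.0, 1.4, 17.0, 450.0,
        ),
        SpeciesArchetype(  # tufted and shallow
            "Chloris anomala", "herb", "radial", (0.05, 0.15), (0.05, 0.20),
            math.log(0.35), 0.4, 40.0, 0.80, 13.0, 0.9, 24.0, 250.0,
        ),
        SpeciesArchetype(  # vertical roots off creeping stems; strength rises with D
            "Ficus tikoua", "creeper", "linear", (0.10, 0.30), (0.10, 0.30),
            math.log(0.8), 0.6, 30.0, -0.30, 23.0, 0.9, 24.0, 300.0,
        ),
        SpeciesArchetype(  # taproot; weak fine roots, strength rises with D
            "Jatropha curcas", "shrub", "radial", (0.20, 0.40), (0.20, 0.40),
            math.log(1.2), 0.6, 8.0, -0.40, 12.0, 0.9, 26.0, 500.0,
        ),
        SpeciesArchetype(  # deep densely branched taproot, very strong fine roots
            "Pueraria stricta", "shrub", "radial", (0.40, 0.70), (0.20, 0.50),
            math.log(0.7), 0.7, 58.0, 0.54, 10.0, 2.0, 14.0, 700.0,
        ),
        SpeciesArchetype(  # sprouting, long deep scarcely branched roots
            "Rhus chinensis", "tree", "radial", (0.30, 0.60), (0.30, 0.70),
            math.log(1.3), 0.6, 10.0, 0.40, 17.0, 1.3, 12.0, 600.0,
        ),
    ]
}

# independent, reproducible RNG streams per generator and archetype
_STREAMS = {
    "root_system": 1,
    "tensile": 2,
    "bending": 3,
    "shear": 4,
    "soil": 5,
    "quadrat": 6,
    "chemistry": 7,
}


def _rng(config: GeneratorConfig, stream: str, *extra: int | str) -> np.random.Generator:
    keys = [int(config.seed), _STREAMS[stream]]
    for e in extra:
        keys.append(zlib.crc32(str(e).encode()) if isinstance(e, str) else int(e))
    return np.random.default_rng(keys)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit median and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(0.0, sigma, size=size)


# ---------------------------------------------------------------------------
# Root systems
# ---------------------------------------------------------------------------


def generate_root_system(
    archetype: SpeciesArchetype, config: GeneratorConfig, plant_index: int = 0
) -> RootSystem:
    """Draw one plant's root system from a species archetype.

    Extents are uniform within the archetype ranges; per (sector, layer)
    segment counts decay exponentially with depth (root density
    concentrates near the surface); segment diameters are lognormal and
    lengths gamma-distributed. Linear-layout archetypes carry a measured
    along-stem extent so the cylinder ISV model applies downstream.
    """
    rng = _rng(config, "root_system", archetype.name, plant_index)
    lo_d, hi_d = archetype.max_depth_range
    lo_r, hi_r = archetype.max_radius_range
    max_depth = rng.uniform(lo_d, hi_d)
    r_up = rng.uniform(lo_r, hi_r)
    r_down = rng.uniform(lo_r, hi_r)
    stem_length = None
    if archetype.root_layout == "linear":
        stem_length = rng.uniform(2.0 * lo_r, 2.0 * hi_r)
    collar = 0.5 * _lognormal_factor(rng, 0.3)  # cm

    plant_id = f"{archetype.name.replace(' ', '_')}_{config.site_label}_{plant_index}"
    n_layers = max(1, math.ceil(max_depth / 0.10))
    segments: list[RootSegment] = []
    for sector in ("up", "down"):
        for layer in range(n_layers):
            mean_count = 8.0 * math.exp(-0.6 * layer)
            count = int(rng.poisson(mean_count)) + (1 if layer == 0 else 0)
            diam = np.exp(
                rng.normal(archetype.diameter_mu, archetype.diameter_sigma, count)
            )
            length = rng.gamma(2.0, 40.0, count)  # mm
            for d, ln in zip(diam, length):
                segments.append(
                    RootSegment(
                        species=archetype.name,
                        plant_id=plant_id,
                        depth_layer=layer,
                        sector=sector,
                        diameter=float(d),
                        length=float(ln),
                    )
                )
    return RootSystem(
        plant_id=plant_id,
        species=archetype.name,
        collar_diameter=float(collar),
        max_radius_up=float(r_up),
        max_radius_down=float(r_down),
        max_depth=float(max_depth),
        layout=archetype.root_layout,
        stem_length=None if stem_length is None else float(stem_length),
        site=config.site_label,
        segments=segments,
    )


# ---------------------------------------------------------------------------
# Tensile tests
# ---------------------------------------------------------------------------

# curve shape fractions: toe to (15% disp, 5% force), elastic to
# (60% disp, 75% force), plastic to (100%, 100%), then drop to 20% of peak
_TOE = (0.15, 0.05)
_ELASTIC = (0.60, 0.75)
_POST_BREAK_FORCE = 0.20


def _tensile_curve(f_peak: float, disp_break: float) -> np.ndarray:
    nodes = [
        (0.0, 0.0),
        (_TOE[0] * disp_break, _TOE[1] * f_peak),
        (_ELASTIC[0] * disp_break, _ELASTIC[1] * f_peak),
        (disp_break, f_peak),
    ]
    pts: list[tuple[float, float]] = []
    counts = (5, 10, 8)
    for (x0, y0), (x1, y1), n in zip(nodes, nodes[1:], counts):
        for t in np.linspace(0.0, 1.0, n, endpoint=False):
            pts.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
    pts.append((disp_break, f_peak))
    pts.append((1.02 * disp_break, _POST_BREAK_FORCE * f_peak))
    return np.array(pts)


def generate_tensile_tests(
    archetype: SpeciesArchetype, config: GeneratorConfig
) -> list[TensileTest]:
    """Tensile records whose peak stress follows the archetype power law.

    Noiseless (``noise_cv=0``) output breaks exactly at
    ``alpha * D**-beta``. A fraction ``config.invalid_fraction`` of
    specimens carries a deliberate validity violation (clamp failure,
    slippage, or a too-short gauge length), cycling over the three kinds.
    """
    if config.n_tensile < 1:
        raise ValueError("n_tensile must be >= 1")
    rng = _rng(config, "tensile", archetype.name)
    tests: list[TensileTest] = []
    for i in range(config.n_tensile):
        d = float(
            np.clip(np.exp(rng.normal(archetype.diameter_mu, archetype.diameter_sigma)),
                    0.1, 3.0)
        )
        t_true = archetype.tmax_alpha * d ** (-archetype.tmax_beta)
        t_peak = t_true * float(_lognormal_factor(rng, config.noise_cv))
        eps_break = archetype.eps_ult_mean * float(
            _lognormal_factor(rng, config.noise_cv)
        )
        gauge = 1.25 * 30.0 * d
        csa = math.pi * d * d / 4.0
        curve = _tensile_curve(t_peak * csa, eps_break / 100.0 * gauge)

        failure, slipped = "middle_third", False
        if rng.random() < config.invalid_fraction:
            kind = i % 3
            if kind == 0:
                failure = "clamp"
            elif kind == 1:
                slipped = True
            else:
                gauge = 20.0 * d  # below the 30x span requirement
                curve = _tensile_curve(t_peak * csa, eps_break / 100.0 * gauge)

        # three calliper readings scatter mildly around the true diameter but
        # keep the same mean so the noiseless stress contract stays exact
        dd = 0.02 * d
        diameters = (d - dd, d, d + dd)
        tests.append(
            TensileTest(
                root_id=f"{archetype.name.replace(' ', '_')}_T{i}",
                species=archetype.name,
                diameters=diameters,
                gauge_length=gauge,
                curve=curve,
                site=config.site_label,
                depth_layer=int(rng.integers(0, 3)),
                sector=("up", "down")[int(rng.integers(0, 2))],
                failure_location=failure,
                slipped=slipped,
            )
        )
    return tests


# ---------------------------------------------------------------------------
# Bending tests
# ---------------------------------------------------------------------------


def generate_bending_tests(
    archetype: SpeciesArchetype, config: GeneratorConfig, span_ratio: float = 25.0
) -> list[BendingTest]:
    """Three-point bending records encoding a known flexural modulus.

    The initial load-deflection slope is exactly ``48 E I / L³`` for the
    per-root true E (archetype mean times lognormal noise), followed by a
    softening plastic tail. A fraction ``invalid_fraction`` of specimens
    gets a span below the shear-safe threshold.
    """
    if config.n_bending < 0:
        raise ValueError("n_bending must be >= 0")
    rng = _rng(config, "bending", archetype.name)
    tests: list[BendingTest] = []
    for i in range(config.n_bending):
        d = float(
            np.clip(
                np.exp(rng.normal(archetype.diameter_mu + 0.7, archetype.diameter_sigma)),
                2.0, 12.0,
            )
        )
        w = d * float(rng.uniform(0.9, 1.1))  # mild eccentricity
        span = span_ratio * d
        if rng.random() < config.invalid_fraction:
            span = 12.0 * d  # below the span/depth threshold
        e_true = archetype.bending_modulus_mean * float(
            _lognormal_factor(rng, config.noise_cv)
        )
        inertia = second_moment_of_inertia(d, w)
        k = 48.0 * e_true * inertia / span**3  # N/mm
        delta_lin = span / 40.0  # end of the linear region
        f_lin = k * delta_lin
        pts = [(x, k * x) for x in np.linspace(0.0, delta_lin, 12)]
        for x in np.linspace(delta_lin, 2.0 * delta_lin, 6)[1:]:
            pts.append((x, f_lin + (k / 3.0) * (x - delta_lin)))
        tests.append(
            BendingTest(
                root_id=f"{archetype.name.replace(' ', '_')}_B{i}",
                species=archetype.name,
                depth_diameter=d,
                width_diameter=float(w),
                span=float(span),
                curve=np.array(pts),
                site=config.site_label,
            )
        )
    return tests


# ---------------------------------------------------------------------------
# Shear, soil, quadrats, chemistry
# ---------------------------------------------------------------------------


def generate_shear_tests(
    cohesion: float,
    friction_angle: float,
    loads: Sequence[float],
    config: GeneratorConfig,
    box_area: float = DEFAULT_BOX_AREA_M2,
    horizon: str = "A",
) -> list[ShearTest]:
    """Direct-shear records on the Mohr-Coulomb line plus Gaussian noise.

    ``config.n_shear`` replicates of the full load set (e.g. the standard
    200/300/500 N weights on a 60 mm box). Noise s.d. is
    ``noise_cv * tau_true`` per point.
    """
    if not loads:
        raise ValueError("loads must be non-empty")
    if any(l <= 0 for l in loads):
        raise ValueError("normal loads must be positive")
    if not 0.0 <= friction_angle < 90.0:
        raise ValueError("friction angle must be in [0, 90) degrees")
    rng = _rng(config, "shear", horizon)
    tan_phi = math.tan(math.radians(friction_angle))
    tests: list[ShearTest] = []
    for _ in range(config.n_shear):
        for load in loads:
            sigma = load / box_area / 1e3  # kPa
            tau_true = cohesion + sigma * tan_phi
            tau = tau_true + rng.normal(0.0, config.noise_cv * tau_true) if config.noise_cv else tau_true
            tests.append(
                ShearTest(
                    normal_load=float(load),
                    peak_shear_force=float(tau * 1e3 * box_area),
                    box_area=box_area,
                    site=config.site_label,
                    horizon=horizon,
                )
            )
    return tests


def generate_soil_samples(
    true_water_fractions: tuple[float, float],
    true_bulk_density: float,
    config: GeneratorConfig,
    n_samples: int = 7,
    horizon: str = "A",
) -> list[SoilSample]:
    """Mass/volume tuples whose gravimetric analysis recovers the targets.

    ``true_water_fractions`` is (w_i, w_s) in %: initial and saturated
    gravimetric water content. Noise jitters volume and per-sample water
    contents multiplicatively while preserving ``m_s >= m_i >= m_d``.
    """
    w_i, w_s = true_water_fractions
    if not 0 <= w_i <= w_s:
        raise ValueError(
            f"infeasible targets: need 0 <= w_i <= w_s, got w_i={w_i}, w_s={w_s}"
        )
    if true_bulk_density <= 0:
        raise ValueError("bulk density must be > 0")
    rng = _rng(config, "soil", horizon)
    samples: list[SoilSample] = []
    for _ in range(n_samples):
        v = 80.0 * float(_lognormal_factor(rng, config.noise_cv / 2))
        m_d = true_bulk_density * v
        ws_k = w_s * float(_lognormal_factor(rng, config.noise_cv))
        wi_k = min(w_i * float(_lognormal_factor(rng, config.noise_cv)), ws_k)
        samples.append(
            SoilSample(
                m_i=m_d * (1.0 + wi_k / 100.0),
                m_s=m_d * (1.0 + ws_k / 100.0),
                m_d=m_d,
                v=v,
            )
        )
    return samples


@dataclass
class QuadratRecord:
    """Stem count of one species in one 1 m² quadrat."""

    quadrat_id: int
    species: str
    count: int
    site: str = "hotspot"
    year: int = 2009


def generate_quadrat_survey(
    species_densities: Mapping[str, float],
    n_quadrats: int,
    config: GeneratorConfig,
    year: int = 2009,
) -> list[QuadratRecord]:
    """Per-quadrat Poisson stem counts at the given mean densities."""
    for sp, dens in species_densities.items():
        if dens < 0:
            raise ValueError(f"negative density for {sp}")
    rng = _rng(config, "quadrat", year)
    records: list[QuadratRecord] = []
    for q in range(n_quadrats):
        for sp, dens in species_densities.items():
            records.append(
                QuadratRecord(
                    quadrat_id=q,
                    species=sp,
                    count=int(rng.poisson(dens)),
                    site=config.site_label,
                    year=year,
                )
            )
    return records


@dataclass
class RootChemistryRecord:
    """Nitrogen and cellulose concentration (%) of one analysed root."""

    root_id: str
    species: str
    n_concentration: float
    cellulose: float


def generate_root_chemistry(
    archetype: SpeciesArchetype, config: GeneratorConfig, n_roots: int = 10
) -> list[RootChemistryRecord]:
    """Per-root N and cellulose values around the archetype means."""
    rng = _rng(config, "chemistry", archetype.name)
    out = []
    for i in range(n_roots):
        out.append(
            RootChemistryRecord(
                root_id=f"{archetype.name.replace(' ', '_')}_C{i}",
                species=archetype.name,
                n_concentration=archetype.n_concentration_mean
                * float(_lognormal_factor(rng, config.noise_cv)),
                cellulose=archetype.cellulose_mean
                * float(_lognormal_factor(rng, config.noise_cv)),
            )
        )
    return out
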