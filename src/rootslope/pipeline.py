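"""End-to-end orchestration: simulate -> traits -> score -> placement.

Stage functions take and return in-memory objects; the CLI wraps them with
CSV I/O. Species-level trait summaries are:

* ``stems_per_m2`` — mean quadrat stem count (quadrats are 1 m²);
* ``isv_over_dc`` — mean per-plant ISV standardized by collar diameter;
* ``rar`` / ``rar_fine`` / ``rar_coarse`` — mean per-plant cumulated root
  volume over the plant's own ISV envelope volume (the perpendicular-
  crossing equivalence), by diameter class;
* ``t_max``, ``eps_ult`` — means over valid tensile results;
* ``ei`` — mean rigidity over valid bending results;
* ``n_concentration``, ``cellulose`` — means over analysed roots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import architecture, mechanics, scoring, soil, synthetic

__all__ = [
    "mechanical_trait_frame",
    "architectural_trait_frame",
    "soil_trait_frame",
    "species_trait_table",
    "derive_placement_profile",
    "placement_table",
    "simulate_dataset",
]


def mechanical_trait_frame(
    tensile_tests: Sequence[mechanics.TensileTest],
    bending_tests: Sequence[mechanics.BendingTest],
    config: mechanics.MechanicsConfig = mechanics.DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-root mechanical traits, one row per tested root."""
    rows = []
    for t in tensile_tests:
        r = mechanics.tensile_curve_metrics(t, config)
        rows.append(
            dict(root_id=r.root_id, species=r.species, kind="tensile",
                 t_max_mpa=r.t_max, eps_ult_pct=r.eps_ult,
                 tensile_modulus_mpa=r.tensile_modulus, csa_mm2=r.csa,
                 mean_diameter_mm=r.mean_diameter, valid=r.valid,
                 invalid_reasons=";".join(sorted(r.invalid_reasons)),
                 e_mpa=np.nan, i_mm4=np.nan, ei_knmm2=np.nan)
        )
    for t in bending_tests:
        r = mechanics.bending_metrics(t, config)
        rows.append(
            dict(root_id=r.root_id, species=r.species, kind="bending",
                 t_max_mpa=np.nan, eps_ult_pct=np.nan, tensile_modulus_mpa=np.nan,
                 csa_mm2=np.nan, mean_diameter_mm=np.nan, valid=r.valid,
                 invalid_reasons=";".join(sorted(r.invalid_reasons)),
                 e_mpa=r.bending_modulus, i_mm4=r.second_moment,
                 ei_knmm2=r.rigidity)
        )
    return pd.DataFrame(rows)


def architectural_trait_frame(
    systems: Sequence[architecture.RootSystem],
) -> pd.DataFrame:
    """Per-plant architectural traits: ISV, ISV/Dc and volume-based RAR."""
    rows = []
    for s in systems:
        isv = architecture.individual_soil_volume(s)
        vol = {"all": 0.0, "fine": 0.0, "coarse": 0.0}
        for seg in s.segments:
            v = architecture.segment_volume(seg)  # mm^3
            cls = "fine" if seg.diameter < architecture.FINE_COARSE_BOUNDARY_MM else "coarse"
            vol["all"] += v
            vol[cls] += v
        isv_mm3 = isv.total * 1e9
        rows.append(
            dict(
                plant_id=s.plant_id, species=s.species, site=s.site,
                isv_m3=isv.total, isv_over_dc=isv.isv_over_dc,
                rar=vol["all"] / isv_mm3 if isv_mm3 > 0 else np.nan,
                rar_fine=vol["fine"] / isv_mm3 if isv_mm3 > 0 else np.nan,
                rar_coarse=vol["coarse"] / isv_mm3 if isv_mm3 > 0 else np.nan,
            )
        )
    return pd.DataFrame(rows)


def soil_trait_frame(
    shear_tests: Sequence[soil.ShearTest],
    soil_samples: Sequence[tuple[str, str, soil.SoilSample]],
) -> pd.DataFrame:
    """Per (site, horizon) soil traits: c, phi and gravimetric means."""
    rows = []
    keys = sorted({(t.site, t.horizon) for t in shear_tests})
    for site, horizon in keys:
        group = [t for t in shear_tests if (t.site, t.horizon) == (site, horizon)]
        fit = soil.mohr_coulomb_fit(group)
        phys = [
            soil.gravimetric_properties(s)
            for st, h, s in soil_samples
            if (st, h) == (site, horizon)
        ]
        rows.append(
            dict(
                site=site, horizon=horizon,
                cohesion_kpa=fit.cohesion, friction_angle_deg=fit.friction_angle,
                r_squared=fit.r_squared, n_shear=fit.n,
                w_i_pct=np.mean([p.w_i for p in phys]) if phys else np.nan,
                w_s_pct=np.mean([p.w_s for p in phys]) if phys else np.nan,
                rho_d_g_cm3=np.mean([p.rho_d for p in phys]) if phys else np.nan,
            )
        )
    return pd.DataFrame(rows)


def species_trait_table(
    mech: pd.DataFrame,
    arch: pd.DataFrame,
    quadrats: Sequence[synthetic.QuadratRecord],
    chemistry: Sequence[synthetic.RootChemistryRecord],
) -> pd.DataFrame:
    """Assemble the species × trait table consumed by the scorer."""
    species = sorted(arch["species"].unique())
    qdf = pd.DataFrame([dict(species=q.species, count=q.count) for q in quadrats])
    cdf = pd.DataFrame(
        [dict(species=c.species, n=c.n_concentration, cell=c.cellulose) for c in chemistry]
    )
    tens = mech[(mech["kind"] == "tensile") & mech["valid"]]
    bend = mech[(mech["kind"] == "bending") & mech["valid"]]
    rows = []
    for sp in species:
        a = arch[arch["species"] == sp]
        rows.append(
            dict(
                species=sp,
                stems_per_m2=qdf.loc[qdf["species"] == sp, "count"].mean(),
                isv_over_dc=a["isv_over_dc"].mean(),
                rar=a["rar"].mean(),
                rar_fine=a["rar_fine"].mean(),
                rar_coarse=a["rar_coarse"].mean(),
                t_max=tens.loc[tens["species"] == sp, "t_max_mpa"].mean(),
                eps_ult=tens.loc[tens["species"] == sp, "eps_ult_pct"].mean(),
                ei=bend.loc[bend["species"] == sp, "ei_knmm2"].mean(),
                n_concentration=cdf.loc[cdf["species"] == sp, "n"].mean(),
                cellulose=cdf.loc[cdf["species"] == sp, "cell"].mean(),
            )
        )
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


def derive_placement_profile(
    systems: Sequence[architecture.RootSystem],
    sector_share_threshold: float = 0.6,
    deep_share_threshold: float = 0.5,
    shallow_share_threshold: float = 0.7,
    deep_boundary_layer: int = 3,
) -> scoring.PlacementProfile:
    """Derive a species' placement profile from its root systems.

    Sector bias: one slope sector holds more than ``sector_share_threshold``
    of total ISV. Depth bias: more than ``deep_share_threshold`` of root
    volume lies at or below ``deep_boundary_layer`` (>= 30 cm) -> deep;
    more than ``shallow_share_threshold`` in the top layer -> shallow.
    Every bias is backed by an evidence statement.
    """
    isv_up = isv_down = 0.0
    vol_total = vol_deep = vol_top = 0.0
    for s in systems:
        isv = architecture.individual_soil_volume(s)
        for (sector, _), v in isv.per_sector_per_layer.items():
            if sector == "up":
                isv_up += v
            else:
                isv_down += v
        for seg in s.segments:
            v = architecture.segment_volume(seg)
            vol_total += v
            if seg.depth_layer >= deep_boundary_layer:
                vol_deep += v
            if seg.depth_layer == 0:
                vol_top += v

    evidence: list[str] = []
    sector_bias = "none"
    isv_total = isv_up + isv_down
    if isv_total > 0:
        up_share = isv_up / isv_total
        if up_share > sector_share_threshold:
            sector_bias = "up"
            evidence.append(f"ISV upslope share {up_share:.0%} exceeds threshold")
        elif 1.0 - up_share > sector_share_threshold:
            sector_bias = "down"
            evidence.append(f"ISV downslope share {1 - up_share:.0%} exceeds threshold")

    depth_bias = "none"
    if vol_total > 0:
        deep_share = vol_deep / vol_total
        top_share = vol_top / vol_total
        if deep_share > deep_share_threshold:
            depth_bias = "deep"
            evidence.append(
                f"root volume share below {deep_boundary_layer * 10} cm "
                f"is {deep_share:.0%}"
            )
        elif top_share > shallow_share_threshold:
            depth_bias = "shallow"
            evidence.append(f"top-layer root volume share is {top_share:.0%}")

    return scoring.PlacementProfile(
        sector_bias=sector_bias, depth_bias=depth_bias, evidence=evidence
    )


def placement_table(
    cards: Mapping[str, scoring.ScoreCard],
    profiles: Mapping[str, scoring.PlacementProfile],
) -> pd.DataFrame:
    rows = []
    for sp, card in cards.items():
        profile = profiles[sp]
        rows.append(
            dict(
                species=sp,
                position=scoring.recommend_position(card, profile).value,
                sector_bias=profile.sector_bias,
                depth_bias=profile.depth_bias,
                evidence=" | ".join(profile.evidence),
            )
        )
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# Simulation bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    systems: list[architecture.RootSystem]
    tensile_tests: list[mechanics.TensileTest]
    bending_tests: list[mechanics.BendingTest]
    shear_tests: list[soil.ShearTest]
    soil_samples: list[tuple[str, str, soil.SoilSample]]
    quadrats: list[synthetic.QuadratRecord]
    chemistry: list[synthetic.RootChemistryRecord]


#: Plausible site-level soil truths used by the stock simulation: low
#: cohesion on a degraded hotspot, moderate friction angle, and the
#: standard 200/300/500 N load set.
_SOIL_TRUTH = dict(cohesion=3.0, friction_angle=25.0, loads=(200.0, 300.0, 500.0))
_SOIL_GRAVIMETRIC = dict(water=(20.0, 55.0), rho_d=0.9)
#: Mean stem densities (stems per m²) by growth habit: herbs dense,
#: planted shrubs/trees sparse.
_DENSITY_BY_FORM = {"herb": 6.0, "creeper": 3.0, "climber": 0.5, "shrub": 0.7, "tree": 1.5}


def simulate_dataset(
    config: synthetic.GeneratorConfig,
    archetypes: Mapping[str, synthetic.SpeciesArchetype] | None = None,
) -> SimulatedDataset:
    """Generate one complete multi-species dataset for the pipeline."""
    archetypes = dict(archetypes or synthetic.DEFAULT_ARCHETYPES)
    systems, tensile, bending, chem = [], [], [], []
    for arch in archetypes.values():
        for i in range(config.n_plants):
            systems.append(synthetic.generate_root_system(arch, config, i))
        tensile.extend(synthetic.generate_tensile_tests(arch, config))
        bending.extend(synthetic.generate_bending_tests(arch, config))
        chem.extend(synthetic.generate_root_chemistry(arch, config))
    shear = synthetic.generate_shear_tests(
        _SOIL_TRUTH["cohesion"], _SOIL_TRUTH["friction_angle"],
        _SOIL_TRUTH["loads"], config,
    )
    samples = [
        (config.site_label, "A", s)
        for s in synthetic.generate_soil_samples(
            _SOIL_GRAVIMETRIC["water"], _SOIL_GRAVIMETRIC["rho_d"], config
        )
    ]
    densities = {
        name: _DENSITY_BY_FORM[arch.growth_form] for name, arch in archetypes.items()
    }
    quadrats = synthetic.generate_quadrat_survey(
        densities, n_quadrats=8, config=config
    )
    return SimulatedDataset(
        systems=systems, tensile_tests=tensile, bending_tests=bending,
        shear_tests=shear, soil_samples=samples, quadrats=quadrats, chemistry=chem,
    )
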