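"""CSV readers and writers for the pipeline's tabular interchange formats.

Curve-bearing records (tensile, bending) are stored long: one row per
curve point, keyed by ``root_id``, with the specimen metadata repeated on
each row. Everything else is one row per record. All readers validate
required columns and return the package's dataclasses.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .architecture import RootSegment, RootSystem
from .mechanics import BendingTest, TensileTest
from .soil import ShearTest, SoilSample
from .synthetic import QuadratRecord, RootChemistryRecord

__all__ = [
    "read_tensile_tests",
    "write_tensile_tests",
    "read_bending_tests",
    "write_bending_tests",
    "read_root_systems",
    "write_root_systems",
    "read_shear_tests",
    "write_shear_tests",
    "read_soil_samples",
    "write_soil_samples",
    "read_quadrats",
    "write_quadrats",
    "read_root_chemistry",
    "write_root_chemistry",
    "SchemaError",
]


class SchemaError(ValueError):
    """An input table is missing required columns or malformed."""


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


# -- tensile ---------------------------------------------------------------

_TENSILE_META = [
    "root_id", "species", "site", "depth_layer", "sector",
    "d1_mm", "d2_mm", "d3_mm", "gauge_length_mm", "failure_location",
    "slipped", "season",
]


def write_tensile_tests(tests: Iterable[TensileTest], path: Path | str) -> None:
    rows = []
    for t in tests:
        for disp, force in t.curve:
            rows.append(
                dict(
                    root_id=t.root_id, species=t.species, site=t.site,
                    depth_layer=t.depth_layer, sector=t.sector,
                    d1_mm=t.diameters[0], d2_mm=t.diameters[1], d3_mm=t.diameters[2],
                    gauge_length_mm=t.gauge_length,
                    failure_location=t.failure_location, slipped=t.slipped,
                    season=t.season_label, displacement_mm=disp, force_n=force,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tensile_tests(path: Path | str) -> list[TensileTest]:
    df = pd.read_csv(path)
    _require(df, _TENSILE_META + ["displacement_mm", "force_n"], "tensile_tests")
    out = []
    for root_id, g in df.groupby("root_id", sort=False):
        m = g.iloc[0]
        out.append(
            TensileTest(
                root_id=str(root_id), species=m["species"],
                diameters=(m["d1_mm"], m["d2_mm"], m["d3_mm"]),
                gauge_length=float(m["gauge_length_mm"]),
                curve=g[["displacement_mm", "force_n"]].to_numpy(float),
                site=m["site"], depth_layer=int(m["depth_layer"]),
                sector=m["sector"], failure_location=m["failure_location"],
                slipped=bool(m["slipped"]), season_label=str(m["season"]),
            )
        )
    return out


# -- bending ---------------------------------------------------------------

_BENDING_META = [
    "root_id", "species", "site", "depth_layer", "sector",
    "depth_diameter_mm", "width_diameter_mm", "span_mm",
]


def write_bending_tests(tests: Iterable[BendingTest], path: Path | str) -> None:
    rows = []
    for t in tests:
        for defl, force in t.curve:
            rows.append(
                dict(
                    root_id=t.root_id, species=t.species, site=t.site,
                    depth_layer=t.depth_layer, sector=t.sector,
                    depth_diameter_mm=t.depth_diameter,
                    width_diameter_mm=t.width_diameter, span_mm=t.span,
                    deflection_mm=defl, force_n=force,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bending_tests(path: Path | str) -> list[BendingTest]:
    df = pd.read_csv(path)
    _require(df, _BENDING_META + ["deflection_mm", "force_n"], "bending_tests")
    out = []
    for root_id, g in df.groupby("root_id", sort=False):
        m = g.iloc[0]
        out.append(
            BendingTest(
                root_id=str(root_id), species=m["species"],
                depth_diameter=float(m["depth_diameter_mm"]),
                width_diameter=float(m["width_diameter_mm"]),
                span=float(m["span_mm"]),
                curve=g[["deflection_mm", "force_n"]].to_numpy(float),
                site=m["site"], depth_layer=int(m["depth_layer"]),
                sector=m["sector"],
            )
        )
    return out


# -- root systems and segments --------------------------------------------

_SYSTEM_COLS = [
    "plant_id", "species", "site", "collar_diameter_cm", "max_radius_up_m",
    "max_radius_down_m", "max_depth_m", "layout", "stem_length_m",
]
_SEGMENT_COLS = [
    "plant_id", "species", "depth_layer", "sector", "diameter_mm",
    "length_mm", "volume_mm3",
]


def write_root_systems(
    systems: Iterable[RootSystem], systems_path: Path | str, segments_path: Path | str
) -> None:
    sys_rows, seg_rows = [], []
    for s in systems:
        sys_rows.append(
            dict(
                plant_id=s.plant_id, species=s.species, site=s.site,
                collar_diameter_cm=s.collar_diameter,
                max_radius_up_m=s.max_radius_up, max_radius_down_m=s.max_radius_down,
                max_depth_m=s.max_depth, layout=s.layout,
                stem_length_m=np.nan if s.stem_length is None else s.stem_length,
            )
        )
        for seg in s.segments:
            seg_rows.append(
                dict(
                    plant_id=seg.plant_id, species=seg.species,
                    depth_layer=seg.depth_layer, sector=seg.sector,
                    diameter_mm=seg.diameter,
                    length_mm=np.nan if seg.length is None else seg.length,
                    volume_mm3=np.nan if seg.volume is None else seg.volume,
                )
            )
    pd.DataFrame(sys_rows).to_csv(systems_path, index=False)
    pd.DataFrame(seg_rows).to_csv(segments_path, index=False)


def read_root_systems(
    systems_path: Path | str, segments_path: Path | str
) -> list[RootSystem]:
    sdf = pd.read_csv(systems_path)
    _require(sdf, _SYSTEM_COLS, "root_systems")
    gdf = pd.read_csv(segments_path)
    _require(gdf, _SEGMENT_COLS, "root_segments")
    seg_by_plant: dict[str, list[RootSegment]] = {}
    for _, r in gdf.iterrows():
        seg = RootSegment(
            species=r["species"], plant_id=r["plant_id"],
            depth_layer=int(r["depth_layer"]), sector=r["sector"],
            diameter=float(r["diameter_mm"]),
            length=None if pd.isna(r["length_mm"]) else float(r["length_mm"]),
            volume=None if pd.isna(r["volume_mm3"]) else float(r["volume_mm3"]),
        )
        seg_by_plant.setdefault(seg.plant_id, []).append(seg)
    systems = []
    for _, r in sdf.iterrows():
        systems.append(
            RootSystem(
                plant_id=r["plant_id"], species=r["species"],
                collar_diameter=float(r["collar_diameter_cm"]),
                max_radius_up=float(r["max_radius_up_m"]),
                max_radius_down=float(r["max_radius_down_m"]),
                max_depth=float(r["max_depth_m"]), layout=r["layout"],
                stem_length=None if pd.isna(r["stem_length_m"]) else float(r["stem_length_m"]),
                site=r["site"], segments=seg_by_plant.get(r["plant_id"], []),
            )
        )
    return systems


# -- shear, soil, quadrats, chemistry --------------------------------------


def write_shear_tests(tests: Iterable[ShearTest], path: Path | str) -> None:
    pd.DataFrame(
        [
            dict(
                site=t.site, horizon=t.horizon, normal_load_n=t.normal_load,
                peak_shear_force_n=t.peak_shear_force, box_area_m2=t.box_area,
            )
            for t in tests
        ]
    ).to_csv(path, index=False)


def read_shear_tests(path: Path | str) -> list[ShearTest]:
    df = pd.read_csv(path)
    _require(
        df,
        ["site", "horizon", "normal_load_n", "peak_shear_force_n", "box_area_m2"],
        "shear_tests",
    )
    return [
        ShearTest(
            normal_load=float(r["normal_load_n"]),
            peak_shear_force=float(r["peak_shear_force_n"]),
            box_area=float(r["box_area_m2"]), site=r["site"], horizon=r["horizon"],
        )
        for _, r in df.iterrows()
    ]


def write_soil_samples(
    samples: Iterable[tuple[str, str, SoilSample]] | Iterable[SoilSample],
    path: Path | str,
) -> None:
    rows = []
    for item in samples:
        if isinstance(item, SoilSample):
            site, horizon, s = "hotspot", "A", item
        else:
            site, horizon, s = item
        rows.append(
            dict(site=site, horizon=horizon, m_i_g=s.m_i, m_s_g=s.m_s, m_d_g=s.m_d, v_cm3=s.v)
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_soil_samples(path: Path | str) -> list[tuple[str, str, SoilSample]]:
    df = pd.read_csv(path)
    _require(df, ["site", "horizon", "m_i_g", "m_s_g", "m_d_g", "v_cm3"], "soil_samples")
    return [
        (
            r["site"],
            r["horizon"],
            SoilSample(m_i=float(r["m_i_g"]), m_s=float(r["m_s_g"]),
                       m_d=float(r["m_d_g"]), v=float(r["v_cm3"])),
        )
        for _, r in df.iterrows()
    ]


def write_quadrats(records: Iterable[QuadratRecord], path: Path | str) -> None:
    pd.DataFrame(
        [
            dict(site=r.site, year=r.year, quadrat_id=r.quadrat_id,
                 species=r.species, count=r.count)
            for r in records
        ]
    ).to_csv(path, index=False)


def read_quadrats(path: Path | str) -> list[QuadratRecord]:
    df = pd.read_csv(path)
    _require(df, ["site", "year", "quadrat_id", "species", "count"], "quadrats")
    return [
        QuadratRecord(quadrat_id=int(r["quadrat_id"]), species=r["species"],
                      count=int(r["count"]), site=r["site"], year=int(r["year"]))
        for _, r in df.iterrows()
    ]


def write_root_chemistry(records: Iterable[RootChemistryRecord], path: Path | str) -> None:
    pd.DataFrame(
        [
            dict(root_id=r.root_id, species=r.species,
                 n_concentration_pct=r.n_concentration, cellulose_pct=r.cellulose)
            for r in records
        ]
    ).to_csv(path, index=False)


def read_root_chemistry(path: Path | str) -> list[RootChemistryRecord]:
    df = pd.read_csv(path)
    _require(df, ["root_id", "species", "n_concentration_pct", "cellulose_pct"],
             "root_chemistry")
    return [
        RootChemistryRecord(root_id=str(r["root_id"]), species=r["species"],
                            n_concentration=float(r["n_concentration_pct"]),
                            cellulose=float(r["cellulose_pct"]))
        for _, r in df.iterrows()
    ]


def write_json(obj, path: Path | str) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
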