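"""Root-system architectural traits: individual soil volume and root area ratio.

The individual soil volume (ISV) is the envelope of soil a plant's root
system occupies, defined by its maximum rooting radius (horizontal
extension, separately up- and downslope of the stem) and maximum rooting
depth.  For radially organised root systems each slope sector contributes a
quarter-ellipsoid of revolution: semi-axes ``r`` (horizontal, the sector's
max radius) and ``z`` (vertical, max depth), i.e. volume ``(1/3) π r² z``
per sector.  Species whose roots emerge linearly along a creeping or
underground stem instead contribute a quarter of an (elliptic) cylinder per
sector: horizontal semi-axis ``r``, vertical semi-axis ``z``, length the
measured along-stem extent, volume ``(π/4) r z L`` per sector.  ISV is
standardized by the plant collar diameter (ISV/Dc) so individuals of
different sizes can be compared.

The root area ratio (RAR) is the cumulated root cross-sectional area
crossing a potential shear surface per unit soil area; under the
perpendicular-crossing assumption this equals cumulated root volume per
soil volume, which is how it is computed here from per-segment volumes.
Roots split into fine (< 2 mm) and coarse (>= 2 mm) diameter classes;
depth layers are half-open 10-cm bins perpendicular to the soil surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "RootSegment",
    "RootSystem",
    "ISVResult",
    "RARResult",
    "individual_soil_volume",
    "root_area_ratio",
    "segment_volume",
    "FINE_COARSE_BOUNDARY_MM",
    "LAYER_HEIGHT_M",
]

#: Diameter boundary between fine and coarse roots; the boundary itself is
#: assigned to the coarse class.
FINE_COARSE_BOUNDARY_MM = 2.0

#: Depth-layer height (10 cm), perpendicular to the soil surface.
LAYER_HEIGHT_M = 0.10

SECTORS = ("up", "down")


@dataclass
class RootSegment:
    """One measured root piece, bucketed by depth layer and slope sector.

    diameter and length in mm; volume in mm³ (computed from the cylinder
    approximation when not measured directly).
    """

    species: str
    plant_id: str
    depth_layer: int  # 10-cm bins: 0 -> [0,10) cm, 1 -> [10,20) cm ...
    sector: str  # up | down
    diameter: float  # mm
    length: float | None = None  # mm
    volume: float | None = None  # mm^3

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ValueError(f"sector must be one of {SECTORS}, got {self.sector!r}")
        if self.depth_layer < 0:
            raise ValueError("depth_layer must be >= 0")
        if self.diameter < 0 or (self.length is not None and self.length < 0):
            raise ValueError("diameter and length must be >= 0")


def segment_volume(segment: RootSegment) -> float:
    """Segment volume in mm³; cylinder π (d/2)² L when not measured."""
    if segment.volume is not None:
        return segment.volume
    if segment.length is None:
        raise ValueError(
            f"segment of {segment.plant_id}: volume missing and not computable "
            "(need length and diameter)"
        )
    return math.pi * (segment.diameter / 2.0) ** 2 * segment.length


@dataclass
class RootSystem:
    """One plant's excavated root geometry and envelope extents.

    Extents in m, collar diameter Dc in cm. ``layout`` is ``radial`` for
    systems spreading around the stem and ``linear`` for systems organised
    along a creeping/underground stem (``stem_length`` then required).
    """

    plant_id: str
    species: str
    collar_diameter: float  # Dc, cm
    max_radius_up: float  # m
    max_radius_down: float  # m
    max_depth: float  # m
    layout: str = "radial"  # radial | linear
    stem_length: float | None = None  # m, linear layout only
    site: str = "hotspot"
    segments: list[RootSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.collar_diameter <= 0:
            raise ValueError(f"{self.plant_id}: collar diameter must be > 0")
        if self.layout not in ("radial", "linear"):
            raise ValueError(f"{self.plant_id}: unknown layout {self.layout!r}")
        if min(self.max_radius_up, self.max_radius_down, self.max_depth) < 0:
            raise ValueError(f"{self.plant_id}: negative extent")


@dataclass
class ISVResult:
    total: float  # m^3
    per_sector_per_layer: dict[tuple[str, int], float]  # (sector, layer) -> m^3
    isv_over_dc: float  # m^3 / cm


def _ellipsoid_sector_slab(r: float, z: float, z1: float, z2: float) -> float:
    """Quarter-ellipsoid volume between depths z1 and z2 (one slope sector).

    Horizontal cross-section at depth t is a half-disk of radius
    ``r * sqrt(1 - t²/z²)``; integrating the half-disk area over [z1, z2]
    gives ``(π r²/2) [(z2-z1) - (z2³-z1³)/(3 z²)]``.
    """
    z1, z2 = max(0.0, z1), min(z, z2)
    if z <= 0 or r <= 0 or z2 <= z1:
        return 0.0
    return 0.5 * math.pi * r * r * ((z2 - z1) - (z2**3 - z1**3) / (3.0 * z * z))


def _cylinder_sector_slab(r: float, z: float, length: float, z1: float, z2: float) -> float:
    """Quarter elliptic-cylinder volume between depths z1 and z2.

    The cylinder runs horizontally along the stem; its cross-section
    (perpendicular to the stem) is a quarter-ellipse with horizontal
    semi-axis r and vertical semi-axis z. Width at depth t is
    ``r sqrt(1 - t²/z²)``; the slab volume is ``L r ∫ sqrt(1 - t²/z²) dt``,
    totalling ``(π/4) r z L`` over the full depth — the classic quarter
    cylinder when r == z.
    """
    z1, z2 = max(0.0, z1), min(z, z2)
    if z <= 0 or r <= 0 or length <= 0 or z2 <= z1:
        return 0.0

    def antider(t: float) -> float:
        u = min(1.0, t / z)
        return 0.5 * (u * math.sqrt(max(0.0, 1.0 - u * u)) + math.asin(u)) * z

    return length * r * (antider(z2) - antider(z1))


def individual_soil_volume(
    system: RootSystem, layer_height: float = LAYER_HEIGHT_M
) -> ISVResult:
    """ISV of one plant, total and sliced into depth layers per sector.

    Per-layer volumes are obtained by slab slicing of the sector solids
    (quarter-ellipsoids or quarter-cylinders) with horizontal planes at
    multiples of ``layer_height``; they sum exactly to the total.
    ``isv_over_dc`` divides the total (m³) by the collar diameter (cm).
    """
    if system.layout == "linear" and system.stem_length is None:
        raise ValueError(
            f"{system.plant_id}: linear layout requires a measured stem_length"
        )
    z = system.max_depth
    n_layers = max(1, math.ceil(z / layer_height)) if z > 0 else 0
    parts: dict[tuple[str, int], float] = {}
    total = 0.0
    for sector, r in (("up", system.max_radius_up), ("down", system.max_radius_down)):
        for layer in range(n_layers):
            z1, z2 = layer * layer_height, (layer + 1) * layer_height
            if system.layout == "radial":
                v = _ellipsoid_sector_slab(r, z, z1, z2)
            else:
                v = _cylinder_sector_slab(r, z, system.stem_length, z1, z2)
            parts[(sector, layer)] = v
            total += v
    return ISVResult(
        total=total,
        per_sector_per_layer=parts,
        isv_over_dc=total / system.collar_diameter,
    )


@dataclass
class RARResult:
    """RAR per (layer, sector, class); class in {fine, coarse, all}."""

    ratios: dict[tuple[int, str, str], float]
    reference_area: float  # mm^2
    layer_height: float  # mm

    def __getitem__(self, key: tuple[int, str, str]) -> float:
        return self.ratios.get(key, 0.0)

    @property
    def total(self) -> float:
        return sum(v for (_, _, cls), v in self.ratios.items() if cls == "all")


def root_area_ratio(
    segments: Iterable[RootSegment],
    reference_area: float,
    layer_height: float = LAYER_HEIGHT_M * 1000.0,
    boundary: float = FINE_COARSE_BOUNDARY_MM,
) -> RARResult:
    """RAR per depth layer, slope sector and diameter class.

    Under the perpendicular-crossing assumption, RAR within a layer equals
    cumulated root volume over the soil volume ``A · h``:
    ``RAR = Σ V_r / (A h)``. Units: reference_area in mm², layer_height in
    mm, segment volumes in mm³; the ratio is dimensionless. Fine roots have
    diameter < ``boundary`` (2 mm); the boundary diameter is coarse.
    """
    if reference_area <= 0 or layer_height <= 0:
        raise ValueError("reference_area and layer_height must be > 0")
    soil_volume = reference_area * layer_height
    ratios: dict[tuple[int, str, str], float] = {}
    for seg in segments:
        v = segment_volume(seg)
        cls = "fine" if seg.diameter < boundary else "coarse"
        for c in (cls, "all"):
            key = (seg.depth_layer, seg.sector, c)
            ratios[key] = ratios.get(key, 0.0) + v / soil_volume
    return RARResult(ratios=ratios, reference_area=reference_area, layer_height=layer_height)
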