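"""Synthetic island landscapes: land-use patch mosaics and a road network.

Emulates the covariate geography the analysis needs: two land-use layers a few
years apart (four categories: agriculture, transportation, natural,
artificial), with a configurable fraction of the island's area changing
category between the two reference years, and a road polyline network whose
buffer forms the transportation polygons (so tubes on transportation land sit
at distance ~0 from the nearest road).

Patches are Voronoi cells around uniformly seeded points, clipped to the
island extent; this is the simplest tiling that is non-overlapping and
jointly covers the extent. Land-use change is induced by re-labelling a
random subset of year-A patches, with a configurable share of the changed
area coming from natural land ("development-related" conversions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely import MultiPoint, box
from shapely.geometry import LineString, MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union, voronoi_diagram

CATEGORIES = ("agriculture", "transportation", "natural", "artificial")

#: Island-wide area shares of the four base categories (remainder = change/mixed).
DEFAULT_SHARES = {
    "natural": 0.522,
    "agriculture": 0.211,
    "artificial": 0.104,
    "transportation": 0.056,
}

#: Share of changed area converted out of natural land cover
#: (development-related conversions).
DEFAULT_DEV_SHARE = 0.616


@dataclass
class LandscapeBundle:
    """Paired land-use layers, road network and island extent (planar meters).

    ``landuse_a`` / ``landuse_b`` are lists of ``(polygon, category)`` pairs;
    within each layer the polygons are non-overlapping and jointly cover the
    extent. ``roads`` is a list of LineStrings, all inside the extent.
    """

    extent: tuple[float, float, float, float]
    landuse_a: list[tuple[Polygon, str]]
    landuse_b: list[tuple[Polygon, str]]
    roads: list[LineString]
    crs_note: str = "planar meters"
    meta: dict = field(default_factory=dict)

    @property
    def extent_polygon(self) -> Polygon:
        return box(*self.extent)

    def changed_area_fraction(self) -> float:
        """Fraction of the extent whose category differs between the layers.

        Layers share patch geometry by construction, so this is a sum over
        matched patches.
        """
        total = self.extent_polygon.area
        changed = sum(
            p.area
            for (p, ca), (_, cb) in zip(self.landuse_a, self.landuse_b)
            if ca != cb
        )
        return changed / total


def _polys(geom) -> list[Polygon]:
    """Flatten a geometry into its non-empty polygonal parts."""
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    return [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]


def _road_lattice(extent, spacing: float) -> list[LineString]:
    xmin, ymin, xmax, ymax = extent
    roads = []
    x = xmin + spacing / 2
    while x < xmax:
        roads.append(LineString([(x, ymin), (x, ymax)]))
        x += spacing
    y = ymin + spacing / 2
    while y < ymax:
        roads.append(LineString([(xmin, y), (xmax, y)]))
        y += spacing
    return roads


def generate_landscape(
    seed: int,
    extent: tuple[float, float, float, float] = (0.0, 0.0, 4000.0, 4000.0),
    n_patches: int = 350,
    change_fraction: float = 0.107,
    road_spacing: float = 500.0,
    road_buffer: float = 12.0,
    category_shares: dict[str, float] | None = None,
    dev_share: float = DEFAULT_DEV_SHARE,
) -> LandscapeBundle:
    """Generate a seeded synthetic landscape bundle.

    Parameters
    ----------
    seed
        Seeds all randomness; identical seeds give identical bundles.
    extent
        (xmin, ymin, xmax, ymax) island rectangle in meters.
    n_patches
        Number of Voronoi seed points; patch granularity controls how closely
        the realised change fraction can track the request (default patches
        are ~0.3% of the island each).
    change_fraction
        Target fraction of island area whose category differs between the two
        layers; realised within ±2 percentage points.
    road_spacing
        Spacing of the rectangular road lattice (m).
    road_buffer
        Half-width of the transportation corridor around each road (m).
    category_shares
        Target area shares per category (defaults to the island-wide shares).
    dev_share
        Share of changed area drawn from natural land (development-related).
    """
    if not 0 <= change_fraction < 1:
        raise ValueError(f"change_fraction must be in [0, 1), got {change_fraction}")
    if road_spacing <= 0:
        raise ValueError("road_spacing must be positive")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"degenerate extent (zero area): {extent}")
    shares = dict(category_shares or DEFAULT_SHARES)

    rng = np.random.default_rng(seed)
    island = box(*extent)
    total_area = island.area

    roads = _road_lattice(extent, road_spacing)
    corridor = unary_union([r.buffer(road_buffer, cap_style="flat") for r in roads])
    corridor = corridor.intersection(island)

    pts = rng.uniform([xmin, ymin], [xmax, ymax], size=(n_patches, 2))
    cells = voronoi_diagram(MultiPoint(pts), envelope=island)
    patches: list[Polygon] = []
    for cell in cells.geoms:
        patches.extend(_polys(cell.intersection(island).difference(corridor)))
    # stable order regardless of shapely's internal cell ordering
    patches.sort(key=lambda p: (round(p.centroid.x, 6), round(p.centroid.y, 6)))

    # assign base categories to off-road patches by renormalised target shares
    base = {c: s for c, s in shares.items() if c != "transportation"}
    tot = sum(base.values())
    cats, probs = zip(*[(c, s / tot) for c, s in base.items()])
    layer_a: list[tuple[Polygon, str]] = [
        (p, str(rng.choice(cats, p=probs))) for p in patches
    ]
    layer_a.extend((p, "transportation") for p in _polys(corridor))

    layer_b = list(layer_a)
    target = change_fraction * total_area
    if target > 0:
        order = rng.permutation(len(patches))
        nat_target = dev_share * target
        other_target = target - nat_target
        changed = {"nat": 0.0, "other": 0.0}
        new_b: dict[int, str] = {}
        for k in order:
            p, cat = layer_a[k]
            if cat == "natural" and changed["nat"] < nat_target:
                new_b[k] = str(rng.choice(["agriculture", "transportation", "artificial"]))
                changed["nat"] += p.area
            elif cat != "natural" and changed["other"] < other_target:
                others = [c for c in CATEGORIES if c != cat]
                new_b[k] = str(rng.choice(others))
                changed["other"] += p.area
            if changed["nat"] >= nat_target and changed["other"] >= other_target:
                break
        layer_b = [
            (p, new_b.get(k, cat)) for k, (p, cat) in enumerate(layer_a)
        ]

    bundle = LandscapeBundle(
        extent=extent,
        landuse_a=layer_a,
        landuse_b=layer_b,
        roads=roads,
        meta={
            "seed": int(seed),
            "n_patches": int(n_patches),
            "change_fraction_requested": float(change_fraction),
            "road_spacing": float(road_spacing),
            "road_buffer": float(road_buffer),
        },
    )
    bundle.meta["change_fraction_realised"] = bundle.changed_area_fraction()
    return bundle


# ---------------------------------------------------------------------------
# GeoJSON I/O (FeatureCollections; polygons carry a "category" property)

def layer_to_geojson(layer: list[tuple[Polygon, str]]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {"category": cat},
            }
            for poly, cat in layer
        ],
    }


def roads_to_geojson(roads: list[LineString]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(r), "properties": {}}
            for r in roads
        ],
    }


def layer_from_geojson(gj: dict) -> list[tuple[Polygon, str]]:
    return [
        (shape(f["geometry"]), f["properties"]["category"]) for f in gj["features"]
    ]


def roads_from_geojson(gj: dict) -> list[LineString]:
    return [shape(f["geometry"]) for f in gj["features"]]


def write_bundle(bundle: LandscapeBundle, outdir) -> None:
    """Write landuse_a/landuse_b/roads GeoJSON plus a metadata JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, gj in (
        ("landuse_a", layer_to_geojson(bundle.landuse_a)),
        ("landuse_b", layer_to_geojson(bundle.landuse_b)),
        ("roads", roads_to_geojson(bundle.roads)),
    ):
        (outdir / f"{name}.geojson").write_text(json.dumps(gj))
    meta = dict(bundle.meta)
    meta["extent"] = list(bundle.extent)
    meta["crs_note"] = bundle.crs_note
    (outdir / "landscape_meta.json").write_text(json.dumps(meta, indent=2))


def read_bundle(outdir) -> LandscapeBundle:
    from pathlib import Path

    outdir = Path(outdir)
    meta = json.loads((outdir / "landscape_meta.json").read_text())
    return LandscapeBundle(
        extent=tuple(meta["extent"]),
        landuse_a=layer_from_geojson(
            json.loads((outdir / "landuse_a.geojson").read_text())
        ),
        landuse_b=layer_from_geojson(
            json.loads((outdir / "landuse_b.geojson").read_text())
        ),
        roads=roads_from_geojson(json.loads((outdir / "roads.geojson").read_text())),
        crs_note=meta.get("crs_note", "planar meters"),
        meta={k: v for k, v in meta.items() if k not in ("extent", "crs_note")},
    )
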