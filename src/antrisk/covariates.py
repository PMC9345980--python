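"""Attach land-use and road-distance covariates to labelled sampling tubes.

Each tube gets:

* ``landuse5`` — the five-level land-use covariate: the point's category if it
  is the same in both reference years, else ``"change"``. Natural land cover
  is the model reference level.
* ``road_dist`` — Euclidean distance (m) to the nearest road centerline.

Category lookup is a point-in-polygon overlay at the tube location; a point
on a shared boundary resolves deterministically by the fixed priority
transportation > artificial > agriculture > natural.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .landscape import LandscapeBundle

logger = logging.getLogger(__name__)

LANDUSE5_LEVELS = ("agriculture", "transportation", "natural", "artificial", "change")
REFERENCE_LEVEL = "natural"

#: boundary-tie priority, highest first
_PRIORITY = ("transportation", "artificial", "agriculture", "natural")


def _pick(cats: list[str], x: float, y: float) -> str:
    if not cats:
        raise ValueError(f"point ({x}, {y}) is covered by no land-use polygon")
    if len(cats) == 1:
        return cats[0]
    for c in _PRIORITY:
        if c in cats:
            return c
    return cats[0]


def category_at_point(x: float, y: float, layer) -> str:
    """Four-way land-use category of the polygon containing the point.

    ``layer`` is a list of ``(polygon, category)`` pairs covering the extent.
    """
    pt = Point(x, y)
    hits = [cat for poly, cat in layer if poly.intersects(pt)]
    return _pick(hits, x, y)


def categories_at_points(xs, ys, layer) -> np.ndarray:
    """Vectorised overlay via an STRtree; same tie rule as category_at_point."""
    polys = [p for p, _ in layer]
    cats = [c for _, c in layer]
    tree = STRtree(polys)
    pts = shapely.points(np.asarray(xs, float), np.asarray(ys, float))
    pt_idx, poly_idx = tree.query(pts, predicate="intersects")
    hits: list[list[str]] = [[] for _ in range(len(pts))]
    for pi, qi in zip(pt_idx, poly_idx):
        hits[pi].append(cats[qi])
    return np.array(
        [_pick(h, float(xs[k]), float(ys[k])) for k, h in enumerate(hits)]
    )


def landuse5(x: float, y: float, layer_a, layer_b) -> str:
    """Five-level covariate: the shared category, or ``"change"`` if it differs."""
    ca = category_at_point(x, y, layer_a)
    cb = category_at_point(x, y, layer_b)
    return ca if ca == cb else "change"


def nearest_road_distance(x: float, y: float, roads) -> float:
    """Minimum Euclidean distance (m) from the point to any road polyline."""
    if not roads:
        raise ValueError("road network is empty")
    pt = Point(x, y)
    return min(pt.distance(r) for r in roads)


def nearest_road_distances(xs, ys, roads) -> np.ndarray:
    if not roads:
        raise ValueError("road network is empty")
    network = unary_union(roads)
    pts = shapely.points(np.asarray(xs, float), np.asarray(ys, float))
    return shapely.distance(pts, network)


def attach_covariates(labelled_tubes: pd.DataFrame, bundle: LandscapeBundle) -> pd.DataFrame:
    """Build the model table: one row per labelled tube with covariates.

    Input needs columns ``tube_id, x, y_coord, y`` (as produced by
    :func:`antrisk.gridding.label_tubes`: planar coordinates ``x``/``y_coord``
    and the binary SIRH indicator ``y``).

    Output columns: ``tube_id, y, landuse5, road_dist, x, y_coord``.
    """
    xs = labelled_tubes["x"].to_numpy(float)
    ys_coord = labelled_tubes["y_coord"].to_numpy(float)
    try:
        ca = categories_at_points(xs, ys_coord, bundle.landuse_a)
        cb = categories_at_points(xs, ys_coord, bundle.landuse_b)
    except ValueError as err:
        raise ValueError(f"covariate overlay failed: {err}") from err
    lu5 = np.where(ca == cb, ca, "change")
    dist = nearest_road_distances(xs, ys_coord, bundle.roads)

    out = pd.DataFrame(
        {
            "tube_id": labelled_tubes["tube_id"].to_numpy(),
            "y": labelled_tubes["y"].astype(int).to_numpy(),
            "landuse5": lu5,
            "road_dist": dist,
            "x": xs,
            "y_coord": ys_coord,
        }
    )
    counts = out["landuse5"].value_counts()
    med = out.groupby("landuse5")["road_dist"].median()
    logger.info("landuse5 counts: %s", counts.to_dict())
    logger.info("per-category median road distance (m): %s", med.round(2).to_dict())
    return out
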