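"""Landscape composition metrics at the node (buffer) and link (strip) level.

Node-level units are forest-herb populations with circular buffer zones of
125-2000 m radius around the population centroid; link-level units are
population pairs with a rectangular strip between the two centroids whose
width is a fixed ratio (1:7 ... 2:3) of its length.  Within a zone the module
measures per-cent cover of the area-based land-use classes, mean multi-year
crop dominance for the crop types, relative length of linear landscape
elements (m per m^2), Shannon diversity of land-use types ("landscape
heterogeneity") and the density of land-use patch edges.

Raster metrics use the cell-centre-in-zone membership rule; their reference
area is the summed area of member cells.  Linear-element metrics use exact
polyline clipping against the zone polygon and the polygon's geometric area.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .config import (
    AREA_CLASSES,
    AREA_CLASS_CODES,
    CROP_CLASSES,
    INDEX_METRICS,
    LINEAR_CLASSES,
    LINK_RATIO_LABELS,
    all_metric_names,
)
from .maps import LandUseMap
from .rasters import Raster

__all__ = [
    "percent_cover", "crop_dominance_zone", "relative_linear_length",
    "shannon_heterogeneity", "edge_density", "node_metrics", "link_strip",
    "link_metrics", "geographic_distance", "metric_wide",
]


# ---- zone rasterization --------------------------------------------------

def _zone_cells(raster: Raster, zone: Polygon) -> np.ndarray:
    """Values of cells whose centres fall inside ``zone`` (flat array)."""
    mask, (r0, r1, c0, c1) = _zone_mask(raster, zone)
    return raster.data[r0:r1, c0:c1][mask]


def _zone_mask(raster: Raster, zone: Polygon):
    """Boolean cell-centre-in-zone mask over the zone's bounding sub-grid."""
    xmin, ymin, xmax, ymax = zone.bounds
    ex = raster.extent
    if xmin >= ex[2] or xmax <= ex[0] or ymin >= ex[3] or ymax <= ex[1]:
        raise ValueError("zone does not intersect the raster extent")
    if xmin < ex[0] or ymin < ex[1] or xmax > ex[2] or ymax > ex[3]:
        warnings.warn("zone extends beyond the window; computed on the clipped part",
                      stacklevel=3)
    c0 = max(0, int((xmin - raster.x0) // raster.cell))
    c1 = min(raster.ncols, int(math.ceil((xmax - raster.x0) / raster.cell)))
    r0 = max(0, int((ex[3] - ymax) // raster.cell))
    r1 = min(raster.nrows, int(math.ceil((ex[3] - ymin) / raster.cell)))
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xs = raster.x0 + (cols + 0.5) * raster.cell
    ys = raster.y0 + (raster.nrows - rows - 0.5) * raster.cell
    gx, gy = np.meshgrid(xs, ys)
    shapely.prepare(zone)
    mask = shapely.contains_xy(zone, gx.ravel(), gy.ravel()).reshape(gx.shape)
    if not mask.any():
        raise ValueError("zone contains no cell centres")
    return mask, (r0, r1, c0, c1)


# ---- individual metrics --------------------------------------------------

def percent_cover(lum: LandUseMap, zone: Polygon, class_name: str) -> float:
    """Fraction of zone cells carrying the given area-based land-use class."""
    code = AREA_CLASS_CODES[class_name]
    cells = _zone_cells(lum.landuse, zone)
    return float(np.mean(cells == code))


def crop_dominance_zone(
    lum: LandUseMap, zone: Polygon, crop: str,
    period: tuple[int, int] | None = None,
) -> float:
    """Mean per-cell crop dominance over the zone.

    Cell dominance is the fraction of years of the period in which the crop
    was grown in that cell (1 = every year, 0 = never).
    """
    dom = lum.dominance(crop, period)
    return float(np.mean(_zone_cells(dom, zone)))


def relative_linear_length(lum: LandUseMap, zone: Polygon, linear_class: str) -> float:
    """Total clipped polyline length of a linear class divided by zone area."""
    lines = lum.lines.get(linear_class, [])
    total = 0.0
    for line in lines:
        clipped = line.intersection(zone)
        total += clipped.length
    return total / zone.area


def shannon_heterogeneity(lum: LandUseMap, zone: Polygon) -> float:
    """Shannon diversity H = -sum p_c ln p_c over area-based classes in the zone."""
    cells = _zone_cells(lum.landuse, zone)
    _, counts = np.unique(cells, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def edge_density(lum: LandUseMap, zone: Polygon) -> float:
    """Length of boundaries between unlike rook-adjacent cells, per zone area.

    Only internal edges (both cells inside the zone) are counted; each unlike
    neighbour pair contributes one cell-side of edge length.
    """
    raster = lum.landuse
    mask, (r0, r1, c0, c1) = _zone_mask(raster, zone)
    sub = raster.data[r0:r1, c0:c1]
    cell = raster.cell
    horiz = (sub[:, :-1] != sub[:, 1:]) & mask[:, :-1] & mask[:, 1:]
    vert = (sub[:-1, :] != sub[1:, :]) & mask[:-1, :] & mask[1:, :]
    length = (horiz.sum() + vert.sum()) * cell
    area = mask.sum() * cell * cell
    return float(length / area)


def geographic_distance(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Euclidean distance between two population centres in metres."""
    return math.hypot(p1[0] - p2[0], p1[1] - p2[1])


# ---- zone constructors ---------------------------------------------------

def node_buffer(centre: Sequence[float], radius_m: float) -> Polygon:
    return Point(centre).buffer(radius_m, quad_segs=64)


def link_strip(p1: Sequence[float], p2: Sequence[float], ratio: float) -> Polygon:
    """Rectangle joining two population centres.

    Length equals the centre distance, width equals ``ratio`` times the
    length; the long axis runs along the connecting segment and the rectangle
    is centred on it.  Symmetric in its endpoints.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    length = float(np.hypot(*d))
    if length == 0:
        raise ValueError("strip endpoints coincide")
    u = d / length
    n = np.array([-u[1], u[0]])
    half_w = 0.5 * ratio * length
    corners = [
        p1 + half_w * n, p2 + half_w * n,
        p2 - half_w * n, p1 - half_w * n,
    ]
    return Polygon([tuple(c) for c in corners])


# ---- metric tables -------------------------------------------------------

def _single_metric(
    lum: LandUseMap, zone: Polygon, metric: str,
    period: tuple[int, int] | None,
) -> float:
    if metric in AREA_CLASS_CODES:
        return percent_cover(lum, zone, metric)
    if metric in CROP_CLASSES:
        return crop_dominance_zone(lum, zone, metric, period)
    if metric in LINEAR_CLASSES:
        return relative_linear_length(lum, zone, metric)
    if metric == "LANDHET":
        return shannon_heterogeneity(lum, zone)
    if metric == "EDGEDEN":
        return edge_density(lum, zone)
    raise KeyError(f"unknown landscape metric {metric!r}")


def _zone_metric_values(
    lum: LandUseMap, zone: Polygon, metrics: list[str],
    dom_rasters: dict[str, Raster],
) -> dict[str, float]:
    """All requested metrics for one zone, rasterizing the zone only once."""
    out: dict[str, float] = {}
    raster_needed = [
        m for m in metrics
        if m in AREA_CLASS_CODES or m in CROP_CLASSES or m in INDEX_METRICS
    ]
    if raster_needed:
        raster = lum.landuse
        mask, (r0, r1, c0, c1) = _zone_mask(raster, zone)
        sub = raster.data[r0:r1, c0:c1]
        cells = sub[mask]
        n_cells = len(cells)
        codes, counts = np.unique(cells, return_counts=True)
        count_of = dict(zip(codes.tolist(), counts.tolist()))
        for m in raster_needed:
            if m in AREA_CLASS_CODES:
                out[m] = count_of.get(AREA_CLASS_CODES[m], 0) / n_cells
            elif m in CROP_CLASSES:
                out[m] = float(dom_rasters[m].data[r0:r1, c0:c1][mask].mean())
            elif m == "LANDHET":
                p = counts / n_cells
                out[m] = float(-(p * np.log(p)).sum())
            elif m == "EDGEDEN":
                horiz = (sub[:, :-1] != sub[:, 1:]) & mask[:, :-1] & mask[:, 1:]
                vert = (sub[:-1, :] != sub[1:, :]) & mask[:-1, :] & mask[1:, :]
                length = (horiz.sum() + vert.sum()) * raster.cell
                out[m] = float(length / (n_cells * raster.cell ** 2))
    for m in metrics:
        if m in LINEAR_CLASSES:
            out[m] = relative_linear_length(lum, zone, m)
    return out


def node_metrics(
    lum: LandUseMap,
    centres: Mapping[str, Sequence[float]],
    radii: Iterable[float],
    metrics: Iterable[str] | None = None,
    period: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Tidy node-level metric table: one row per (unit, metric, scale).

    ``unit`` is the population id, ``scale`` the buffer radius in metres.
    """
    metrics = list(metrics) if metrics is not None else all_metric_names()
    dom = {c: lum.dominance(c, period) for c in metrics if c in CROP_CLASSES}
    rows = []
    for unit, centre in centres.items():
        for radius in radii:
            zone = node_buffer(centre, radius)
            values = _zone_metric_values(lum, zone, metrics, dom)
            for metric in metrics:
                rows.append({
                    "unit": unit, "metric": metric,
                    "scale": f"{radius:g}",
                    "value": values[metric],
                    "level": "node", "window": lum.window_id,
                })
    return pd.DataFrame(rows)


def link_metrics(
    lum: LandUseMap,
    centres: Mapping[str, Sequence[float]],
    ratios: Iterable[float],
    metrics: Iterable[str] | None = None,
    period: tuple[int, int] | None = None,
    include_distance: bool = True,
) -> pd.DataFrame:
    """Tidy link-level metric table over all population pairs within the window.

    ``unit`` is "popA|popB" with the pair in sorted order; ``scale`` the
    width-to-length ratio label.  Geographic distance between the centres is
    appended as an extra scale-free candidate metric (scale ``"-"``).
    """
    metrics = list(metrics) if metrics is not None else all_metric_names()
    dom = {c: lum.dominance(c, period) for c in metrics if c in CROP_CLASSES}
    units = sorted(centres)
    rows = []
    for i, a in enumerate(units):
        for b in units[i + 1:]:
            unit = f"{a}|{b}"
            for ratio in ratios:
                label = LINK_RATIO_LABELS.get(ratio, f"{ratio:g}")
                zone = link_strip(centres[a], centres[b], ratio)
                values = _zone_metric_values(lum, zone, metrics, dom)
                for metric in metrics:
                    rows.append({
                        "unit": unit, "metric": metric, "scale": label,
                        "value": values[metric],
                        "level": "link", "window": lum.window_id,
                    })
            if include_distance:
                rows.append({
                    "unit": unit, "metric": "DISTANCE", "scale": "-",
                    "value": geographic_distance(centres[a], centres[b]),
                    "level": "link", "window": lum.window_id,
                })
    return pd.DataFrame(rows)


def metric_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy metric table to columns named ``<METRIC><scale>``.

    E.g. MAIZE at the 2000 m buffer becomes column ``MAIZE2000``; at the 1:7
    strip ratio, ``MAIZE1to7``.  Rows are indexed by unit (with the window
    carried along).
    """
    t = table.copy()
    t["name"] = np.where(
        t["scale"] == "-", t["metric"], t["metric"] + t["scale"].astype(str)
    )
    wide = t.pivot_table(index=["window", "unit"], columns="name",
                         values="value", aggfunc="first")
    wide.columns.name = None
    return wide.reset_index()
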