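"""Columnar assignment, the normalized polar column frame, and map topography.

Positions live in a right-handed µm frame. "Column radius along a vector" is
the centroid-to-boundary ray-intersection distance of the column polygon, so
normalized radius 1 always lies on the boundary regardless of column shape.
Angles are degrees counterclockwise; the 8 centroid-to-neighbor-centroid
directions define canonical 45° sectors in the normalized frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import LineString, Point

from .data_model import (
    AnalysisConfig,
    BarrelColumn,
    BarrelMap,
    GeometryError,
    NormalizedPosition,
    RoiRecord,
    WhiskerId,
)

__all__ = [
    "assign_column",
    "column_radius",
    "normalize_position",
    "EnsembleStats",
    "ensemble_topography",
    "gradient_regression",
    "assign_columns",
]

SEPTAL = "septal"
EXCLUDED = "excluded"


def column_radius(column: BarrelColumn, direction: np.ndarray,
                  barrel_map: BarrelMap | None = None) -> float:
    """Centroid-to-boundary distance along ``direction`` (µm).

    With a concave boundary the ray may cross twice; the nearest intersection
    is used.
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.hypot(*direction)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    unit = direction / norm
    cx, cy = column.centroid
    minx, miny, maxx, maxy = column.boundary.bounds
    reach = 4.0 * max(maxx - minx, maxy - miny, 1.0)
    ray = LineString([(cx, cy), (cx + unit[0] * reach, cy + unit[1] * reach)])
    inter = ray.intersection(column.boundary.exterior)
    if inter.is_empty:
        raise GeometryError(
            f"ray from centroid of {column.whisker} misses its boundary"
        )
    pts = []
    for geom in getattr(inter, "geoms", [inter]):
        if isinstance(geom, Point):
            pts.append((geom.x, geom.y))
        else:  # a collinear segment: use its nearest endpoint
            pts.extend(list(geom.coords))
    dists = [np.hypot(px - cx, py - cy) for px, py in pts]
    return float(min(d for d in dists if d > 1e-12))


def normalized_radius(position, column: BarrelColumn) -> float:
    """Distance from the column centroid in units of column radii."""
    cx, cy = column.centroid
    v = np.array([position[0] - cx, position[1] - cy], dtype=float)
    dist = float(np.hypot(*v))
    if dist == 0:
        return 0.0
    return dist / column_radius(column, v)


def scaled_boundary(column: BarrelColumn, factor: float):
    """Column polygon scaled about its centroid.

    Because normalized radius is the centroid-ray distance ratio, a point has
    normalized radius ≤ f exactly when it lies inside the f-scaled polygon
    (polygons are star-shaped about their centroid).
    """
    from shapely import affinity

    return affinity.scale(column.boundary, xfact=factor, yfact=factor,
                          origin=column.centroid)


def assign_column(roi: RoiRecord, barrel_map: BarrelMap,
                  config: AnalysisConfig | None = None):
    """Column :class:`WhiskerId`, ``"septal"`` or ``"excluded"`` for one ROI.

    Inside a column polygon → that column. Outside all polygons but within
    the inclusion radius (default 1.25 column radii) of some stimulated
    column → septal. Otherwise excluded from analysis.
    """
    config = config or AnalysisConfig()
    pt = Point(roi.x, roi.y)
    for col in barrel_map.columns:
        if col.boundary.covers(pt):
            return col.whisker
    for col in barrel_map.columns:
        if scaled_boundary(col, config.inclusion_radius).covers(pt):
            return SEPTAL
    return EXCLUDED


def assign_columns(rois, barrel_map: BarrelMap,
                   config: AnalysisConfig | None = None
                   ) -> dict[str, WhiskerId | str]:
    """Bulk :func:`assign_column`, vectorized over ROIs."""
    import shapely

    config = config or AnalysisConfig()
    rois = list(rois)
    x = np.array([r.x for r in rois])
    y = np.array([r.y for r in rois])
    out = np.full(len(rois), None, dtype=object)
    for col in barrel_map.columns:
        inside = shapely.contains_xy(col.boundary, x, y) | \
            shapely.intersects_xy(col.boundary, x, y)
        out[inside & (out == None)] = col.whisker  # noqa: E711
    unassigned = out == None  # noqa: E711
    if unassigned.any():
        septal = np.zeros(len(rois), dtype=bool)
        for col in barrel_map.columns:
            geom = scaled_boundary(col, config.inclusion_radius)
            septal |= shapely.intersects_xy(geom, x, y)
        out[unassigned & septal] = SEPTAL
        out[unassigned & ~septal] = EXCLUDED
    return {r.roi_id: out[i] for i, r in enumerate(rois)}


def _neighbor_frame(reference: WhiskerId, barrel_map: BarrelMap):
    """(physical angle, canonical angle) pairs for existing grid neighbors.

    Canonical angles: +arc direction is 0°, rows count upward C-over-E, so
    the offset (d_arc, d_row) maps to atan2(−d_row, d_arc) in 45° multiples.
    """
    ref = barrel_map.column(reference)
    rr, ra = reference.grid
    pairs = []
    for dr in (-1, 0, 1):
        for da in (-1, 0, 1):
            if dr == 0 and da == 0:
                continue
            r2, a2 = rr + dr, ra + da
            if not (0 <= r2 < 3 and 0 <= a2 < 3):
                continue
            try:
                nb = barrel_map.column(WhiskerId.from_grid(r2, a2))
            except KeyError:
                continue
            v = np.array(nb.centroid) - np.array(ref.centroid)
            phys = float(np.degrees(np.arctan2(v[1], v[0]))) % 360.0
            canon = float(np.degrees(np.arctan2(-dr, da))) % 360.0
            pairs.append((phys, canon))
    if len(pairs) < 2:
        raise GeometryError("reference column needs >=2 neighbors for angles")
    return sorted(pairs)


def normalize_position(roi, reference_column: WhiskerId,
                       barrel_map: BarrelMap) -> NormalizedPosition:
    """Polar position about a reference column in column-radius units.

    The angle is mapped piecewise-linearly so each centroid-to-neighbor
    direction lands on its canonical 45° sector angle, making maps from
    differently oriented or sheared fields comparable.
    """
    position = roi.position if isinstance(roi, RoiRecord) else tuple(roi)
    ref = barrel_map.column(reference_column)
    v = np.array(position, dtype=float) - np.array(ref.centroid)
    dist = float(np.hypot(*v))
    if dist == 0:
        return NormalizedPosition(reference_column, 0.0, 0.0)
    radius = dist / column_radius(ref, v)
    phys = float(np.degrees(np.arctan2(v[1], v[0]))) % 360.0
    pairs = _neighbor_frame(reference_column, barrel_map)
    phys_angles = [p for p, _ in pairs]
    canon_angles = [c for _, c in pairs]
    n = len(pairs)
    i = int(np.searchsorted(phys_angles, phys, side="right")) - 1
    if i < 0:
        i = n - 1
    j = (i + 1) % n
    span_phys = (phys_angles[j] - phys_angles[i]) % 360.0 or 360.0
    span_canon = (canon_angles[j] - canon_angles[i]) % 360.0 or 360.0
    t = ((phys - phys_angles[i]) % 360.0) / span_phys
    angle = (canon_angles[i] + t * span_canon) % 360.0
    return NormalizedPosition(reference_column, float(radius), float(angle))


@dataclass
class EnsembleStats:
    """Spatial statistics of one whisker's tuning ensemble."""

    whisker: str
    members: list[str]
    in_column_fraction: float
    radii: np.ndarray                # distance to BW column center, column radii
    circular_mean_deg: float
    resultant_length: float          # 0 = isotropic, 1 = all at one angle


def ensemble_topography(bw_by_roi: dict[str, str],
                        rois: dict[str, RoiRecord],
                        barrel_map: BarrelMap) -> dict[str, EnsembleStats]:
    """Per-whisker tuning-ensemble membership and spatial spread.

    An ensemble is every responsive cell whose nominal BW is that whisker,
    regardless of which column the cell sits in.
    """
    out: dict[str, EnsembleStats] = {}
    for col in barrel_map.columns:
        label = col.whisker.label
        members = [r for r, bw in bw_by_roi.items() if bw == label]
        if not members:
            continue
        radii = []
        angles = []
        inside = 0
        for roi_id in members:
            roi = rois[roi_id]
            np_pos = normalize_position(roi, col.whisker, barrel_map)
            radii.append(np_pos.radius)
            angles.append(np.radians(np_pos.angle))
            if col.boundary.covers(Point(roi.x, roi.y)):
                inside += 1
        z = np.mean(np.exp(1j * np.asarray(angles)))
        out[label] = EnsembleStats(
            whisker=label,
            members=members,
            in_column_fraction=inside / len(members),
            radii=np.asarray(radii),
            circular_mean_deg=float(np.degrees(np.angle(z)) % 360.0),
            resultant_length=float(np.abs(z)),
        )
    return out


def gradient_regression(x, y):
    """OLS of a per-cell quantity on distance-to-column-center.

    Returns (slope, intercept, t, p) with a two-sided t-test for non-zero
    slope. Degenerate x (zero variance) raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    res = stats.linregress(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return float(res.slope), float(res.intercept), float(t), float(res.pvalue)
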