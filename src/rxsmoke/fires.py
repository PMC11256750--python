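"""Prescribed-burn identification from satellite fire detections.

Satellite thermal-anomaly products (FINN-style) report individual fire
detections but do not say which are prescribed burns. The approach here:

1. drop detections on agricultural land (agricultural field burning is a
   separate source category);
2. aggregate the remainder into events by spatio-temporal proximity
   (connected components of the "within ``spatial_radius_km`` and within
   ``temporal_gap_days``" relation);
3. classify each event by duration — prescribed burns start and end on the
   same day, multi-day events are treated as wildfires;
4. calibrate the satellite-detected burned area of prescribed events
   against burn-permit records (the more trustworthy area source) with an
   ordinary least-squares line fitted at grid-cell level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy import stats

__all__ = [
    "AGRICULTURAL",
    "PRESCRIBED",
    "WILDFIRE",
    "FireDetection",
    "FireCluster",
    "AreaCalibration",
    "filter_agricultural",
    "cluster_detections",
    "classify_cluster",
    "fit_area_calibration",
    "apply_area_calibration",
]

logger = logging.getLogger(__name__)

AGRICULTURAL = "agricultural"
PRESCRIBED = "prescribed"
WILDFIRE = "wildfire"

#: one 4-km grid cell; the temporal link allows next-day detections to chain
DEFAULT_SPATIAL_RADIUS_KM = 4.0
DEFAULT_TEMPORAL_GAP_DAYS = 1


@dataclass(frozen=True)
class FireDetection:
    id: str
    x_km: float
    y_km: float
    date: pd.Timestamp
    detected_area: float  # acres
    landcover: str

    def __post_init__(self) -> None:
        if self.detected_area < 0:
            raise ValueError(
                f"detection {self.id}: detected_area must be >= 0, "
                f"got {self.detected_area}"
            )
        object.__setattr__(self, "date", pd.Timestamp(self.date))


@dataclass
class FireCluster:
    """A spatio-temporally aggregated fire event."""

    member_ids: tuple[str, ...]
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    centroid_x: float
    centroid_y: float
    total_detected_area: float
    label: str | None = None
    calibrated_area: float | None = None

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("cluster end_date precedes start_date")

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass(frozen=True)
class AreaCalibration:
    """OLS line mapping detected area to permit-reported area per cell."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("area calibration needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict(self, detected_area: float) -> float:
        return max(0.0, self.slope * detected_area + self.intercept)


def filter_agricultural(
    detections: list[FireDetection],
) -> tuple[list[FireDetection], list[FireDetection]]:
    """Split detections into (kept, removed-agricultural), order preserved."""
    kept = [d for d in detections if d.landcover != AGRICULTURAL]
    removed = [d for d in detections if d.landcover == AGRICULTURAL]
    return kept, removed


def cluster_detections(
    detections: list[FireDetection],
    spatial_radius_km: float = DEFAULT_SPATIAL_RADIUS_KM,
    temporal_gap_days: int = DEFAULT_TEMPORAL_GAP_DAYS,
) -> list[FireCluster]:
    """Group detections into events by spatio-temporal connectivity.

    Two detections are linked iff their planar distance is at most
    ``spatial_radius_km`` AND their dates differ by at most
    ``temporal_gap_days``; events are the connected components (transitive
    closure) of this relation. Every detection lands in exactly one event.
    """
    if not spatial_radius_km > 0:
        raise ValueError("spatial_radius_km must be > 0")
    if temporal_gap_days < 0:
        raise ValueError("temporal_gap_days must be >= 0")
    if not detections:
        return []

    xy = np.array([[d.x_km, d.y_km] for d in detections])
    days = np.array([d.date.toordinal() for d in detections])

    tree = cKDTree(xy)
    pairs = tree.query_pairs(spatial_radius_km, output_type="ndarray")
    if len(pairs):
        close_in_time = (
            np.abs(days[pairs[:, 0]] - days[pairs[:, 1]]) <= temporal_gap_days
        )
        pairs = pairs[close_in_time]
    n = len(detections)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(adj, directed=False)

    clusters: list[FireCluster] = []
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        members = [detections[i] for i in idx]
        areas = np.array([m.detected_area for m in members])
        total = float(areas.sum())
        # area-weighted centroid; plain mean when all areas are zero
        w = areas if total > 0 else np.ones(len(members))
        cx = float(np.average(xy[idx, 0], weights=w))
        cy = float(np.average(xy[idx, 1], weights=w))
        clusters.append(
            FireCluster(
                member_ids=tuple(m.id for m in members),
                start_date=min(m.date for m in members),
                end_date=max(m.date for m in members),
                centroid_x=cx,
                centroid_y=cy,
                total_detected_area=total,
            )
        )
    clusters.sort(key=lambda cl: (cl.start_date, cl.centroid_x, cl.centroid_y))
    logger.info("clustered %d detections into %d events", n, len(clusters))
    return clusters


def classify_cluster(cluster: FireCluster) -> str:
    """Duration rule: single-day events are prescribed, multi-day wildfires.

    Agricultural detections are assumed removed upstream; the rule only
    distinguishes prescribed burns from wildfires.
    """
    if not cluster.member_ids:
        raise ValueError("cannot classify an empty cluster")
    return WILDFIRE if cluster.duration_days > 1 else PRESCRIBED


def classify_clusters(clusters: list[FireCluster]) -> list[FireCluster]:
    """Return clusters with labels attached (non-mutating convenience)."""
    return [replace(c, label=classify_cluster(c)) for c in clusters]


def fit_area_calibration(
    pairs: list[tuple[float, float]],
) -> AreaCalibration:
    """OLS of permit-reported area on satellite-detected area, per grid cell.

    ``pairs`` holds ``(detected_area, permit_area)`` for cells with permit
    coverage. Rejects a degenerate design (fewer than two distinct detected
    areas).
    """
    if len(pairs) < 2:
        raise ValueError("area calibration needs >= 2 (detected, permit) pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(
            "degenerate design: all detected areas identical; cannot fit slope"
        )
    fit = stats.linregress(x, y)
    return AreaCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(pairs),
    )


def apply_area_calibration(
    clusters: list[FireCluster], cal: AreaCalibration
) -> list[FireCluster]:
    """Replace prescribed clusters' area by the calibrated prediction.

    Predictions are clamped at zero (negative burned area is unphysical);
    wildfire clusters are passed through untouched.
    """
    out = []
    for c in clusters:
        if c.label == PRESCRIBED:
            out.append(replace(c, calibrated_area=cal.predict(c.total_detected_area)))
        else:
            out.append(replace(c, calibrated_area=None))
    return out


def clusters_to_frame(clusters: list[FireCluster]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "cluster_id": i,
                "start": c.start_date.date().isoformat(),
                "end": c.end_date.date().isoformat(),
                "centroid_x_km": c.centroid_x,
                "centroid_y_km": c.centroid_y,
                "n_detections": len(c.member_ids),
                "area_acres_raw": c.total_detected_area,
                "area_acres_calibrated": (
                    c.calibrated_area if c.calibrated_area is not None else ""
                ),
                "label": c.label or "",
            }
        )
    return pd.DataFrame(rows)
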