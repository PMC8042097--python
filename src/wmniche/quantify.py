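"""Image-derived cell quantification metrics.

Operates on measurement tables exported from image analysis (cell
positions, nucleus radii, per-marker mean grey intensities, ROI labels,
axon traces, tumour-bulk outlines) — not on pixels. Implements the
percent-positive counting rules with minimum-cell ROI requirements,
nuclear-intensity tiering, the nucleus-to-axon contact rule, fluoromyelin
disruption scoring, invasion area/perimeter normalisation, migrated
distances and migration-track statistics.

All geometry is 2-D in micrometres with the image convention (y grows
downward); distances are Euclidean. Thresholds quoted as "<" are strict.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .containers import AxonPath, CellRecord, Track

__all__ = [
    "percent_positive",
    "tier_by_intensity",
    "axon_contact",
    "myelin_disruption",
    "invasion_metrics",
    "migrated_distances",
    "track_metrics",
]

log = logging.getLogger(__name__)


def _point_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    """Euclidean distance from a point to a polyline (segment-wise, exact)."""
    p = np.asarray(point, dtype=float)
    pts = np.asarray(polyline, dtype=float)
    a, b = pts[:-1], pts[1:]
    ab = b - a
    denom = (ab**2).sum(axis=1)
    t = np.zeros(len(a))
    nz = denom > 0
    t[nz] = ((p - a[nz]) * ab[nz]).sum(axis=1) / denom[nz]
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return float(np.sqrt(((closest - p) ** 2).sum(axis=1)).min())


# ---------------------------------------------------------------------------
# Percent positive
# ---------------------------------------------------------------------------

def percent_positive(
    cells: Sequence[CellRecord],
    marker: str,
    denominator_marker: str | None = None,
    min_cells: int = 750,
) -> pd.DataFrame:
    """Percentage of marker-positive cells per ROI, with minimum-cell rules.

    The denominator is the count of cells positive for
    ``denominator_marker`` (e.g. HuNu to restrict to tumour cells), or all
    cells when None. ROIs whose denominator falls below ``min_cells`` are
    excluded (logged, not an error). A pooled percentage across surviving
    ROIs is appended as ROI ``"pooled"``.
    """
    by_roi: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_roi.setdefault(c.roi, []).append(c)

    rows = []
    pooled_pos = pooled_den = 0
    for roi, members in by_roi.items():
        if denominator_marker is None:
            denom_cells = members
        else:
            denom_cells = [c for c in members if c.flags.get(denominator_marker, False)]
        n_den = len(denom_cells)
        if n_den < min_cells:
            log.info("percent_positive: ROI %r excluded (%d < %d denominator cells)", roi, n_den, min_cells)
            continue
        if n_den == 0:
            log.info("percent_positive: ROI %r skipped (zero denominator)", roi)
            continue
        n_pos = sum(1 for c in denom_cells if c.flags.get(marker, False))
        pooled_pos += n_pos
        pooled_den += n_den
        rows.append({"roi": roi, "n_positive": n_pos, "n_denominator": n_den,
                     "percent": 100.0 * n_pos / n_den})
    out = pd.DataFrame(rows)
    if pooled_den > 0:
        pooled = pd.DataFrame(
            [{"roi": "pooled", "n_positive": pooled_pos, "n_denominator": pooled_den,
              "percent": 100.0 * pooled_pos / pooled_den}]
        )
        out = pd.concat([out, pooled], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Intensity tiering
# ---------------------------------------------------------------------------

def tier_by_intensity(
    cells: Sequence[CellRecord],
    marker: str,
    mode: str = "percentile",
    reference_intensities: Sequence[float] | None = None,
    percentiles: tuple[float, float] = (25.0, 75.0),
    min_reference: int = 100,
    background: float | None = None,
    high_reference_intensities: Sequence[float] | None = None,
    min_high_reference: int = 20,
) -> pd.DataFrame:
    """Tier cells by nuclear mean grey value.

    percentile mode: thresholds are the 25th/75th percentiles of the
    reference nuclei intensities (>=100 nuclei from the tumour bulk);
    a cell is ``low`` when its intensity <= Q25, ``high`` when >= Q75,
    otherwise ``medium``.

    reference mode: ``negative`` below the background mean grey value
    (strict <); ``high`` at or above the minimum intensity of >20 manually
    flagged high-expressing cells; otherwise ``low``.
    """
    intens = np.array([c.intensities[marker] for c in cells], dtype=float)
    ids = [c.cell_id for c in cells]

    if mode == "percentile":
        if reference_intensities is None:
            reference_intensities = intens
        ref = np.asarray(reference_intensities, dtype=float)
        if len(ref) < min_reference:
            raise ValueError(
                f"percentile tiering needs >={min_reference} reference nuclei, got {len(ref)}"
            )
        q_low, q_high = np.percentile(ref, percentiles)
        labels = np.where(intens <= q_low, "low", np.where(intens >= q_high, "high", "medium"))
        thresholds = {"low": float(q_low), "high": float(q_high)}
    elif mode == "reference":
        if background is None:
            raise ValueError("reference tiering needs a background mean grey value")
        if high_reference_intensities is None or len(high_reference_intensities) <= min_high_reference:
            n = 0 if high_reference_intensities is None else len(high_reference_intensities)
            raise ValueError(
                f"reference tiering needs >{min_high_reference} flagged high cells, got {n}"
            )
        high_min = float(np.min(high_reference_intensities))
        labels = np.where(
            intens < background, "negative", np.where(intens >= high_min, "high", "low")
        )
        thresholds = {"background": float(background), "high": high_min}
    else:
        raise ValueError(f"unknown tiering mode {mode!r}")

    out = pd.DataFrame({"cell_id": ids, "intensity": intens, "tier": labels})
    out.attrs["thresholds"] = thresholds
    return out


# ---------------------------------------------------------------------------
# Axon contact
# ---------------------------------------------------------------------------

def axon_contact(
    cells: Sequence[CellRecord],
    axon_paths: Sequence[AxonPath],
    max_distance: float = 1.5,
) -> pd.Series:
    """Per-cell contact call: nucleus edge strictly closer than ``max_distance``.

    The nucleus is a disc of ``nucleus_radius`` around the cell position;
    contact holds when min over axon traces of (distance to trace minus
    radius) < ``max_distance``. A nucleus overlapping the trace has negative
    edge distance and always counts as contact.
    """
    if not axon_paths:
        log.warning("axon_contact: no axon paths supplied; all calls are False")
        return pd.Series([False] * len(cells), index=[c.cell_id for c in cells], name="contact")
    calls = []
    for c in cells:
        d = min(_point_polyline_distance(np.asarray(c.position), p.points) for p in axon_paths)
        calls.append((d - c.nucleus_radius) < max_distance)
    return pd.Series(calls, index=[c.cell_id for c in cells], name="contact")


# ---------------------------------------------------------------------------
# Myelin disruption
# ---------------------------------------------------------------------------

def myelin_disruption(
    roi_mean_grey: float,
    roi_max_grey: float,
    contralateral_normalised: float | None = None,
    fraction: float = 0.25,
    has_axons: bool = True,
) -> dict:
    """Normalise fluoromyelin intensity and score disruption.

    The ROI mean grey value is normalised to its max grey value to absorb
    image-to-image intensity variation. A white matter ROI is disrupted
    when it contains axons AND its normalised intensity is strictly below
    ``fraction`` of the contralateral intact reference. Without a
    contralateral reference, only the normalised intensity is returned.
    """
    if roi_max_grey <= 0:
        raise ValueError("max grey value must be positive")
    normalised = roi_mean_grey / roi_max_grey
    if contralateral_normalised is None:
        return {"normalised_intensity": normalised, "disrupted": None}
    disrupted = bool(has_axons and normalised < fraction * contralateral_normalised)
    return {"normalised_intensity": normalised, "disrupted": disrupted}


# ---------------------------------------------------------------------------
# Invasion and migration
# ---------------------------------------------------------------------------

def migrated_distances(
    positions: np.ndarray, bulk_polygon: np.ndarray | Polygon
) -> np.ndarray:
    """Distance of each cell to the tumour-bulk edge; 0 for cells inside."""
    poly = bulk_polygon if isinstance(bulk_polygon, Polygon) else Polygon(np.asarray(bulk_polygon))
    if not poly.is_valid:
        raise ValueError("bulk polygon is not simple (self-intersecting)")
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    return np.array([poly.distance(Point(p)) for p in pts])


def invasion_metrics(
    tumour_cell_positions: np.ndarray,
    bulk_polygon: np.ndarray | Polygon,
    occupied_area: float | None = None,
) -> dict:
    """Invasion index (occupied area / bulk perimeter) and migrated distances.

    The area occupied by tumour cells defaults to the convex hull of the
    cell positions; a caller-supplied mask area can replace it. Normalising
    by the bulk perimeter compensates for different rates of tumour growth.
    """
    poly = bulk_polygon if isinstance(bulk_polygon, Polygon) else Polygon(np.asarray(bulk_polygon))
    if not poly.is_valid:
        raise ValueError("bulk polygon is not simple (self-intersecting)")
    pts = np.atleast_2d(np.asarray(tumour_cell_positions, dtype=float))
    distances = migrated_distances(pts, poly)
    if occupied_area is None:
        if len(pts) < 3:
            log.warning("invasion_metrics: <3 positions; hull area undefined")
            occupied_area = np.nan
        else:
            occupied_area = MultiPoint([tuple(p) for p in pts]).convex_hull.area
    index = occupied_area / poly.length if np.isfinite(occupied_area) else np.nan
    return {
        "occupied_area": occupied_area,
        "bulk_perimeter": poly.length,
        "invasion_index": index,
        "migrated_distances": distances,
    }


def track_metrics(tracks: Sequence[Track]) -> pd.DataFrame:
    """Path length, net displacement, straightness and mean speed per track."""
    rows = []
    for tr in tracks:
        steps = np.sqrt((np.diff(tr.positions, axis=0) ** 2).sum(axis=1))
        path_length = float(steps.sum())
        displacement = float(np.sqrt(((tr.positions[-1] - tr.positions[0]) ** 2).sum()))
        elapsed = float(tr.times[-1] - tr.times[0])
        rows.append(
            {
                "cell_id": tr.cell_id,
                "path_length": path_length,
                "net_displacement": displacement,
                "straightness": displacement / path_length if path_length > 0 else 0.0,
                "mean_speed": path_length / elapsed,
            }
        )
    return pd.DataFrame(rows)
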