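"""Electron-microscopy myelin morphometry.

Feret (maximum caliper) diameters of axon and axon-plus-sheath contours,
g-ratios, decompaction / degeneration scoring and the g-ratio-versus-
diameter regression used to compare infiltrated and intact white matter.
Higher g-ratios mean thinner myelin relative to the axon, i.e.
demyelination.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .containers import AxonMeasurement

__all__ = [
    "feret_diameter",
    "g_ratio",
    "classify_axon",
    "gratio_trend",
    "measure_axons",
    "MIN_AXONS_PER_SAMPLE",
]

log = logging.getLogger(__name__)

MIN_AXONS_PER_SAMPLE = 50  # EM scoring convention; warn below this


def feret_diameter(points: np.ndarray) -> float:
    """Maximum caliper: the largest pairwise distance between contour points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("feret_diameter needs at least two 2-D points")
    if pts.shape[0] > 8:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (collinear) input: fall through to all pairs
            pass
    return float(pdist(pts).max())


def g_ratio(axon_feret: float, outer_feret: float, axon_id: str = "?") -> float:
    """Axon diameter over axon-plus-myelin diameter; 1.0 means a naked axon."""
    if axon_feret <= 0:
        raise ValueError(f"axon {axon_id}: axon diameter must be positive")
    if outer_feret < axon_feret:
        raise ValueError(
            f"axon {axon_id}: outer diameter {outer_feret} smaller than axon diameter {axon_feret}"
        )
    return axon_feret / outer_feret


def classify_axon(
    m: AxonMeasurement, decompaction_threshold: float = 0.15
) -> dict[str, bool]:
    """Score pathology flags for one axon.

    Decompacted when strictly more than ``decompaction_threshold`` of the
    circumference shows myelin decompaction; degenerating when any of the
    qualitative degeneration features is present.
    """
    return {
        "decompacted": m.decompacted_arc_fraction > decompaction_threshold,
        "degenerating": len(m.features) > 0,
    }


def measure_axons(
    axons: list[AxonMeasurement],
    decompaction_threshold: float = 0.15,
) -> pd.DataFrame:
    """Per-axon Ferets, g-ratio and pathology flags for a measurement set.

    Contour-based measurements take precedence; otherwise pre-measured Feret
    diameters are used as recorded. Emits a warning (not an error) when a
    condition group holds fewer than 50 axons, the usual minimum for EM
    scoring.
    """
    rows = []
    for m in axons:
        if m.axon_contour is not None and m.outer_contour is not None:
            af = feret_diameter(m.axon_contour)
            of = feret_diameter(m.outer_contour)
        elif m.axon_feret is not None and m.outer_feret is not None:
            af, of = float(m.axon_feret), float(m.outer_feret)
        else:
            raise ValueError(f"axon {m.axon_id}: needs contours or both Feret diameters")
        flags = classify_axon(m, decompaction_threshold)
        rows.append(
            {
                "axon_id": m.axon_id,
                "condition": m.condition,
                "axon_feret": af,
                "outer_feret": of,
                "g_ratio": g_ratio(af, of, m.axon_id),
                "decompacted": flags["decompacted"],
                "degenerating": flags["degenerating"],
            }
        )
    out = pd.DataFrame(rows)
    for cond, grp in out.groupby("condition"):
        if len(grp) < MIN_AXONS_PER_SAMPLE:
            warnings.warn(
                f"condition {cond!r} has only {len(grp)} axons (<{MIN_AXONS_PER_SAMPLE})",
                stacklevel=2,
            )
    return out


def gratio_trend(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-condition OLS fit of g-ratio against axon diameter.

    Input is the ``measure_axons`` table. Returns one row per condition with
    slope, intercept, R^2, mean g-ratio and axon count; conditions with
    constant diameters get NaN slope and a ``degenerate_x`` flag.
    """
    rows = []
    for cond, grp in measurements.groupby("condition"):
        if len(grp) < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 axons")
        x = grp["axon_feret"].to_numpy()
        y = grp["g_ratio"].to_numpy()
        if np.ptp(x) == 0:
            rows.append(
                {"condition": cond, "slope": np.nan, "intercept": np.nan, "r_squared": np.nan,
                 "mean_g_ratio": y.mean(), "n": len(grp), "degenerate_x": True}
            )
            continue
        if np.ptp(y) == 0:
            # constant response: flat line fits exactly but r is undefined; report 0
            rows.append(
                {"condition": cond, "slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0,
                 "mean_g_ratio": y.mean(), "n": len(grp), "degenerate_x": False}
            )
            continue
        fit = stats.linregress(x, y)
        rows.append(
            {
                "condition": cond,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.rvalue**2,
                "mean_g_ratio": y.mean(),
                "n": len(grp),
                "degenerate_x": False,
            }
        )
    return pd.DataFrame(rows)
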