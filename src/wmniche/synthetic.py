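"""Synthetic-data generators with recorded ground truth.

Every downstream stage of the pipeline (signature derivation, differential
expression, morphometry, cell quantification) is exercised against data
produced here, so each generator returns both the dataset and a truth object
recording exactly what was planted.

A single global seed is expanded into independent per-generator substreams
by fixed offsets, so adding a generator never perturbs another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    AxonMeasurement,
    AxonPath,
    CellRecord,
    CountMatrix,
    ExpressionMatrix,
)

__all__ = [
    "AtlasTruth",
    "RegionTruth",
    "generate_reference_atlas",
    "generate_region_counts",
    "generate_axon_set",
    "generate_cell_field",
]

# Fixed substream offsets: rng(seed, offset) is independent across generators.
_ATLAS_STREAM = 11
_COUNTS_STREAM = 23
_AXON_STREAM = 37
_CELLS_STREAM = 53

REGIONS = ("Bulk", "CC", "ST")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


# ---------------------------------------------------------------------------
# Reference atlas
# ---------------------------------------------------------------------------

@dataclass
class AtlasTruth:
    """What was planted in a synthetic reference atlas.

    ``marker_assignment`` maps each gene to its cell type or ``"none"`` for
    background genes. ``marker_effect`` is the log2-scale elevation of a
    marker in its own cell type; ``noise_sd`` the log2-scale dispersion of
    every value.
    """

    marker_assignment: dict[str, str]
    n_cell_types: int
    n_replicates_per_type: int
    marker_effect: float
    noise_sd: float
    cell_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("atlas needs at least 2 cell types")
        if self.n_replicates_per_type < 2:
            raise ValueError("atlas needs at least 2 replicates per cell type")
        if self.marker_effect <= 0:
            raise ValueError("marker_effect must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def markers_of(self, cell_type: str) -> set[str]:
        return {g for g, t in self.marker_assignment.items() if t == cell_type}


def generate_reference_atlas(
    n_cell_types: int = 3,
    markers_per_type: int = 50,
    n_background: int = 500,
    n_replicates: int = 3,
    marker_effect: float = 2.0,
    noise_sd: float = 0.5,
    base_log2_range: tuple[float, float] = (2.0, 6.0),
    seed: int = 0,
) -> tuple[ExpressionMatrix, AtlasTruth]:
    """Simulate a brain cell-type expression atlas with planted marker blocks.

    Values are expression-scale (FPKM-like): each gene has a log2 baseline
    drawn uniformly from ``base_log2_range``; markers gain ``marker_effect``
    log2 units in their own cell type; every value receives multiplicative
    log-normal noise of ``noise_sd`` log2 units.
    """
    cell_types = [f"type{i + 1}" for i in range(n_cell_types)]
    marker_assignment: dict[str, str] = {}
    genes: list[str] = []
    for t_idx, ct in enumerate(cell_types):
        for m in range(markers_per_type):
            g = f"MK{t_idx + 1}_{m + 1}"
            genes.append(g)
            marker_assignment[g] = ct
    for b in range(n_background):
        g = f"BG_{b + 1}"
        genes.append(g)
        marker_assignment[g] = "none"

    truth = AtlasTruth(
        marker_assignment=marker_assignment,
        n_cell_types=n_cell_types,
        n_replicates_per_type=n_replicates,
        marker_effect=marker_effect,
        noise_sd=noise_sd,
        cell_types=cell_types,
    )

    rng = _rng(seed, _ATLAS_STREAM)
    n_genes = len(genes)
    base = rng.uniform(*base_log2_range, size=n_genes)

    cols: dict[str, np.ndarray] = {}
    for ct in cell_types:
        is_marker = np.array([marker_assignment[g] == ct for g in genes])
        mean_log2 = base + np.where(is_marker, marker_effect, 0.0)
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else 0.0
            cols[f"{ct}:{rep}"] = np.exp2(mean_log2 + noise)

    matrix = ExpressionMatrix(pd.DataFrame(cols, index=genes))
    return matrix, truth


# ---------------------------------------------------------------------------
# Region count matrices
# ---------------------------------------------------------------------------

@dataclass
class RegionTruth:
    """Planted differential expression for Bulk/CC/ST count libraries.

    ``de_assignment`` maps gene -> (region, direction, log2 effect); the
    expected fold change of a planted gene in its region relative to Bulk is
    ``2**log2_effect`` (negative effects encode down-regulation).
    ``planted_signature_links`` optionally names the signature a planted
    gene subset was drawn from, for the enrichment-detection checks.
    """

    de_assignment: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    planted_signature_links: dict[str, list[str]] = field(default_factory=dict)
    library_size_factors: dict[str, float] = field(default_factory=dict)
    dispersion: float | dict[str, float] = 0.1

    def __post_init__(self) -> None:
        for g, (region, direction, eff) in self.de_assignment.items():
            if region not in ("CC", "ST"):
                raise ValueError(f"planted gene {g}: region must be CC or ST")
            if direction not in ("up", "down"):
                raise ValueError(f"planted gene {g}: direction must be up or down")
            if not math.isfinite(eff):
                raise ValueError(f"planted gene {g}: effect must be finite")
        disps = (
            self.dispersion.values() if isinstance(self.dispersion, dict) else [self.dispersion]
        )
        for a in disps:
            if a <= 0:
                raise ValueError("dispersion must be positive")
        for s, f in self.library_size_factors.items():
            if f <= 0:
                raise ValueError(f"size factor for {s} must be positive")

    def effect_of(self, gene: str) -> float:
        region, direction, eff = self.de_assignment[gene]
        return eff if direction == "up" else -eff


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with variance mu + alpha * mu**2."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_region_counts(
    truth: RegionTruth,
    n_genes: int = 2000,
    n_per_region: int = 3,
    base_mean_range: tuple[float, float] = (20.0, 2000.0),
    genes: list[str] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, RegionTruth]:
    """Simulate Bulk/CC/ST RNA-seq libraries with planted regional effects.

    Gene names default to ``G0001``-style ids unless an explicit ``genes``
    list is given (e.g. to share a namespace with an atlas); planted genes
    named in ``truth.de_assignment`` are honoured whether or not they follow
    that scheme (extra names extend the matrix). Baseline means are
    log-uniform over ``base_mean_range``; counts are NB with variance
    mu + alpha*mu^2.
    """
    if n_per_region < 2:
        raise ValueError("need at least 2 replicates per region")
    rng = _rng(seed, _COUNTS_STREAM)

    if genes is None:
        genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    else:
        genes = list(genes)
    extra = [g for g in truth.de_assignment if g not in set(genes)]
    genes = genes + sorted(extra)

    lo, hi = base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))

    samples = [f"{region}:{rep}" for region in REGIONS for rep in range(1, n_per_region + 1)]
    size_factors = {s: truth.library_size_factors.get(s, 1.0) for s in samples}
    truth.library_size_factors = size_factors

    def alpha_of(gene: str) -> float:
        if isinstance(truth.dispersion, dict):
            return truth.dispersion.get(gene, 0.1)
        return truth.dispersion

    lfc = {region: np.zeros(len(genes)) for region in REGIONS}
    for i, g in enumerate(genes):
        if g in truth.de_assignment:
            region, direction, eff = truth.de_assignment[g]
            lfc[region][i] = eff if direction == "up" else -eff

    cols: dict[str, np.ndarray] = {}
    alphas = np.array([alpha_of(g) for g in genes])
    for s in samples:
        region = s.split(":")[0]
        mu = base * np.exp2(lfc[region]) * size_factors[s]
        # draw per unique dispersion value to keep the vectorised NB sampler
        col = np.empty(len(genes), dtype=np.int64)
        for a in np.unique(alphas):
            m = alphas == a
            col[m] = _nb_draw(rng, mu[m], float(a))
        cols[s] = col

    return CountMatrix(pd.DataFrame(cols, index=genes)), truth


# ---------------------------------------------------------------------------
# Axon sets
# ---------------------------------------------------------------------------

def _ellipse_polygon(
    center: np.ndarray, a: float, b: float, angle: float, n_points: int = 48
) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return pts @ rot.T + center


def generate_axon_set(
    n: int = 60,
    radius_range: tuple[float, float] = (0.3, 1.2),
    myelin_thickness_range: tuple[float, float] = (0.1, 0.3),
    decompacted_fraction: float = 0.0,
    degenerating_fraction: float = 0.0,
    eccentricity: float = 0.2,
    condition: str = "intact",
    seed: int = 0,
) -> tuple[list[AxonMeasurement], dict]:
    """Simulate myelinated axon cross-sections as elliptical polygon contours.

    The outer contour is the axon ellipse dilated by a uniform myelin
    thickness. Exactly ``round(n * fraction)`` axons carry decompaction arcs
    above the 15% scoring threshold, and likewise for degeneration features.
    """
    if radius_range[0] <= 0 or myelin_thickness_range[0] <= 0:
        raise ValueError("radius and myelin thickness ranges must be positive")
    if not (0 <= decompacted_fraction <= 1 and 0 <= degenerating_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")

    rng = _rng(seed, _AXON_STREAM)
    n_decomp = round(n * decompacted_fraction)
    n_degen = round(n * degenerating_fraction)
    decomp_ids = set(rng.choice(n, size=n_decomp, replace=False).tolist()) if n_decomp else set()
    degen_ids = set(rng.choice(n, size=n_degen, replace=False).tolist()) if n_degen else set()
    feature_pool = sorted(
        ["condensed axoplasm", "organelle accumulation", "axonal swelling", "vacuoles",
         "dark axoplasm"]
    )

    axons: list[AxonMeasurement] = []
    for i in range(n):
        r = rng.uniform(*radius_range)
        t = rng.uniform(*myelin_thickness_range)
        ecc = rng.uniform(0.0, eccentricity)
        angle = rng.uniform(0.0, np.pi)
        center = rng.uniform(0.0, 50.0, size=2)
        a, b = r, r * (1.0 - ecc)
        if i in decomp_ids:
            arc = rng.uniform(0.16, 0.60)  # above the 15% threshold
        else:
            arc = rng.uniform(0.0, 0.14)  # below it
        features = frozenset([feature_pool[rng.integers(len(feature_pool))]]) if i in degen_ids else frozenset()
        axons.append(
            AxonMeasurement(
                axon_id=f"ax{i + 1}",
                axon_contour=_ellipse_polygon(center, a, b, angle),
                outer_contour=_ellipse_polygon(center, a + t, b + t, angle),
                decompacted_arc_fraction=float(arc),
                features=features,
                condition=condition,
            )
        )
    truth = {
        "n_decompacted": n_decomp,
        "n_degenerating": n_degen,
        "decompacted_ids": sorted(f"ax{i + 1}" for i in decomp_ids),
        "degenerating_ids": sorted(f"ax{i + 1}" for i in degen_ids),
    }
    return axons, truth


# ---------------------------------------------------------------------------
# Cell fields
# ---------------------------------------------------------------------------

def generate_cell_field(
    n_cells: int = 200,
    positive_fraction_by_marker: dict[str, float] | None = None,
    intensity_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    axon_paths: list[AxonPath] | None = None,
    bulk_polygon: np.ndarray | None = None,
    field_size: tuple[float, float] = (200.0, 200.0),
    nucleus_radius_range: tuple[float, float] = (3.0, 5.0),
    contact_distance: float = 1.5,
    seed: int = 0,
) -> tuple[list[CellRecord], list[AxonPath], dict]:
    """Simulate a 2-D field of cells with marker intensities and axon paths.

    ``positive_fraction_by_marker`` fixes exactly ``round(n * f)`` positive
    cells per marker. ``intensity_params`` maps a marker to uniform intensity
    bands per tier, e.g. ``{"SOX10": {"negative": (0, 20), "low": (30, 50),
    "high": (80, 100)}}``; each cell's tier is recorded in the truth. Contact
    truth against ``axon_paths`` uses the nucleus-edge rule with the given
    strict distance threshold.
    """
    if positive_fraction_by_marker is None:
        positive_fraction_by_marker = {"SOX10": 0.4}
    for m, f in positive_fraction_by_marker.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"positive fraction for {m} must lie in [0, 1]")
    if intensity_params is None:
        intensity_params = {
            "SOX10": {"negative": (0.0, 20.0), "low": (30.0, 55.0), "high": (75.0, 100.0)}
        }

    rng = _rng(seed, _CELLS_STREAM)
    w, h = field_size
    positions = rng.uniform([0, 0], [w, h], size=(n_cells, 2))
    radii = rng.uniform(*nucleus_radius_range, size=n_cells)

    if axon_paths is None:
        axon_paths = []
        for _ in range(3):
            y0 = rng.uniform(0, h)
            xs = np.linspace(0, w, 12)
            ys = y0 + rng.normal(0, 2.0, size=len(xs)).cumsum() * 0.3
            axon_paths.append(AxonPath(np.column_stack([xs, ys])))

    flags: dict[str, np.ndarray] = {}
    for m, f in positive_fraction_by_marker.items():
        n_pos = round(n_cells * f)
        pos = np.zeros(n_cells, dtype=bool)
        pos[rng.choice(n_cells, size=n_pos, replace=False)] = True
        flags[m] = pos

    tier_truth: dict[str, list[str]] = {}
    intens: dict[str, np.ndarray] = {}
    overlap_warnings: list[str] = []
    for m, tiers in intensity_params.items():
        bands = sorted(tiers.items(), key=lambda kv: kv[1][0])
        for (n1, b1), (n2, b2) in zip(bands, bands[1:]):
            if b1[1] > b2[0]:
                overlap_warnings.append(f"{m}: tiers {n1} and {n2} overlap")
        pos = flags.get(m)
        labels: list[str] = []
        vals = np.empty(n_cells)
        positive_tiers = [t for t in tiers if t != "negative"] or list(tiers)
        for i in range(n_cells):
            if pos is not None and not pos[i] and "negative" in tiers:
                tier = "negative"
            else:
                tier = positive_tiers[rng.integers(len(positive_tiers))]
            lo, hi = tiers[tier]
            vals[i] = rng.uniform(lo, hi)
            labels.append(tier)
        tier_truth[m] = labels
        intens[m] = vals

    # contact truth: strict nucleus-edge rule against segment distances
    from .quantify import _point_polyline_distance  # local import avoids a cycle

    contact = np.zeros(n_cells, dtype=bool)
    if axon_paths:
        for i in range(n_cells):
            dmin = min(_point_polyline_distance(positions[i], p.points) for p in axon_paths)
            contact[i] = (dmin - radii[i]) < contact_distance

    cells = [
        CellRecord(
            cell_id=f"c{i + 1}",
            position=(float(positions[i, 0]), float(positions[i, 1])),
            nucleus_radius=float(radii[i]),
            intensities={m: float(v[i]) for m, v in intens.items()},
            flags={m: bool(v[i]) for m, v in flags.items()},
            roi="field",
        )
        for i in range(n_cells)
    ]
    truth = {
        "positive_counts": {m: int(v.sum()) for m, v in flags.items()},
        "tiers": tier_truth,
        "contact": contact.tolist(),
        "overlapping_tiers": overlap_warnings,
        "bulk_polygon": None if bulk_polygon is None else np.asarray(bulk_polygon).tolist(),
    }
    return cells, axon_paths, truth
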