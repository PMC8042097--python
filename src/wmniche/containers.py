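"""Core in-memory containers shared across the pipeline.

Expression and count matrices are thin wrappers around a pandas DataFrame
whose columns follow the ``condition:replicate`` labelling convention used
throughout the package (e.g. ``CC:1``, ``oligodendrocyte:2``). Genes are
rows; the index holds gene symbols (upper-cased on construction when
``normalise_case`` is requested by callers that mix species).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledMatrix",
    "ExpressionMatrix",
    "CountMatrix",
    "GeneSignatureSet",
    "DEResult",
    "AxonMeasurement",
    "CellRecord",
    "AxonPath",
    "Track",
    "split_label",
]

DEGENERATION_FEATURES = frozenset(
    {
        "condensed axoplasm",
        "organelle accumulation",
        "axonal swelling",
        "vacuoles",
        "dark axoplasm",
    }
)


def split_label(label: str) -> tuple[str, str]:
    """Split a ``condition:replicate`` sample label into its two parts."""
    if ":" not in label:
        raise ValueError(f"sample label {label!r} is not of the form 'condition:replicate'")
    cond, rep = label.split(":", 1)
    return cond, rep


class LabeledMatrix:
    """Gene-by-sample matrix with ``condition:replicate`` column labels."""

    def __init__(self, data: pd.DataFrame):
        if data.shape[1] == 0:
            raise ValueError("matrix has no samples")
        for c in data.columns:
            split_label(str(c))
        if not np.all(np.isfinite(data.to_numpy(dtype=float))):
            raise ValueError("matrix contains non-finite values")
        self.data = data.copy()
        self.data.columns = [str(c) for c in data.columns]
        self.data.index = [str(g) for g in data.index]

    # -- basic structure -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_labels(self) -> list[tuple[str, str]]:
        return [split_label(c) for c in self.data.columns]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for cond, _ in self.sample_labels:
            if cond not in seen:
                seen.append(cond)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        return [c for c in self.data.columns if split_label(c)[0] == condition]

    def condition_means(self) -> pd.DataFrame:
        """Average replicate columns within each condition (column order kept)."""
        out = {cond: self.data[self.samples_for(cond)].mean(axis=1) for cond in self.conditions}
        return pd.DataFrame(out, index=self.data.index)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.data.shape
        return f"<{type(self).__name__} {g} genes x {s} samples, {len(self.conditions)} conditions>"


class ExpressionMatrix(LabeledMatrix):
    """Continuous, non-negative expression values (FPKM-like atlas scale)."""

    def __init__(self, data: pd.DataFrame):
        super().__init__(data)


class CountMatrix(LabeledMatrix):
    """Integer read counts from bulk RNA-seq libraries."""

    def __init__(self, data: pd.DataFrame):
        arr = data.to_numpy()
        if not np.allclose(arr, np.round(np.asarray(arr, dtype=float))):
            raise ValueError("count matrix must contain integers")
        if (np.asarray(arr, dtype=float) < 0).any():
            raise ValueError("count matrix must be non-negative")
        super().__init__(data.round().astype(np.int64))


@dataclass
class GeneSignatureSet:
    """Named gene lists marking cell types or states (GMT-serialisable)."""

    signatures: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if len(genes) == 0:
                raise ValueError(f"signature {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.signatures)

    def __getitem__(self, name: str) -> list[str]:
        return self.signatures[name]

    def __iter__(self):
        return iter(self.signatures)

    def items(self):
        return self.signatures.items()


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one comparison.

    ``table`` is indexed by gene with columns ``base_mean``, ``log2_ratio``,
    ``p`` and ``p_adj``. Genes with zero counts in both groups carry NaN
    statistics and are excluded from the multiple-testing denominator.
    """

    comparison: tuple[str, str]  # (reference, test) e.g. ("Bulk", "CC")
    table: pd.DataFrame

    def significant(self, alpha: float = 0.05, lfc_min: float = 0.0) -> pd.DataFrame:
        t = self.table
        mask = (t["p_adj"] < alpha) & (t["log2_ratio"].abs() > lfc_min)
        return t[mask.fillna(False)]


@dataclass
class AxonMeasurement:
    """A single EM-measured axon: geometry plus qualitative pathology flags."""

    axon_id: str
    axon_contour: np.ndarray | None = None  # (n, 2) points in um
    outer_contour: np.ndarray | None = None
    axon_feret: float | None = None
    outer_feret: float | None = None
    decompacted_arc_fraction: float = 0.0
    features: frozenset[str] = frozenset()
    condition: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.decompacted_arc_fraction <= 1.0:
            raise ValueError(f"axon {self.axon_id}: arc fraction must lie in [0, 1]")
        unknown = set(self.features) - DEGENERATION_FEATURES
        if unknown:
            raise ValueError(f"axon {self.axon_id}: unknown features {sorted(unknown)}")


@dataclass
class CellRecord:
    """One segmented cell: position, nucleus size, per-marker intensities."""

    cell_id: str
    position: tuple[float, float]
    nucleus_radius: float
    intensities: dict[str, float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)
    roi: str = ""

    def __post_init__(self) -> None:
        if self.nucleus_radius <= 0:
            raise ValueError(f"cell {self.cell_id}: nucleus radius must be positive")
        for marker, v in self.intensities.items():
            if v < 0:
                raise ValueError(f"cell {self.cell_id}: negative intensity for {marker}")


@dataclass
class AxonPath:
    """Polyline trace of a neurofilament-positive axon (um coordinates)."""

    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValueError("axon path needs at least two 2-D points")


@dataclass
class Track:
    """Time-ordered positions of one migrating cell."""

    cell_id: str
    times: np.ndarray
    positions: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions differ in length")
        if len(self.times) < 2:
            raise ValueError("track needs at least two time points")
        d = np.diff(self.times)
        if (d == 0).any():
            raise ValueError(f"track {self.cell_id}: duplicate timestamps")
        if (d < 0).any():
            raise ValueError(f"track {self.cell_id}: timestamps must increase")


def cells_to_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    """Flatten CellRecords into a tidy DataFrame (one row per cell)."""
    rows = []
    for c in cells:
        row: dict = {
            "cell_id": c.cell_id,
            "x": c.position[0],
            "y": c.position[1],
            "nucleus_radius": c.nucleus_radius,
            "roi": c.roi,
        }
        for m, v in c.intensities.items():
            row[f"intensity_{m}"] = v
        for m, v in c.flags.items():
            row[f"flag_{m}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
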