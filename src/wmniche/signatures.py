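"""Cell-type gene-signature derivation from a reference expression atlas.

The workflow mirrors how brain cell-type signatures are built from bulk
atlases (human and mouse cortical purification datasets): duplicate entries
averaged, low-coverage genes removed, replicates averaged per cell type,
rows median-centred, the most variable genes selected by coefficient of
variation, K-means clustered, and clusters with good single-cell-type
discrimination promoted to signatures.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix, GeneSignatureSet

__all__ = [
    "preprocess_atlas",
    "select_variable_genes",
    "derive_signatures",
    "read_gmt",
    "write_gmt",
]

log = logging.getLogger(__name__)


def _collapse_duplicates(data: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene id, keeping first-occurrence order."""
    if data.index.is_unique:
        return data
    order = list(dict.fromkeys(data.index))
    return data.groupby(level=0, sort=False).mean().loc[order]


def preprocess_atlas(
    matrix: ExpressionMatrix,
    low_coverage_min: float = 1.0,
    log2_transform: bool = True,
) -> ExpressionMatrix:
    """Collapse duplicates, drop low-coverage genes, average replicates, centre.

    A gene is low-coverage when its maximum condition mean (on the input
    scale) falls below ``low_coverage_min``. After filtering, replicates are
    averaged per condition, values optionally moved to log2(x + 1), and each
    gene row is median-centred so that cross-cell-type contrasts, not
    absolute abundance, drive the downstream clustering.
    """
    data = _collapse_duplicates(matrix.data)
    m = ExpressionMatrix(data)
    cond_means = m.condition_means()
    keep = cond_means.max(axis=1) >= low_coverage_min
    if not keep.any():
        raise ValueError(
            f"no gene passes the low-coverage cutoff {low_coverage_min}; "
            "check the expression scale of the atlas"
        )
    dropped = int((~keep).sum())
    if dropped:
        log.info("preprocess_atlas: dropped %d low-coverage genes (< %s)", dropped, low_coverage_min)
    cond_means = cond_means[keep]
    if log2_transform:
        cond_means = np.log2(cond_means + 1.0)
    centred = cond_means.sub(cond_means.median(axis=1), axis=0)
    centred.columns = [f"{c}:avg" for c in centred.columns]
    return ExpressionMatrix(centred)


def select_variable_genes(matrix: ExpressionMatrix, cv_cutoff: float = 1.0) -> list[str]:
    """Return genes whose coefficient of variation across cell types exceeds the cutoff.

    The CV (sample sd / mean) is computed on condition-averaged values before
    any median-centring, since sd/mean requires a positive mean. Genes with
    non-positive mean are excluded and logged. Input order is preserved.
    """
    data = _collapse_duplicates(matrix.data)
    cond_means = ExpressionMatrix(data).condition_means()
    means = cond_means.mean(axis=1)
    sds = cond_means.std(axis=1, ddof=1)
    undefined = means <= 0
    if undefined.any():
        log.warning(
            "select_variable_genes: %d genes with non-positive mean excluded (CV undefined)",
            int(undefined.sum()),
        )
    cv = sds.where(~undefined) / means.where(~undefined)
    selected = cv > cv_cutoff
    return [g for g in cond_means.index if bool(selected.get(g, False))]


def derive_signatures(
    matrix: ExpressionMatrix,
    genes: list[str],
    k: int | None = None,
    margin: float = 0.5,
    seed: int = 0,
) -> GeneSignatureSet:
    """K-means cluster variable genes and keep clusters that discriminate one cell type.

    ``matrix`` is a preprocessed atlas (condition-averaged, centred). Genes
    are clustered on their centred condition profiles; a cluster becomes the
    signature of cell type T when its mean profile peaks at T and exceeds
    the runner-up condition by at least ``margin``. At most one cluster is
    assigned per cell type (largest margin wins); clusters that discriminate
    no single type are discarded.
    """
    missing = [g for g in genes if g not in set(matrix.gene_ids)]
    if missing:
        raise ValueError(f"{len(missing)} requested genes absent from matrix (e.g. {missing[:3]})")
    conditions = matrix.conditions
    if k is None:
        k = 2 * len(conditions)
    if k < len(conditions):
        raise ValueError(f"k={k} is below the number of cell types ({len(conditions)})")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the number of genes ({len(genes)})")

    profiles = matrix.data.loc[genes]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())

    # candidate (cell type, margin, cluster) assignments
    candidates: list[tuple[str, float, int]] = []
    for c in range(k):
        if not (labels == c).any():  # k-means may leave duplicates unfilled
            continue
        mean_profile = profiles.to_numpy()[labels == c].mean(axis=0)
        order = np.argsort(mean_profile)[::-1]
        best, second = mean_profile[order[0]], mean_profile[order[1]]
        if best - second >= margin:
            candidates.append((conditions[order[0]], best - second, c))

    assigned: dict[str, tuple[float, int]] = {}
    for ct, mg, c in candidates:
        if ct not in assigned or mg > assigned[ct][0]:
            assigned[ct] = (mg, c)

    if not assigned:
        log.warning("derive_signatures: no cluster passed the margin %.3g; empty signature set", margin)
        return GeneSignatureSet({}, provenance={"k": k, "margin": margin, "seed": seed})

    sigs = {
        ct: [g for g, lab in zip(genes, labels) if lab == cluster]
        for ct, (mg, cluster) in sorted(assigned.items())
    }
    return GeneSignatureSet(sigs, provenance={"k": k, "margin": margin, "seed": seed})


# ---------------------------------------------------------------------------
# GMT serialisation
# ---------------------------------------------------------------------------

def write_gmt(path: str | Path, signatures: GeneSignatureSet) -> None:
    """Write signatures as GMT: ``name<TAB>description<TAB>gene...`` per line."""
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            desc = str(signatures.provenance.get("source", "."))
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path, upper: bool = False) -> GeneSignatureSet:
    """Read a GMT file; duplicate signature names or short lines are errors."""
    sigs: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need name, description, genes)")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if upper:
                genes = [g.upper() for g in genes]
            if name in sigs:
                raise ValueError(f"{path}:{lineno}: duplicate signature name {name!r}")
            sigs[name] = genes
    return GeneSignatureSet(sigs, provenance={"source": str(path)})
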