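"""Single-gene cohort scoring and qPCR relative expression.

Covers the TCGA-style classification of tumours as SOX10-high from cohort
z-scores, and delta-Ct relative expression against a housekeeping gene
(GAPDH in the original assays).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["zscore_and_classify", "qpcr_relative_expression", "fold_change_over_control"]


def zscore_and_classify(
    values: pd.Series,
    threshold_z: float = 1.0,
    precomputed_z: bool = False,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Z-score a gene's expression across a cohort and call high expressors.

    A sample is labelled ``high`` when its z-score strictly exceeds
    ``threshold_z`` (default 1.0, under which a normal cohort yields a
    high-expressing subset of roughly 16%). Set ``precomputed_z`` when the
    input is already on the z scale (e.g. portal-downloaded z-scores).
    Optional ``annotations`` (e.g. transcriptional subtype) are passed
    through by sample id.
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 3:
        raise ValueError("cohort must contain at least 3 samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    if precomputed_z:
        z = values.copy()
    else:
        sd = values.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance across the cohort; z-scores undefined")
        z = (values - values.mean()) / sd
    out = pd.DataFrame({"z": z, "label": np.where(z > threshold_z, "high", "not-high")},
                       index=values.index)
    if annotations is not None:
        out = out.join(annotations, how="left")
    return out


def qpcr_relative_expression(
    ct_gene: float | np.ndarray | pd.Series,
    ct_reference: float | np.ndarray | pd.Series,
) -> float | np.ndarray | pd.Series:
    """Relative expression 2**-(Ct_gene - Ct_reference) against a housekeeper."""
    ct_gene = np.asarray(ct_gene, dtype=float) if not np.isscalar(ct_gene) else ct_gene
    if ct_reference is None:
        raise ValueError("reference Ct is required")
    gene_arr = np.asarray(ct_gene, dtype=float)
    ref_arr = np.asarray(ct_reference, dtype=float)
    if (gene_arr <= 0).any() or (ref_arr <= 0).any():
        raise ValueError("cycle-threshold values must be positive")
    result = 2.0 ** -(gene_arr - ref_arr)
    if np.isscalar(ct_gene) and np.isscalar(ct_reference):
        return float(result)
    return result


def fold_change_over_control(rel_expression, rel_expression_control):
    """Delta-delta-Ct style fold change: sample relative expression over control's."""
    control = np.asarray(rel_expression_control, dtype=float)
    if (control <= 0).any():
        raise ValueError("control relative expression must be positive")
    return np.asarray(rel_expression, dtype=float) / control
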