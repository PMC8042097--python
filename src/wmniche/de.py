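"""Region-specific differential expression, clustering and set enrichment.

Implements the bulk RNA-seq comparisons between tumour-bulk, corpus-callosum
and striatum libraries: count filtering, median-of-ratios normalisation, a
negative-binomial Wald test, K-means clustering of regulated genes on their
(CC, ST) log2-ratio profiles, and one-sided Fisher (hypergeometric) overlap
enrichment of gene groups against cell-type signatures.

The DE test is a deliberately transparent NB pipeline: per-gene dispersions
by method of moments with a floor, no shrinkage, no independent filtering.
Exact concordance with external tools is not promised beyond the size-factor
estimator and the count filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, DEResult, GeneSignatureSet

__all__ = [
    "filter_counts",
    "estimate_size_factors",
    "test_differential_expression",
    "select_and_cluster",
    "enrich",
    "signature_regulation_summary",
    "pca_samples",
    "adjust_pvalues",
]

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-4
PSEUDOCOUNT = 0.5


def filter_counts(counts: CountMatrix, min_count: int = 5, min_samples: int = 3) -> CountMatrix:
    """Keep genes with at least ``min_count`` counts in at least ``min_samples`` samples."""
    arr = counts.data.to_numpy()
    keep = (arr >= min_count).sum(axis=1) >= min_samples
    if not keep.any():
        log.warning("filter_counts: no gene passes (>=%d counts in >=%d samples)", min_count, min_samples)
    return CountMatrix(counts.data[keep])


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample, the factor is the median over genes (restricted to
    genes with a positive geometric mean across samples) of the ratio of
    that sample's count to the gene's geometric mean.
    """
    arr = counts.data.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    log_geomean = log_arr.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no gene is expressed in every sample; size factors undefined "
            "(filter the matrix or merge lanes first)"
        )
    ratios = np.exp(log_arr[usable] - log_geomean[usable, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.data.columns, name="size_factor")


def _group_columns(counts: CountMatrix, condition: str) -> list[str]:
    cols = counts.samples_for(condition)
    if len(cols) < 2:
        raise ValueError(f"condition {condition!r} has fewer than 2 replicates")
    return cols


def test_differential_expression(
    counts: CountMatrix,
    comparison: tuple[str, str],
    size_factors: pd.Series | None = None,
) -> DEResult:
    """NB Wald test of ``comparison = (reference, test)`` on a filtered matrix.

    Counts are size-factor normalised; per-gene dispersion alpha (variance
    mu + alpha*mu^2) is estimated by method of moments pooled across the two
    groups and floored at 1e-4. The Wald statistic is the log2 ratio of
    group means (pseudo-count 0.5) over its delta-method standard error;
    p-values are two-sided against a t reference with n_A + n_B - 2 degrees
    of freedom (the estimated standard error makes a plain normal reference
    anticonservative at typical replication) and BH-adjusted across tested
    genes.
    """
    ref, test = comparison
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    cols_a = _group_columns(counts, ref)
    cols_b = _group_columns(counts, test)

    q = counts.data.to_numpy(dtype=float) / size_factors.reindex(counts.data.columns).to_numpy()
    idx_a = [counts.data.columns.get_loc(c) for c in cols_a]
    idx_b = [counts.data.columns.get_loc(c) for c in cols_b]
    qa, qb = q[:, idx_a], q[:, idx_b]
    na, nb = qa.shape[1], qb.shape[1]
    inv_s = 1.0 / size_factors.to_numpy()
    ca = inv_s[idx_a].mean()
    cb = inv_s[idx_b].mean()

    mu_a = qa.mean(axis=1)
    mu_b = qb.mean(axis=1)
    va = qa.var(axis=1, ddof=1)
    vb = qb.var(axis=1, ddof=1)

    # method-of-moments dispersion pooled over both groups:
    # Var(K/s) ~= mu * mean(1/s) + alpha * mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (va - mu_a * ca) / mu_a**2
        alpha_b = (vb - mu_b * cb) / mu_b**2
    wa, wb = na - 1, nb - 1
    alpha_parts = []
    for alpha_i, mu_i, w in ((alpha_a, mu_a, wa), (alpha_b, mu_b, wb)):
        part = np.where(mu_i > 0, np.nan_to_num(alpha_i, nan=0.0), np.nan)
        alpha_parts.append((part, w))
    with np.errstate(invalid="ignore"):
        alpha = np.nansum([p * w for p, w in alpha_parts], axis=0) / np.nansum(
            [np.where(np.isnan(p), 0, w) for p, w in alpha_parts], axis=0
        )
    alpha = np.maximum(np.nan_to_num(alpha, nan=DISPERSION_FLOOR), DISPERSION_FLOOR)

    lfc = np.log2((mu_b + PSEUDOCOUNT) / (mu_a + PSEUDOCOUNT))

    var_mu_a = (mu_a * ca + alpha * mu_a**2) / na
    var_mu_b = (mu_b * cb + alpha * mu_b**2) / nb
    se_lfc = np.sqrt(
        var_mu_a / (mu_a + PSEUDOCOUNT) ** 2 + var_mu_b / (mu_b + PSEUDOCOUNT) ** 2
    ) / np.log(2.0)

    tested = (mu_a > 0) | (mu_b > 0)
    z = np.full(len(lfc), np.nan)
    valid = tested & (se_lfc > 0)
    z[valid] = lfc[valid] / se_lfc[valid]
    p = np.full(len(lfc), np.nan)
    p[valid] = 2.0 * stats.t.sf(np.abs(z[valid]), df=na + nb - 2)
    # tested genes with identical group means and zero variance: no evidence
    p[tested & ~valid] = 1.0

    p_adj = np.full(len(lfc), np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        p_adj[mask] = multipletests(p[mask], method="fdr_bh")[1]

    base_mean = q.mean(axis=1)
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_ratio": np.where(tested, lfc, np.nan),
            "p": p,
            "p_adj": p_adj,
        },
        index=counts.data.index,
    )
    return DEResult(comparison=comparison, table=table)


def select_and_cluster(
    de_cc: DEResult,
    de_st: DEResult,
    lfc_min: float = 0.58,
    alpha: float = 0.05,
    k: int = 7,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster regionally regulated genes on their (CC, ST) log2-ratio vectors.

    Genes passing ``p_adj < alpha`` and ``|log2_ratio| > lfc_min`` (both
    strict) in at least one comparison are K-means-clustered with ``k``
    clusters. Returns a table indexed by gene with the two ratios and the
    cluster label.
    """
    common = de_cc.table.index.intersection(de_st.table.index)
    if len(common) != len(de_cc.table) or len(common) != len(de_st.table):
        log.warning("select_and_cluster: comparisons share only %d genes", len(common))
    cc = de_cc.table.loc[common]
    st = de_st.table.loc[common]

    def passes(t: pd.DataFrame) -> pd.Series:
        return ((t["p_adj"] < alpha) & (t["log2_ratio"].abs() > lfc_min)).fillna(False)

    selected = passes(cc) | passes(st)
    n_sel = int(selected.sum())
    if n_sel < k:
        raise ValueError(
            f"only {n_sel} genes pass selection but k={k}; lower k or relax thresholds"
        )
    feats = pd.DataFrame(
        {"log2_ratio_cc": cc["log2_ratio"][selected], "log2_ratio_st": st["log2_ratio"][selected]}
    )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    feats["cluster"] = km.fit_predict(feats.to_numpy())
    return feats


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    raise ValueError(f"unknown correction {method!r} (use 'bh' or 'bonferroni')")


def enrich(
    gene_groups: dict[str, list[str]],
    signatures: GeneSignatureSet,
    universe: list[str],
    correction: str = "bh",
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper-tail) overlap enrichment.

    Each group and signature is intersected with the universe first. The
    p-value of a (group, signature) cell is P(X >= overlap) for X
    hypergeometric with population ``|universe|``, successes
    ``|signature & universe|`` and draws ``|group|``. Correction is applied
    across all cells of the matrix. ``pct_of_group`` is the percentage of
    the group's genes found in the signature.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty gene universe")
    uni_set = set(uni)
    rows = []
    for gname, glist in gene_groups.items():
        group = [g for g in dict.fromkeys(glist) if g in uni_set]
        if not group:
            raise ValueError(f"group {gname!r} is empty after intersecting with the universe")
        for sname, slist in signatures.items():
            sig = set(slist) & uni_set
            if not sig:
                log.warning("enrich: signature %r disjoint from universe", sname)
            overlap = len(set(group) & sig)
            M, K, N = len(uni_set), len(sig), len(group)
            p = float(stats.hypergeom.sf(overlap - 1, M, K, N)) if K else 1.0
            a = overlap
            b = N - overlap
            c = K - overlap
            d = M - N - K + overlap
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
            rows.append(
                {
                    "group": gname,
                    "signature": sname,
                    "overlap": overlap,
                    "group_size": N,
                    "signature_size": K,
                    "universe_size": M,
                    "odds_ratio": odds,
                    "pct_of_group": 100.0 * overlap / N,
                    "p": min(1.0, p),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method=correction)
    out["neg_log10_p_adj"] = -np.log10(out["p_adj"].clip(lower=np.finfo(float).tiny))
    return out


def signature_regulation_summary(
    de: DEResult, signatures: GeneSignatureSet, alpha: float = 0.1
) -> pd.DataFrame:
    """List significantly regulated member genes of each signature.

    Returns one row per (signature, regulated gene) with the log2 ratio and
    direction; signatures without a regulated member keep a placeholder row
    (gene NaN) so every signature appears in the table.
    """
    rows = []
    t = de.table
    for sname, genes in signatures.items():
        members = [g for g in genes if g in t.index]
        sub = t.loc[members]
        reg = sub[(sub["p_adj"] < alpha).fillna(False)]
        if len(reg) == 0:
            rows.append(
                {"signature": sname, "gene": np.nan, "log2_ratio": np.nan,
                 "p_adj": np.nan, "direction": ""}
            )
            continue
        for g, r in reg.iterrows():
            rows.append(
                {
                    "signature": sname,
                    "gene": g,
                    "log2_ratio": r["log2_ratio"],
                    "p_adj": r["p_adj"],
                    "direction": "up" if r["log2_ratio"] > 0 else "down",
                }
            )
    return pd.DataFrame(rows)


def pca_samples(
    counts: CountMatrix,
    n_top_genes: int = 500,
    size_factors: pd.Series | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(normalised count + 1) over the most variable genes.

    Returns per-sample coordinates (all PCs) and the variance fraction of
    each component. The sign of each PC is fixed by forcing its
    largest-magnitude gene loading positive, so results do not depend on
    SVD sign conventions.
    """
    if counts.data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    norm = counts.data.to_numpy(dtype=float) / size_factors.reindex(counts.data.columns).to_numpy()
    logd = np.log2(norm + 1.0)
    var = logd.var(axis=1)
    top = np.sort(np.argsort(var, kind="stable")[::-1][: min(n_top_genes, len(var))])
    x = logd[top].T  # samples x genes
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix sign per component by the largest-|loading| gene
    for j in range(len(s)):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    coords = u * s
    total = (s**2).sum()
    var_frac = s**2 / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{j + 1}" for j in range(coords.shape[1])]
    return pd.DataFrame(coords, index=counts.data.columns, columns=cols), var_frac
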