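"""End-to-end orchestration of the synthetic white-matter niche analysis.

A single :class:`RunConfig` holds every threshold of the pipeline with the
study's printed values as defaults; :func:`run_pipeline` executes
simulate -> signatures -> differential expression -> clustering ->
enrichment -> reports into a run directory, writing a resolved config
snapshot and per-file hashes so a run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import de as de_mod
from . import signatures as sig_mod
from .containers import GeneSignatureSet
from .io import write_json, write_matrix
from .synthetic import RegionTruth, generate_reference_atlas, generate_region_counts

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """All knobs of the pipeline, defaulting to the study's printed values."""

    seed: int = 0

    # synthetic atlas
    n_cell_types: int = 3
    markers_per_type: int = 50
    n_background: int = 500
    n_atlas_replicates: int = 3
    marker_effect: float = 2.0
    atlas_noise_sd: float = 0.5

    # signature derivation
    low_coverage_min: float = 1.0
    cv_cutoff: float = 0.5
    k_atlas: int | None = None  # None -> 2 x number of cell types
    margin: float = 0.5

    # synthetic region counts
    n_region_genes: int = 2000
    n_per_region: int = 3
    nb_dispersion: float = 0.05
    planted_lfc: float = 2.0
    n_planted_signature_genes: int = 30
    n_planted_background: int = 20

    # differential expression / clustering / enrichment
    min_count: int = 5
    min_samples: int = 3
    lfc_min: float = 0.58
    alpha_select: float = 0.05
    alpha_signature: float = 0.1
    k_de: int = 7
    correction: str = "bh"
    pca_top_genes: int = 500

    # quantification thresholds (recorded for completeness / CLI defaults)
    decompaction_threshold: float = 0.15
    contact_distance: float = 1.5
    disruption_fraction: float = 0.25
    tier_percentiles: tuple[float, float] = (25.0, 75.0)
    threshold_z: float = 1.0

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["tier_percentiles"] = list(self.tier_percentiles)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tier_percentiles" in payload:
            payload["tier_percentiles"] = tuple(payload["tier_percentiles"])
        return cls(**payload)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return wrapped

    return deco


def plant_region_truth(
    config: RunConfig, signatures: GeneSignatureSet, rng: np.random.Generator
) -> tuple[RegionTruth, str]:
    """Build a RegionTruth planting CC-up genes inside one derived signature.

    The first signature (alphabetically) receives ``n_planted_signature_genes``
    of its members as CC-up at ``planted_lfc``; background structure is added
    as ST-up and CC-down genes outside any signature.
    """
    if len(signatures) == 0:
        raise ValueError("no signatures to plant into")
    target = sorted(signatures.signatures)[0]
    members = signatures[target]
    n_plant = min(config.n_planted_signature_genes, len(members))
    planted = list(rng.choice(members, size=n_plant, replace=False))

    de_assignment: dict[str, tuple[str, str, float]] = {
        g: ("CC", "up", config.planted_lfc) for g in planted
    }
    all_sig_genes = {g for _, gl in signatures.items() for g in gl}
    background = [f"BG_{i + 1}" for i in range(config.n_background) if f"BG_{i + 1}" not in all_sig_genes]
    extra = list(rng.choice(background, size=min(2 * config.n_planted_background, len(background)),
                            replace=False))
    for g in extra[: config.n_planted_background]:
        de_assignment[g] = ("ST", "up", config.planted_lfc)
    for g in extra[config.n_planted_background:]:
        de_assignment[g] = ("CC", "down", config.planted_lfc)

    truth = RegionTruth(
        de_assignment=de_assignment,
        planted_signature_links={target: planted},
        dispersion=config.nb_dispersion,
    )
    return truth, target


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic analysis into ``out_dir``; returns a summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "stages": []}

    def record(stage: str, **info) -> None:
        log.info("stage %-12s %s", stage, info)
        summary["stages"].append({"stage": stage, **info})

    # 1. simulate atlas ----------------------------------------------------
    @_stage("simulate_atlas")
    def s1():
        atlas, truth = generate_reference_atlas(
            n_cell_types=config.n_cell_types,
            markers_per_type=config.markers_per_type,
            n_background=config.n_background,
            n_replicates=config.n_atlas_replicates,
            marker_effect=config.marker_effect,
            noise_sd=config.atlas_noise_sd,
            seed=config.seed,
        )
        write_matrix(out / "atlas.tsv", atlas)
        record("atlas", genes=len(atlas.gene_ids), samples=atlas.data.shape[1])
        return atlas, truth

    atlas, atlas_truth = s1()

    # 2. signatures --------------------------------------------------------
    @_stage("signatures")
    def s2():
        variable = sig_mod.select_variable_genes(atlas, cv_cutoff=config.cv_cutoff)
        centred = sig_mod.preprocess_atlas(atlas, low_coverage_min=config.low_coverage_min)
        variable = [g for g in variable if g in set(centred.gene_ids)]
        sigs = sig_mod.derive_signatures(
            centred, variable, k=config.k_atlas, margin=config.margin, seed=config.seed
        )
        sig_mod.write_gmt(out / "signatures.gmt", sigs)
        record("signatures", variable_genes=len(variable), signatures=len(sigs))
        return sigs

    signatures = s2()

    # 3. simulate region counts -------------------------------------------
    @_stage("simulate_counts")
    def s3():
        rng = np.random.default_rng([config.seed, 97])
        truth, target = plant_region_truth(config, signatures, rng)
        counts, truth = generate_region_counts(
            truth,
            n_genes=config.n_region_genes,
            n_per_region=config.n_per_region,
            genes=atlas.gene_ids,
            seed=config.seed,
        )
        write_matrix(out / "counts.tsv", counts)
        record("counts", genes=len(counts.gene_ids), samples=counts.data.shape[1],
               planted_signature=target)
        return counts, truth, target

    counts, region_truth, planted_signature = s3()

    # 4. filter + DE -------------------------------------------------------
    @_stage("differential_expression")
    def s4():
        filtered = de_mod.filter_counts(counts, config.min_count, config.min_samples)
        record("filter", genes_retained=len(filtered.gene_ids))
        factors = de_mod.estimate_size_factors(filtered)
        de_cc = de_mod.test_differential_expression(filtered, ("Bulk", "CC"), factors)
        de_st = de_mod.test_differential_expression(filtered, ("Bulk", "ST"), factors)
        de_cc.table.to_csv(out / "de_cc_vs_bulk.tsv", sep="\t")
        de_st.table.to_csv(out / "de_st_vs_bulk.tsv", sep="\t")
        record("de", comparisons=["CC vs Bulk", "ST vs Bulk"])
        return filtered, de_cc, de_st

    filtered, de_cc, de_st = s4()

    # 5. select + cluster --------------------------------------------------
    @_stage("select_and_cluster")
    def s5():
        clusters = de_mod.select_and_cluster(
            de_cc, de_st, lfc_min=config.lfc_min, alpha=config.alpha_select,
            k=config.k_de, seed=config.seed,
        )
        clusters.to_csv(out / "clusters.tsv", sep="\t")
        record("cluster", selected_genes=len(clusters), k=config.k_de)
        return clusters

    clusters = s5()

    # 6. enrichment --------------------------------------------------------
    @_stage("enrichment")
    def s6():
        groups = {
            f"cluster_{c}": list(grp.index)
            for c, grp in clusters.groupby("cluster")
        }
        table = de_mod.enrich(groups, signatures, universe=filtered.gene_ids,
                              correction=config.correction)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        top = table.loc[table["p_adj"].idxmin()]
        record("enrich", cells=len(table), top_group=top["group"], top_signature=top["signature"])
        return table

    enrichment = s6()

    # 7. reports -----------------------------------------------------------
    @_stage("reports")
    def s7():
        reg = de_mod.signature_regulation_summary(de_cc, signatures, alpha=config.alpha_signature)
        reg.to_csv(out / "signature_regulation_cc.tsv", sep="\t", index=False)
        coords, var_frac = de_mod.pca_samples(filtered, n_top_genes=config.pca_top_genes)
        coords.iloc[:, :2].assign(
            var_frac_pc1=var_frac[0], var_frac_pc2=var_frac[1]
        ).to_csv(out / "pca_samples.tsv", sep="\t")
        record("reports", pc1_var=float(var_frac[0]), pc2_var=float(var_frac[1]))

    s7()

    config.to_yaml(out / "config.yaml")
    outputs = sorted(p.name for p in out.iterdir() if p.suffix in {".tsv", ".gmt"})
    summary["output_hashes"] = {name: _sha256(out / name) for name in outputs}
    top = enrichment.loc[enrichment["p_adj"].idxmin()]
    summary["planted_signature"] = planted_signature
    summary["top_enrichment"] = {
        "group": str(top["group"]),
        "signature": str(top["signature"]),
        "p_adj": float(top["p_adj"]),
    }
    summary["atlas_truth_markers"] = {
        ct: sorted(atlas_truth.markers_of(ct)) for ct in atlas_truth.cell_types
    }
    summary["planted_cc_up"] = region_truth.planted_signature_links
    write_json(out / "run_summary.json", summary)
    return summary
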