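"""Count filtering, normalisation, NB testing, clustering and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from wmniche.containers import CountMatrix, DEResult, GeneSignatureSet
from wmniche.de import (
    adjust_pvalues,
    enrich,
    estimate_size_factors,
    filter_counts,
    pca_samples,
    select_and_cluster,
    signature_regulation_summary,
    test_differential_expression as nb_wald_test,
)
from wmniche.synthetic import RegionTruth, generate_region_counts


def _cm(rows: dict[str, list[int]], samples: list[str]) -> CountMatrix:
    return CountMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=samples))


class TestFilterCounts:
    def test_boundary_of_rule(self):
        samples = [f"x:{i}" for i in range(1, 5)]
        cm = _cm({"keep": [5, 5, 5, 0], "drop": [5, 5, 4, 0]}, samples)
        out = filter_counts(cm)
        assert out.gene_ids == ["keep"]

    def test_all_zero_matrix_empty_output(self):
        samples = [f"x:{i}" for i in range(1, 4)]
        cm = _cm({"g1": [0, 0, 0], "g2": [0, 0, 0]}, samples)
        assert filter_counts(cm).gene_ids == []

    def test_idempotent(self):
        counts, _ = generate_region_counts(RegionTruth(), n_genes=200, seed=0)
        once = filter_counts(counts)
        twice = filter_counts(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestSizeFactors:
    def test_closed_form_two_sample_example(self, tiny_counts):
        f = estimate_size_factors(tiny_counts)
        assert f["a:1"] == pytest.approx(1 / math.sqrt(2), abs=1e-12)
        assert f["b:1"] == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_identical_samples_give_unit_factors(self):
        cm = _cm({"g1": [7, 7, 7], "g2": [3, 3, 3]}, ["a:1", "a:2", "a:3"])
        assert np.allclose(estimate_size_factors(cm), 1.0)

    def test_column_scaling_scales_its_relative_factor(self, rng):
        # scaling one library by c shifts every gene's geometric mean by
        # c**(1/n), so the exact statement is about factor ratios: the scaled
        # sample's factor triples relative to every other sample's.
        base = rng.poisson(200, size=(100, 4))
        samples = ["a:1", "a:2", "b:1", "b:2"]
        cm = _cm({f"g{i}": base[i].tolist() for i in range(100)}, samples)
        f0 = estimate_size_factors(cm)
        scaled = cm.data.copy()
        scaled["b:1"] = scaled["b:1"] * 3
        f1 = estimate_size_factors(CountMatrix(scaled))
        for s in ("a:1", "a:2", "b:2"):
            assert f1["b:1"] / f1[s] == pytest.approx(3 * f0["b:1"] / f0[s], rel=1e-9)
        assert f1["a:1"] / f1["a:2"] == pytest.approx(f0["a:1"] / f0["a:2"], rel=1e-9)

    def test_matches_independent_reference_estimator(self, rng):
        from pydeseq2.preprocessing import deseq2_norm

        # odd gene count: the reference tool takes the ratio median on the log
        # scale, which only agrees exactly when no middle-pair averaging occurs
        mat = rng.poisson(rng.uniform(50, 500, size=(81, 1)), size=(81, 6))
        samples = [f"c:{i}" for i in range(1, 7)]
        cm = _cm({f"g{i}": mat[i].tolist() for i in range(81)}, samples)
        ours = estimate_size_factors(cm).to_numpy()
        theirs = deseq2_norm(pd.DataFrame(mat.T))[1]
        assert np.allclose(ours, np.asarray(theirs), rtol=1e-10)

    def test_no_universal_gene_fails(self):
        cm = _cm({"g1": [5, 0], "g2": [0, 5]}, ["a:1", "b:1"])
        with pytest.raises(ValueError, match="size factors"):
            estimate_size_factors(cm)


class TestDifferentialExpression:
    def test_identical_groups_zero_ratio(self):
        samples = ["Bulk:1", "Bulk:2", "CC:1", "CC:2"]
        cm = _cm({f"g{i}": [10 + i, 20 + i, 10 + i, 20 + i] for i in range(5)}, samples)
        de = nb_wald_test(cm, ("Bulk", "CC"))
        assert np.allclose(de.table["log2_ratio"], 0.0)

    def test_planted_effect_recovered(self):
        planted = {f"G{i + 1:04d}": ("CC", "up", 2.0) for i in range(50)}
        counts, _ = generate_region_counts(
            RegionTruth(de_assignment=planted, dispersion=0.01),
            n_genes=500, n_per_region=10, seed=7,
        )
        de = nb_wald_test(filter_counts(counts), ("Bulk", "CC"))
        lfc = de.table.loc[list(planted), "log2_ratio"]
        assert (np.abs(lfc - 2.0) <= 0.3).mean() >= 0.9

    def test_padj_at_least_p_and_bh_monotone(self):
        counts, _ = generate_region_counts(RegionTruth(), n_genes=300, n_per_region=3, seed=2)
        de = nb_wald_test(filter_counts(counts), ("Bulk", "ST"))
        t = de.table.dropna()
        assert (t["p_adj"] >= t["p"] - 1e-12).all()


class TestSelectAndCluster:
    def _mk_de(self, genes, lfc, padj, comparison=("Bulk", "CC")):
        table = pd.DataFrame(
            {"base_mean": 100.0, "log2_ratio": lfc, "p": padj, "p_adj": padj}, index=genes
        )
        return DEResult(comparison=comparison, table=table)

    def test_selection_in_one_comparison_suffices(self):
        genes = [f"g{i}" for i in range(6)]
        cc = self._mk_de(genes, [0.6, 0.58, 0.0, 1.0, -1.0, 0.2], [0.01, 0.01, 0.9, 0.01, 0.01, 0.9])
        st = self._mk_de(genes, [0.0, 0.58, 0.0, 1.0, -1.0, 0.2], [0.9, 0.01, 0.9, 0.01, 0.01, 0.9],
                         comparison=("Bulk", "ST"))
        out = select_and_cluster(cc, st, k=2, seed=0)
        assert "g0" in out.index  # passes in CC only
        assert "g1" not in out.index  # 0.58 is not > 0.58 (strict)
        assert "g2" not in out.index and "g5" not in out.index

    def test_separable_blobs_reproduced(self):
        genes = [f"u{i}" for i in range(10)] + [f"d{i}" for i in range(10)]
        lfc = [3.0] * 10 + [-3.0] * 10
        cc = self._mk_de(genes, lfc, [0.001] * 20)
        st = self._mk_de(genes, lfc, [0.001] * 20, comparison=("Bulk", "ST"))
        out = select_and_cluster(cc, st, k=2, seed=0)
        up = set(out.loc[[g for g in genes if g.startswith("u")], "cluster"])
        down = set(out.loc[[g for g in genes if g.startswith("d")], "cluster"])
        assert len(up) == 1 and len(down) == 1 and up != down

    def test_too_few_selected_fails(self):
        genes = ["g1", "g2"]
        cc = self._mk_de(genes, [1.0, 1.0], [0.01, 0.01])
        st = self._mk_de(genes, [0.0, 0.0], [0.9, 0.9], comparison=("Bulk", "ST"))
        with pytest.raises(ValueError, match="k"):
            select_and_cluster(cc, st, k=7, seed=0)


def brute_force_upper_tail(universe_size, sig_size, group_size, overlap):
    """Exhaustive hypergeometric upper tail by enumerating all draws."""
    universe = list(range(universe_size))
    sig = set(universe[:sig_size])
    total = hits = 0
    for draw in itertools.combinations(universe, group_size):
        total += 1
        if len(sig & set(draw)) >= overlap:
            hits += 1
    return hits / total


class TestEnrich:
    def test_zero_overlap_p_is_one(self):
        sigs = GeneSignatureSet({"S": ["c", "d"]})
        out = enrich({"G": ["a", "b"]}, sigs, universe=["a", "b", "c", "d"])
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # universe {a,b,c,d}, group {a,b}, signature {a,b}: P(overlap >= 2) = 1/6
        sigs = GeneSignatureSet({"S": ["a", "b"]})
        out = enrich({"G": ["a", "b"]}, sigs, universe=["a", "b", "c", "d"])
        assert out["p"].iloc[0] == pytest.approx(1 / 6, abs=1e-12)

    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(0)
        for m in range(4, 13, 2):
            universe = [f"g{i}" for i in range(m)]
            for _ in range(5):
                ks = int(rng.integers(1, m))
                ng = int(rng.integers(1, m))
                sig = universe[:ks]
                group = list(rng.choice(universe, size=ng, replace=False))
                out = enrich({"G": group}, GeneSignatureSet({"S": sig}), universe)
                overlap = int(out["overlap"].iloc[0])
                oracle = brute_force_upper_tail(m, ks, ng, overlap)
                assert out["p"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_reports_percentage_of_group(self):
        sigs = GeneSignatureSet({"S": ["a", "b", "c"]})
        out = enrich({"G": ["a", "b", "x", "y"]}, sigs, universe=list("abcxyz"))
        assert out["pct_of_group"].iloc[0] == pytest.approx(50.0)

    def test_empty_group_or_universe_errors(self):
        sigs = GeneSignatureSet({"S": ["a"]})
        with pytest.raises(ValueError):
            enrich({"G": ["zz"]}, sigs, universe=["a", "b"])
        with pytest.raises(ValueError):
            enrich({"G": ["a"]}, sigs, universe=[])

    def test_adjusted_never_below_raw_min(self, rng):
        universe = [f"g{i}" for i in range(200)]
        groups = {f"G{j}": list(rng.choice(universe, size=20, replace=False)) for j in range(4)}
        sigs = GeneSignatureSet(
            {f"S{j}": list(rng.choice(universe, size=25, replace=False)) for j in range(4)}
        )
        out = enrich(groups, sigs, universe)
        assert out["p_adj"].min() >= out["p"].min() - 1e-15


class TestCorrections:
    def test_bh_step_up_hand_oracle(self):
        adj = adjust_pvalues(np.array([0.01, 0.02, 0.03, 0.04]), method="bh")
        assert np.allclose(adj, 0.04)

    def test_bonferroni(self):
        p = np.array([0.01, 0.2, 0.5])
        assert np.allclose(adjust_pvalues(p, "bonferroni"), np.minimum(1.0, p * 3))


class TestSignatureSummary:
    def test_planted_members_listed(self):
        table = pd.DataFrame(
            {"base_mean": 10.0, "log2_ratio": [2.0, -1.0, 0.1], "p": [0.001, 0.001, 0.9],
             "p_adj": [0.005, 0.02, 0.95]},
            index=["a", "b", "c"],
        )
        de = DEResult(("Bulk", "CC"), table)
        sigs = GeneSignatureSet({"OPC": ["a", "b", "c"], "Neuron": ["zz"]})
        out = signature_regulation_summary(de, sigs, alpha=0.1)
        opc = out[out["signature"] == "OPC"]
        assert sorted(opc["gene"]) == ["a", "b"]
        assert set(opc["direction"]) == {"up", "down"}
        # empty signature retained as placeholder row
        assert (out["signature"] == "Neuron").sum() == 1

    def test_alpha_one_lists_every_tested_member(self):
        table = pd.DataFrame(
            {"base_mean": 10.0, "log2_ratio": [1.0, 0.5], "p": [0.5, 0.9], "p_adj": [0.6, 0.95]},
            index=["a", "b"],
        )
        de = DEResult(("Bulk", "CC"), table)
        out = signature_regulation_summary(de, GeneSignatureSet({"S": ["a", "b"]}), alpha=1.0)
        assert sorted(out["gene"]) == ["a", "b"]


class TestPCA:
    def test_duplicated_groups_collapse_to_points(self):
        samples = ["a:1", "a:2", "b:1", "b:2"]
        rng = np.random.default_rng(1)
        ga = rng.poisson(100, size=60)
        gb = rng.poisson(300, size=60)
        cm = _cm({f"g{i}": [ga[i], ga[i], gb[i], gb[i]] for i in range(60)}, samples)
        coords, _ = pca_samples(cm, n_top_genes=60)
        assert np.allclose(coords.loc["a:1"], coords.loc["a:2"], atol=1e-8)
        assert np.allclose(coords.loc["b:1"], coords.loc["b:2"], atol=1e-8)

    def test_regions_separate_with_planted_profiles(self):
        from sklearn.metrics import silhouette_score

        planted = {f"G{i + 1:04d}": ("CC", "up", 3.0) for i in range(100)}
        planted.update({f"G{i + 1:04d}": ("ST", "up", 3.0) for i in range(100, 200)})
        counts, _ = generate_region_counts(
            RegionTruth(de_assignment=planted, dispersion=0.02), n_genes=800, n_per_region=4, seed=5
        )
        coords, var_frac = pca_samples(filter_counts(counts))
        labels = [s.split(":")[0] for s in coords.index]
        assert silhouette_score(coords.iloc[:, :2], labels) > 0.5

    def test_sample_permutation_equivariant(self):
        counts, _ = generate_region_counts(RegionTruth(), n_genes=300, seed=8)
        coords, _ = pca_samples(counts)
        perm = list(counts.data.columns[::-1])
        coords_p, _ = pca_samples(CountMatrix(counts.data[perm]))
        pd.testing.assert_frame_equal(coords.loc[perm], coords_p, atol=1e-9, rtol=0)

    def test_single_sample_fails(self):
        cm = _cm({"g1": [5]}, ["a:1"])
        with pytest.raises(ValueError):
            pca_samples(cm)
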