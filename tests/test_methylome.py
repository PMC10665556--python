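"""Methylation arm: transforms, DML calling, replication, DMG, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atrisk import methylome, synth
from atrisk.methylome import (
    BetaMatrix,
    beta_to_m,
    call_dml,
    called_probes,
    classify_one_vs_one,
    cross_cohort,
    embed,
    filter_probes,
    hier_cluster,
    map_dmg,
    pathway_enrichment,
    welch_t,
)


def welch_oracle(a, b):
    """Textbook Welch t with Welch-Satterthwaite df, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestTransforms:
    def test_filter_probes(self, tiny_beta):
        assert filter_probes(tiny_beta, set()).values.equals(tiny_beta.values)
        kept = filter_probes(tiny_beta, {"cg0", "cg2"})
        assert list(kept.probe_ids) == ["cg1", "cg3"]
        with pytest.raises(ValueError):
            filter_probes(tiny_beta, set(tiny_beta.probe_ids))

    def test_disjoint_blacklist_warns_but_identity(self, tiny_beta, caplog):
        with caplog.at_level("WARNING", logger="atrisk"):
            out = filter_probes(tiny_beta, {"not_a_probe"})
        assert out.values.equals(tiny_beta.values)
        assert "disjoint" in caplog.text

    @pytest.mark.parametrize("beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_m_value_closed_forms(self, beta, expected, tiny_beta):
        values = tiny_beta.values.copy()
        values.iloc[:, :] = beta
        m = beta_to_m(BetaMatrix(values, tiny_beta.sample_meta))
        assert np.allclose(m.values.to_numpy(), expected)

    def test_m_value_clipping_at_boundary(self, tiny_beta):
        values = tiny_beta.values.copy()
        values.iloc[:, :] = 1.0
        m = beta_to_m(BetaMatrix(values, tiny_beta.sample_meta), clip=1e-3)
        assert np.allclose(m.values.to_numpy(), np.log2(0.999 / 0.001))

    def test_bad_clip_rejected(self, tiny_beta):
        with pytest.raises(ValueError):
            beta_to_m(tiny_beta, clip=0.7)


class TestWelch:
    def test_identical_vectors(self):
        t, p = welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0 and p == 1

    def test_separated_groups(self):
        rng = np.random.default_rng(1)
        t, p = welch_t(rng.normal(0, 1e-3, 6), 1 + rng.normal(0, 1e-3, 6))
        assert p < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 7), rng.normal(0.4, 2, 5)
        t, p = welch_t(a, b)
        t0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0) and p == pytest.approx(p0)

    def test_degenerate_variance_flagged_missing(self):
        t, p = welch_t([1, 1, 1], [2, 2, 2])
        assert np.isnan(t) and np.isnan(p)


class TestCallDml:
    def _oracle(self, beta, pair, alpha=0.05, delta=0.1):
        """Brute-force per-locus loop with scalar Welch tests."""
        meta = beta.sample_meta
        out = {}
        for cohort in sorted(meta["cohort"].unique()):
            cols_a = meta.index[(meta["group"] == pair[0]) & (meta["cohort"] == cohort)]
            cols_b = meta.index[(meta["group"] == pair[1]) & (meta["cohort"] == cohort)]
            called = set()
            for probe in beta.probe_ids:
                a = beta.values.loc[probe, cols_a].to_numpy(float)
                b = beta.values.loc[probe, cols_b].to_numpy(float)
                t, p = welch_t(a, b)
                if np.isfinite(p) and p < alpha and abs(a.mean() - b.mean()) > delta:
                    called.add(probe)
            out[cohort] = called
        return out

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_bruteforce_oracle(self, seed):
        cfg = synth.SynthConfig(n_per_group_per_cohort=5, n_probes=40,
                                n_planted_dml=8, delta_beta_effect=0.2,
                                beta_noise_sd=0.06, seed=seed)
        beta, _ = synth.make_beta_matrix(cfg)
        dml = call_dml(beta, ("ctrl", "at_risk"))
        oracle = self._oracle(beta, ("ctrl", "at_risk"))
        for cohort in (1, 2):
            assert called_probes(dml, cohort=cohort) == oracle[cohort]

    def test_effect_gate_blocks_small_delta(self, tiny_beta):
        """Significant p but |delta beta| <= 0.1 must not be called."""
        values = tiny_beta.values.copy()
        rng = np.random.default_rng(3)
        ctrl_cols = [c for c in values.columns if c.startswith("ctrl")]
        ar_cols = [c for c in values.columns if c.startswith("at_risk")]
        values.loc["cg0", ctrl_cols] = 0.50 + rng.normal(0, 1e-3, len(ctrl_cols))
        values.loc["cg0", ar_cols] = 0.55 + rng.normal(0, 1e-3, len(ar_cols))
        beta = BetaMatrix(values, tiny_beta.sample_meta)
        dml = call_dml(beta, ("ctrl", "at_risk"))
        row = dml[dml["probe"] == "cg0"].iloc[0]
        assert row["p"] < 0.05 and not row["called"]

    def test_zero_variance_locus_excluded(self, tiny_beta):
        values = tiny_beta.values.copy()
        values.loc["cg1", :] = 0.5
        beta = BetaMatrix(values, tiny_beta.sample_meta)
        dml = call_dml(beta, ("ctrl", "at_risk"))
        row = dml[dml["probe"] == "cg1"].iloc[0]
        assert not row["called"] and (np.isnan(row["p"]) or row["p"] == 1.0)

    def test_absent_group_raises_named_error(self, tiny_beta):
        with pytest.raises(ValueError, match="early_ra"):
            call_dml(tiny_beta, ("ctrl", "early_ra"))

    def test_invariant_to_sample_column_order(self, small_synth_cfg):
        beta, _ = synth.make_beta_matrix(small_synth_cfg)
        shuffled = BetaMatrix(beta.values[beta.values.columns[::-1]], beta.sample_meta)
        d1 = call_dml(beta, ("ctrl", "at_risk"))
        d2 = call_dml(shuffled, ("ctrl", "at_risk"))
        for cohort in (1, 2):
            assert called_probes(d1, cohort=cohort) == called_probes(d2, cohort=cohort)

    def test_any_pair_mode_unions_pairwise_calls(self, small_synth_cfg):
        beta, _ = synth.make_beta_matrix(small_synth_cfg)
        dml = call_dml(beta, ("ctrl", "at_risk", "early_ra"), mode="any_pair")
        any_called = called_probes(dml, cohort=1, any_pair=True)
        union = set()
        for pair_label in dml["comparison"].unique():
            sub = dml[(dml["comparison"] == pair_label) & (dml["cohort"] == 1)]
            union |= set(sub.loc[sub["called"], "probe"])
        assert any_called == union


class TestCrossCohort:
    def test_exact_small_example(self):
        # N=10, K=5, n=4, m=4: C(5,4)C(5,0)/C(10,4) = 5/210
        test, union = cross_cohort({"a", "b", "c", "d", "e"}, {"a", "b", "c", "d"}, 10)
        assert test.p == pytest.approx(5 / 210)
        assert union == {"a", "b", "c", "d", "e"}

    def test_zero_overlap_p_one(self):
        test, _ = cross_cohort({"a"}, {"b"}, 10)
        assert test.overlap == 0 and test.p == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pmf_summation(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 200))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        probes = [f"p{i}" for i in range(N)]
        s1 = set(rng.choice(probes, size=K, replace=False))
        s2 = set(rng.choice(probes, size=n, replace=False))
        test, union = cross_cohort(s1, s2, N)
        m = len(s1 & s2)
        p_oracle = sum(stats.hypergeom.pmf(i, N, K, n) for i in range(m, min(K, n) + 1))
        assert test.p == pytest.approx(p_oracle, rel=1e-9)
        assert len(union) == K + n - m  # union arithmetic identity

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError):
            cross_cohort({"a", "b"}, {"c"}, 2)


class TestMapDmg:
    @pytest.fixture
    def annotation(self):
        return pd.DataFrame({
            "probe_id": ["p1", "p2", "p3", "p4", "p5"],
            "chrom": "chr1",
            "pos": [9000, 7499, 11000, 5000, 50000],
            "strand": ["+", "+", "-", "-", "+"],
            "gene": ["G1", "G1", "G2", "G2", "G3"],
            "tss": [10000, 10000, 10000, 10000, 40000],
            "gene_start": [10000, 10000, 3000, 3000, 40000],
            "gene_end": [15000, 15000, 10000, 10000, 45000],
        })

    def test_plus_strand_within_window_is_promoter(self, annotation):
        dmg = map_dmg({"p1"}, annotation)  # TSS-1000
        assert dmg.iloc[0].tolist() == ["G1", "p1", "promoter"]

    def test_plus_strand_boundary_exclusive_outside(self, annotation):
        dmg = map_dmg({"p2"}, annotation)  # TSS-2501: outside closed window
        assert not ((dmg["probe"] == "p2") & (dmg["region"] == "promoter")).any()

    def test_minus_strand_window_is_orientation_aware(self, annotation):
        # p3 sits 1000 bp to the right of the TSS in genomic coordinates;
        # on the minus strand that is 1000 bp upstream -> promoter
        dmg = map_dmg({"p3"}, annotation)
        assert dmg.iloc[0].tolist() == ["G2", "p3", "promoter"]

    def test_body_assignment_and_unannotated_drop(self, annotation):
        dmg = map_dmg({"p4", "p5", "missing"}, annotation)
        assert ("G2", "p4", "body") in [tuple(r) for r in dmg.to_numpy()]
        assert "missing" not in set(dmg["probe"])

    def test_dedup(self, annotation):
        two = pd.concat([annotation, annotation], ignore_index=True)
        dmg = map_dmg({"p1"}, two)
        assert len(dmg) == 1


class TestPathwayEnrichment:
    def test_exact_enumeration_small_universe(self):
        bg = {f"g{i}" for i in range(10)}
        genes = {"g0", "g1", "g2"}
        res = pathway_enrichment(genes, {"s": genes}, bg)
        # overlap 3 of a set of 3 when drawing 3 from 10
        p_oracle = 1 / (10 * 9 * 8 / 6)
        assert res["p"].iloc[0] == pytest.approx(p_oracle)

    def test_disjoint_set_p_one(self):
        bg = {f"g{i}" for i in range(10)}
        res = pathway_enrichment({"g0"}, {"s": {"g5", "g6"}}, bg)
        assert res["p"].iloc[0] == 1.0

    def test_bh_adjustment_matches_hand_computation(self):
        bg = {f"g{i}" for i in range(40)}
        genes = {f"g{i}" for i in range(8)}
        res = pathway_enrichment(genes, {"a": {"g0", "g1", "g2"},
                                         "b": {"g30", "g31"}}, bg)
        p = res.sort_values("set_id")["p"].to_numpy()
        expected = np.minimum.accumulate([min(1, 2 * p[0] / 1), min(1, 2 * p[1] / 2)][::-1])[::-1]
        np.testing.assert_allclose(res.sort_values("set_id")["fdr"].to_numpy(), expected)

    def test_empty_after_background_skipped(self):
        res = pathway_enrichment({"g0"}, {"s": {"x"}}, {"g0", "g1"})
        assert res.empty


class TestEmbeddings:
    def test_pca_matches_eigendecomposition(self, small_synth_cfg):
        beta, _ = synth.make_beta_matrix(small_synth_cfg)
        m = beta_to_m(beta)
        coords = embed(m, method="pca")
        X = m.values.T.to_numpy()
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(Xc.T))
        proj = Xc @ evecs[:, ::-1][:, :2]
        # match up to per-axis sign
        for k in range(2):
            assert (np.allclose(coords.iloc[:, k], proj[:, k], atol=1e-6)
                    or np.allclose(coords.iloc[:, k], -proj[:, k], atol=1e-6))

    def test_collinear_samples_embed_collinear(self, tiny_beta):
        from atrisk.methylome import MValueMatrix

        # samples on a straight line in M-value space stay on a line in 2-D
        u = np.array([0.0, 1.0, -1.0, 0.5])
        v = np.array([1.0, 2.0, 0.5, -1.0])
        values = tiny_beta.values.copy()
        for i, c in enumerate(values.columns):
            values[c] = u + 0.3 * i * v
        m = MValueMatrix(values, tiny_beta.sample_meta)
        coords = embed(m, method="mds").to_numpy()
        centered = coords - coords.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        assert s[1] < 1e-6 * max(s[0], 1e-12)

    def test_planted_blocks_separate(self, small_synth_cfg):
        from sklearn.metrics import silhouette_score

        beta, truth = synth.make_beta_matrix(small_synth_cfg)
        m = beta_to_m(beta)
        coords = embed(m, method="pca", features=list(truth["probe"]))
        labels = (beta.sample_meta.loc[coords.index, "group"] == "at_risk").astype(int)
        assert silhouette_score(coords.to_numpy(), labels) > 0

    def test_missing_values_imputed(self, tiny_beta):
        values = tiny_beta.values.copy()
        values.iloc[0, 0] = np.nan
        m = beta_to_m(BetaMatrix(values, tiny_beta.sample_meta))
        m.values.iloc[1, 1] = np.nan
        coords = embed(m, method="pca")
        assert np.isfinite(coords.to_numpy()).all()


class TestHierCluster:
    def test_duplicate_samples_merge_at_zero(self, tiny_beta):
        values = tiny_beta.values.copy()
        values["ctrl_0b"] = values["ctrl_0"]
        meta = tiny_beta.sample_meta.copy()
        meta.loc["ctrl_0b"] = meta.loc["ctrl_0"]
        m = beta_to_m(BetaMatrix(values, meta))
        rep = hier_cluster(m, list(m.values.index))
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        coph = squareform(cophenet(rep["linkage"]))
        i = rep["samples"].index("ctrl_0")
        j = rep["samples"].index("ctrl_0b")
        assert coph[i, j] == 0

    def test_two_blocks_split_first(self, small_synth_cfg):
        beta, truth = synth.make_beta_matrix(small_synth_cfg)
        m = beta_to_m(beta)
        rep = hier_cluster(m, list(truth["probe"]))
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(rep["linkage"], 2, criterion="maxclust")
        groups = beta.sample_meta.loc[rep["samples"], "group"] == "at_risk"
        # the top split should separate the shifted group from the rest
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(groups, two) == pytest.approx(1.0)

    def test_single_sample_rejected(self, tiny_beta):
        m = beta_to_m(tiny_beta)
        m_single = type(m)(m.values[["ctrl_0"]], m.sample_meta.loc[["ctrl_0"]])
        with pytest.raises(ValueError):
            hier_cluster(m_single, list(m.values.index))


class TestClassifier:
    def test_fixed_seed_reproducible(self, small_synth_cfg):
        beta, truth = synth.make_beta_matrix(small_synth_cfg)
        m = beta_to_m(beta)
        feats = sorted(truth["probe"])
        grid = {"n_estimators": [100], "max_features": ["sqrt"]}
        r1 = classify_one_vs_one(m, feats, ("ctrl", "at_risk"), seed=5, grid=grid)
        r2 = classify_one_vs_one(m, feats, ("ctrl", "at_risk"), seed=5, grid=grid)
        assert r1.test_accuracy == r2.test_accuracy
        assert r1.selected_features == r2.selected_features

    def test_small_class_rejected(self, tiny_beta):
        m = beta_to_m(tiny_beta)
        with pytest.raises(ValueError, match="minimum"):
            classify_one_vs_one(m, list(m.values.index), ("ctrl", "at_risk"),
                                seed=1, min_per_class=10)
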