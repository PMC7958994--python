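import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methqtl import comparison_enrichment as ce


def results_table(rows, model):
    df = pd.DataFrame(rows, columns=["snp", "gene", "beta", "pvalue", "fdr"])
    df["model"] = model
    df["n_cpgs"] = 1
    return df


class TestClassifyPairs:
    def test_meth_only_threshold_logic(self):
        pc = results_table([["rs1", "g1", 0.5, 0.01, 0.2]], "pc")
        me = results_table([["rs1", "g1", 0.6, 0.001, 0.01]], "meth")
        comp, counts = ce.classify_pairs(pc, me)
        assert comp.iloc[0]["group"] == "meth_only"
        assert counts["group1"] == 1

    def test_shared_decreased_is_group3(self):
        pc = results_table([["rs1", "g1", 0.5, 1e-9, 0.001]], "pc")
        me = results_table([["rs1", "g1", 0.45, 1e-7, 0.01]], "meth")
        comp, counts = ce.classify_pairs(pc, me)
        row = comp.iloc[0]
        assert row["group"] == "shared"
        assert row["direction"] == "decreased"
        assert row["group3"] and not row["group2"]

    def test_identical_tables_all_shared_unchanged(self):
        rows = [["rs1", "g1", 0.5, 0.001, 0.01],
                ["rs2", "g2", -0.2, 0.5, 0.7]]
        pc = results_table(rows, "pc")
        me = results_table(rows, "meth")
        comp, counts = ce.classify_pairs(pc, me)
        assert (comp["direction"] == "unchanged").all()
        assert counts["group2"] == 0 and counts["group3"] == 0
        assert counts["shared"] == 1 and counts["not_significant"] == 1

    def test_partition_property(self):
        rng = np.random.default_rng(17)
        n = 200
        rows_pc, rows_me = [], []
        for i in range(n):
            p1, p2 = rng.uniform(1e-6, 1, 2)
            rows_pc.append([f"rs{i}", f"g{i}", rng.normal(), p1, min(1, p1 * 3)])
            rows_me.append([f"rs{i}", f"g{i}", rng.normal(), p2, min(1, p2 * 3)])
        comp, counts = ce.classify_pairs(results_table(rows_pc, "pc"),
                                         results_table(rows_me, "meth"))
        total = sum(counts[k] for k in ce.GROUP_LABELS) + counts["not_tested"]
        assert total == counts["n_pairs"] == n

    def test_symmetric_under_model_swap(self):
        rng = np.random.default_rng(18)
        rows_a, rows_b = [], []
        for i in range(50):
            pa, pb = rng.uniform(1e-6, 1, 2)
            rows_a.append([f"rs{i}", "g", rng.normal(), pa, min(1, pa * 2)])
            rows_b.append([f"rs{i}", "g", rng.normal(), pb, min(1, pb * 2)])
        a, b = results_table(rows_a, "pc"), results_table(rows_b, "meth")
        _, fwd = ce.classify_pairs(a, b)
        _, rev = ce.classify_pairs(b, a)
        assert fwd["meth_only"] == rev["pc_only"]
        assert fwd["pc_only"] == rev["meth_only"]
        assert fwd["shared"] == rev["shared"]

    def test_one_sided_pair_rejected(self):
        pc = results_table([["rs1", "g1", 0.5, 0.01, 0.02]], "pc")
        me = results_table([["rs1", "g1", 0.5, 0.01, 0.02],
                            ["rs2", "g2", 0.1, 0.5, 0.6]], "meth")
        with pytest.raises(ValueError, match="rs2"):
            ce.classify_pairs(pc, me)
        comp, counts = ce.classify_pairs(pc, me, allow_partial=True)
        assert counts["n_pairs"] == 1


class TestEffectSizeCorrelation:
    def _comp(self, beta_pc, beta_meth):
        n = len(beta_pc)
        return pd.DataFrame({
            "snp": [f"rs{i}" for i in range(n)], "gene": "g",
            "beta_pc": beta_pc, "beta_meth": beta_meth,
            "p_pc": 0.5, "p_meth": 0.5, "fdr_pc": 0.9, "fdr_meth": 0.9,
            "group": "not_significant"})

    def test_identity_rho_one(self):
        b = np.linspace(-1, 1, 10)
        rho, p, n = ce.effect_size_correlation(self._comp(b, b))
        assert rho == pytest.approx(1.0)

    def test_negation_rho_minus_one(self):
        b = np.linspace(-1, 1, 10)
        rho, _, _ = ce.effect_size_correlation(self._comp(b, -b))
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(19)
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, _, n = ce.effect_size_correlation(self._comp(x, y))
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)
        assert n == 20

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            ce.effect_size_correlation(self._comp([1.0, 2.0], [1.0, 2.0]))


class TestExpandLd:
    def _gwas(self, rows):
        return pd.DataFrame(rows, columns=["rsid", "trait", "category",
                                           "pvalue"])

    def test_strict_r2_boundary(self):
        gwas = self._gwas([["rs1", "t", "c1", 1e-9]])
        ld = pd.DataFrame({"rsid_a": ["rs1", "rs1"],
                           "rsid_b": ["rsP1", "rsP2"], "r2": [0.85, 0.8]})
        m = ce.expand_ld(gwas, ld, 0.8)
        assert "rsP1" in m and "rsP2" not in m

    def test_empty_ld_keeps_catalog_rsids(self):
        gwas = self._gwas([["rs1", "t", "c1", 1e-9]])
        m = ce.expand_ld(gwas, pd.DataFrame(columns=["rsid_a", "rsid_b",
                                                     "r2"]))
        assert set(m) == {"rs1"}

    def test_proxy_inherits_both_categories_once(self):
        gwas = self._gwas([["rs1", "t1", "c1", 1e-9],
                           ["rs2", "t2", "c2", 1e-10]])
        ld = pd.DataFrame({"rsid_a": ["rs1", "rs2"],
                           "rsid_b": ["rsP", "rsP"], "r2": [0.9, 0.95]})
        m = ce.expand_ld(gwas, ld)
        cats = {c for _, c in m["rsP"]}
        assert cats == {"c1", "c2"}

    def test_symmetric_pair_orientation(self):
        gwas = self._gwas([["rs1", "t", "c1", 1e-9]])
        ld = pd.DataFrame({"rsid_a": ["rsP"], "rsid_b": ["rs1"],
                           "r2": [0.95]})
        m = ce.expand_ld(gwas, ld)
        assert "rsP" in m


class TestOverlap:
    def _map(self):
        gwas = pd.DataFrame({"rsid": ["rs1", "rs2"], "trait": ["t1", "t2"],
                             "category": ["c1", "c2"],
                             "pvalue": [1e-9, 1e-9]})
        return ce.expand_ld(gwas, pd.DataFrame(columns=["rsid_a", "rsid_b",
                                                        "r2"]))

    def test_disjoint_empty(self):
        assert ce.overlap_eqtls_gwas({"rsX"}, self._map()).empty

    def test_snp_in_many_pairs_counted_once(self):
        ov = ce.overlap_eqtls_gwas(["rs1", "rs1", "rs1"], self._map())
        assert len(ov) == 1

    def test_both_count_conventions(self):
        counts = ce.overlap_counts({"rs1", "rs2"}, self._map())
        assert counts == {"n_overlap_snps": 2, "n_overlap_associations": 2}


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p as a hypergeometric tail sum."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, col1, row1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestEnrichment:
    def _map_from(self, assignments):
        gwas = pd.DataFrame(
            [[r, "t", c, 1e-9] for r, c in assignments],
            columns=["rsid", "trait", "category", "pvalue"])
        return ce.expand_ld(gwas, pd.DataFrame(columns=["rsid_a", "rsid_b",
                                                        "r2"]))

    def test_group_equals_background_no_enrichment(self):
        snps = [f"rs{i}" for i in range(20)]
        gwas_map = self._map_from([(s, "c1") for s in snps[:5]])
        res = ce.enrichment_test(snps, snps, gwas_map)
        assert (res["odds_ratio"] == 1.0).all()
        assert (res["pvalue"] == 1.0).all()

    def test_fisher_matches_hypergeometric_oracle(self):
        # the spec's worked table: 8/20 in group vs 10/980 in the rest
        group = [f"g{i}" for i in range(20)]
        rest = [f"b{i}" for i in range(980)]
        hits = [(s, "c1") for s in group[:8]] + [(s, "c1") for s in rest[:10]]
        gwas_map = self._map_from(hits)
        res = ce.enrichment_test(group, group + rest, gwas_map)
        expected = fisher_oracle(8, 12, 10, 970)
        assert res.iloc[0]["pvalue"] == pytest.approx(expected, abs=1e-10)

    def test_planted_enrichment_minimizes_fdr(self):
        rng = np.random.default_rng(23)
        background = [f"rs{i}" for i in range(1000)]
        group = background[:500]
        assignments = []
        for s in background:
            if s in set(group) and rng.uniform() < 0.25:
                assignments.append((s, "planted"))
            elif rng.uniform() < 0.05:
                assignments.append((s, rng.choice(["c1", "c2", "c3"])))
        gwas_map = self._map_from(assignments)
        res = ce.enrichment_test(group, background, gwas_map)
        best = res.sort_values("fdr").iloc[0]
        assert best["category"] == "planted"
        assert best["fdr"] < 0.05

    def test_empty_group_flagged(self):
        gwas_map = self._map_from([("rs1", "c1")])
        res = ce.enrichment_test([], ["rs1", "rs2"], gwas_map)
        assert (res["flag"] == "empty_group").all()
        assert res["pvalue"].isna().all()

    def test_group_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            ce.enrichment_test(["rsX"], ["rs1"], {})

    def test_permutation_agrees_with_fisher_direction(self):
        group = [f"g{i}" for i in range(30)]
        rest = [f"b{i}" for i in range(200)]
        hits = [(s, "c1") for s in group[:15]] + \
               [(s, "c1") for s in rest[:10]]
        gwas_map = self._map_from(hits)
        fisher = ce.enrichment_test(group, group + rest, gwas_map)
        perm = ce.enrichment_test(group, group + rest, gwas_map,
                                  method="permutation",
                                  n_permutations=2000, seed=5)
        assert fisher.iloc[0]["pvalue"] < 0.01
        assert perm.iloc[0]["pvalue"] < 0.01

    def test_null_enrichment_rarely_significant(self):
        """With random group membership, BH across 17 categories should
        keep the family-wise false-enrichment rate low."""
        rng = np.random.default_rng(29)
        background = [f"rs{i}" for i in range(400)]
        cats = [f"c{i}" for i in range(17)]
        assignments = [(s, rng.choice(cats)) for s in background
                       if rng.uniform() < 0.3]
        gwas_map = self._map_from(assignments)
        false_hits = 0
        n_runs = 60
        for _ in range(n_runs):
            group = list(rng.choice(background, size=80, replace=False))
            res = ce.enrichment_test(group, background, gwas_map,
                                     categories=cats)
            false_hits += bool((res["fdr"] < 0.05).any())
        assert false_hits / n_runs <= 0.10
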