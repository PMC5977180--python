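"""Weighted-sum burden test: weights, permutation p, scan behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exomewas import burden, simulate
from exomewas.burden import (
    collapse_by_gene,
    madsen_browning_weights,
    weighted_sum_test,
)
from exomewas.core_io import MISSING

from conftest import labels_for, tiny_matrix


def _annotation(G, genes, dann=None):
    return pd.DataFrame(
        {
            "variant_key": G.variant_keys,
            "gene": genes,
            "func_class": "exonic",
            "dann": dann if dann is not None else [0.5] * G.n_variants,
        }
    )


class TestWeights:
    def test_weight_formula_example(self):
        # 2 controls with 1 alt allele: q = (1+1)/(4+2) = 1/3, w = 1.5
        Xco = np.array([[1], [0]])
        w = madsen_browning_weights(Xco)
        assert w[0] == pytest.approx(1.5)

    def test_rarer_variants_get_larger_weights(self):
        rng = np.random.default_rng(0)
        qs = np.linspace(0.01, 0.4, 10)
        Xco = np.column_stack(
            [rng.binomial(2, q, size=200) for q in qs]
        )
        w = madsen_browning_weights(Xco)
        m = Xco.sum(0)
        order = np.argsort(m)  # fewer alt alleles -> larger weight
        assert (np.diff(w[order]) <= 1e-12).all()


class TestCollapse:
    def test_gene_sets_and_orphans(self, small_cohort):
        G, labels, _ = small_cohort
        genes = ["APOB"] * 36 + [""] * 4 + ["MUC6"] * (G.n_variants - 40)
        ann = _annotation(G, genes)
        sets = collapse_by_gene(ann, G, labels, "all")
        by_gene = {s.gene: s for s in sets}
        assert by_gene["APOB"].n_variants == 36
        assert "" not in by_gene
        assert sum(s.n_variants for s in sets) == G.n_variants - 4

    def test_rare_stratum_strict_maf(self):
        # control MAF exactly 0.05 must be excluded from the rare stratum
        n_ctrl = 100
        case = np.zeros((2, 2), dtype=np.int8)
        ctrl = np.zeros((n_ctrl, 2), dtype=np.int8)
        ctrl[:10, 0] = 1  # MAF 10/200 = 0.05 -> excluded
        ctrl[:9, 1] = 1  # MAF 0.045 -> kept
        G = tiny_matrix(np.vstack([case, ctrl]))
        labels = labels_for(2, n_ctrl)
        ann = _annotation(G, ["X", "X"])
        sets = collapse_by_gene(ann, G, labels, "rare", "IBS")
        assert sets[0].variant_keys == [G.variant_keys[1]]

    def test_gene_without_dann_excluded(self, small_cohort):
        G, labels, _ = small_cohort
        genes = ["NOSCORE"] * 5 + ["OK"] * (G.n_variants - 5)
        dann = [np.nan] * 5 + [0.5] * (G.n_variants - 5)
        sets = collapse_by_gene(_annotation(G, genes, dann), G, labels, "all")
        assert [s.gene for s in sets] == ["OK"]


class TestWeightedSumTest:
    def _carrier_case_setup(self):
        # one variant: het in all 8 cases, absent in 107 controls
        calls = np.zeros((115, 1), dtype=np.int8)
        calls[:8, 0] = 1
        G = tiny_matrix(calls)
        labels = labels_for(8, 107)
        gvs = collapse_by_gene(_annotation(G, ["X"], [0.9]), G, labels, "all")[0]
        return gvs, G, labels

    def test_minimum_attainable_p(self):
        gvs, G, labels = self._carrier_case_setup()
        res = weighted_sum_test(gvs, G, labels, "IBS", n_perm=999, seed=1)
        assert res.p_perm == pytest.approx(1 / 1000)

    def test_p_floor_never_zero(self):
        gvs, G, labels = self._carrier_case_setup()
        for n_perm in (99, 999):
            res = weighted_sum_test(gvs, G, labels, "IBS", n_perm=n_perm, seed=2)
            assert res.p_perm >= 1 / (n_perm + 1)

    def test_degenerate_scores_flagged(self):
        calls = np.zeros((30, 1), dtype=np.int8)
        G = tiny_matrix(calls)
        labels = labels_for(3, 27)
        gvs = collapse_by_gene(_annotation(G, ["X"], [0.9]), G, labels, "all")[0]
        res = weighted_sum_test(gvs, G, labels, "IBS", n_perm=99, seed=0)
        assert res.degenerate and res.p_perm == 1.0

    def test_same_seed_reproducible(self, small_cohort):
        G, labels, ann = small_cohort
        gvs = collapse_by_gene(ann, G, labels, "all")[0]
        r1 = weighted_sum_test(gvs, G, labels, "IBS", n_perm=199, seed=7)
        r2 = weighted_sum_test(gvs, G, labels, "IBS", n_perm=199, seed=7)
        assert r1.p_perm == r2.p_perm and r1.statistic == r2.statistic

    def test_dann_monotonicity(self):
        # raising a case-carried variant's DANN never lowers the statistic
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, 0.02, size=(60, 6)).astype(np.int8)
        calls[:5, 0] = 2  # cases carry variant 0
        G = tiny_matrix(calls)
        labels = labels_for(5, 55)
        stats_seen = []
        for d0 in (0.1, 0.5, 0.9):
            dann = [d0, 0.5, 0.5, 0.5, 0.5, 0.5]
            gvs = collapse_by_gene(_annotation(G, ["X"] * 6, dann), G, labels, "all")[0]
            res = weighted_sum_test(gvs, G, labels, "IBS", n_perm=9, seed=1)
            stats_seen.append(res.statistic)
        assert stats_seen == sorted(stats_seen)

    def test_null_permutation_p_uniform(self):
        # genotypes independent of labels -> p_perm ~ Uniform
        cfg = simulate.SimConfig(
            n_cases=8,
            n_controls_per_cohort={"IBS": 107},
            n_variants=40,
            burden_genes=[
                simulate.BurdenGene(f"NULL{i:03d}", 8, enrichment=1.0,
                                    dann_beta=(2.0, 2.0))
                for i in range(250)
            ],
            seed=19,
        )
        G, labels, ann = simulate.gen_genotypes(cfg)
        sets = collapse_by_gene(ann, G, labels, "all")
        ps = []
        for i, gvs in enumerate(s for s in sets if s.gene.startswith("NULL")):
            ps.append(
                weighted_sum_test(gvs, G, labels, "IBS", n_perm=999, seed=i).p_perm
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBurdenScan:
    def test_enriched_genes_are_the_significant_set(self):
        cfg = simulate.SimConfig(
            n_cases=8,
            n_controls_per_cohort={"IBS": 107},
            n_variants=60,
            burden_genes=(
                [simulate.BurdenGene("HIT_A", 17), simulate.BurdenGene("HIT_B", 34)]
                + [
                    simulate.BurdenGene(f"NULL{i:03d}", 10, enrichment=1.0,
                                        dann_beta=(2.0, 2.0))
                    for i in range(98)
                ]
            ),
            seed=23,
        )
        G, labels, ann = simulate.gen_genotypes(cfg)
        rt = burden.burden_scan(
            G, labels, ann, strata=("rare",), n_perm=999, seed=5
        )
        sig = rt.data[rt.data["significant_bonferroni"]]
        assert set(sig["gene"]) == {"HIT_A", "HIT_B"}

    def test_escalation_clears_bonferroni_floor(self):
        cfg = simulate.SimConfig(
            n_cases=8,
            n_controls_per_cohort={"IBS": 107},
            n_variants=40,
            burden_genes=[simulate.BurdenGene("HIT", 20)],
            seed=29,
        )
        G, labels, ann = simulate.gen_genotypes(cfg)
        rt = burden.burden_scan(G, labels, ann, strata=("rare",), n_perm=999, seed=2)
        hit = rt.data[rt.data["gene"] == "HIT"].iloc[0]
        assert hit["n_perm"] > 999  # escalated
        assert hit["p_perm"] < hit["bonferroni_alpha"]

    def test_pseudo_replication_across_cohorts(self):
        cfg = simulate.SimConfig(
            n_cases=8,
            n_variants=40,
            burden_genes=(
                [simulate.BurdenGene("HIT", 24)]
                + [
                    simulate.BurdenGene(f"NULL{i:02d}", 10, enrichment=1.0,
                                        dann_beta=(2.0, 2.0))
                    for i in range(40)
                ]
            ),
            seed=31,
        )
        G, labels, ann = simulate.gen_genotypes(cfg)
        rt = burden.burden_scan(
            G, labels, ann, strata=("rare",),
            cohorts=["IBS", "TSI", "GBR", "CEU"], discovery_cohort="IBS",
            n_perm=999, seed=3,
        )
        hit = rt.data[rt.data["gene"] == "HIT"]
        assert len(hit) == 4
        assert hit["significant_bonferroni"].all()
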