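"""Moderated t, BH FDR, ROC/AUC, and the cross-study candidate report."""

import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from exomewas import expression, simulate
from exomewas.expression import (
    bh_fdr,
    candidate_report,
    differential_expression,
    fit_ebayes,
    moderated_t,
    posterior_variances,
    roc_auc,
)
from exomewas.simulate import ExpressionSimConfig, ExpressionStudy


def _study(seed=1, n_genes=200, n1=6, n0=6, de=()):
    cfg = ExpressionSimConfig(
        n_genes=n_genes, n_per_group=(n1, n0), de_genes=list(de), seed=seed
    )
    return simulate.gen_expression(cfg)


class TestModeratedT:
    def test_identical_group_means_give_null_result(self):
        st = _study(seed=2)
        i = 7
        case_cols = st.group == "case"
        # force equal means for one gene
        st.expression[i, case_cols] -= st.expression[i, case_cols].mean()
        st.expression[i, ~case_cols] -= st.expression[i, ~case_cols].mean()
        df, _ = moderated_t(st)
        assert df.loc[i, "t"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc[i, "p"] == pytest.approx(1.0)

    def test_d0_zero_recovers_pooled_t(self):
        st = _study(seed=3)
        df, _ = moderated_t(st, d0_override=0.0)
        case = st.expression[:, st.group == "case"]
        ctrl = st.expression[:, st.group == "control"]
        ref = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(df["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(df["p"], ref.pvalue, rtol=1e-10)

    def test_two_path_posterior_formula_oracle(self):
        # independent direct evaluation of the shrinkage formula per gene
        st = _study(seed=4)
        df, params = moderated_t(st)
        case = st.expression[:, st.group == "case"]
        ctrl = st.expression[:, st.group == "control"]
        n1, n0 = case.shape[1], ctrl.shape[1]
        d = n1 + n0 - 2
        for i in (0, 57, 123, 199):
            s2 = (
                (n1 - 1) * case[i].var(ddof=1) + (n0 - 1) * ctrl[i].var(ddof=1)
            ) / d
            s2_post = (params.d0 * params.s0sq + d * s2) / (params.d0 + d)
            lfc = case[i].mean() - ctrl[i].mean()
            t = lfc / np.sqrt(s2_post * (1 / n1 + 1 / n0))
            assert df.loc[i, "t"] == pytest.approx(t, rel=1e-10)

    def test_shrinkage_lies_between_gene_and_prior_variance(self):
        st = _study(seed=5)
        df, params = moderated_t(st)
        s2, s2_post = df["s2"].to_numpy(), df["s2_post"].to_numpy()
        lo = np.minimum(s2, params.s0sq) - 1e-12
        hi = np.maximum(s2, params.s0sq) + 1e-12
        assert ((s2_post >= lo) & (s2_post <= hi)).all()

    def test_matches_limma_reference(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        st = _study(seed=6, n_genes=80, n1=5, n0=5)
        mat = pd.DataFrame(
            st.expression,
            index=st.genes,
            columns=[f"{g}_{i}" for i, g in enumerate(st.group)],
        )
        mat.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim(commandArgs(TRUE)[1], row.names = 1))
            grp <- factor(ifelse(grepl("^case", colnames(x)), "case", "control"),
                          levels = c("control", "case"))
            fit <- eBayes(lmFit(x, model.matrix(~grp)))
            out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2],
                              d0 = fit$df.prior, s0sq = fit$s2.prior)
            write.table(out, commandArgs(TRUE)[2], sep = "\t", quote = FALSE)
            """
        )
        (tmp_path / "limma.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "limma.R"), str(tmp_path / "expr.tsv"),
             str(tmp_path / "limma.tsv")],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        df, params = moderated_t(st)
        assert params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert params.s0sq == pytest.approx(ref["s0sq"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(df["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(df["p"], ref["p"], rtol=1e-6)

    def test_zero_variance_everywhere_rejected(self):
        st = _study(seed=7, n_genes=10)
        st.expression[:] = 1.0
        with pytest.raises(ValueError):
            moderated_t(st)


class TestFitEbayes:
    def test_moment_equations_invert(self):
        # variances drawn from the model: s2 ~ s0sq * F(d, d0) scaled
        rng = np.random.default_rng(8)
        d, d0, s0sq = 10.0, 6.0, 0.25
        chi_g = rng.chisquare(d, 5000) / d
        chi_0 = rng.chisquare(d0, 5000) / d0
        s2 = s0sq * chi_g / chi_0
        params = fit_ebayes(s2, d)
        assert params.d0 == pytest.approx(d0, rel=0.15)
        assert params.s0sq == pytest.approx(s0sq, rel=0.1)

    def test_no_excess_variance_gives_infinite_d0(self):
        params = fit_ebayes(np.full(50, 0.3), 10.0)
        assert np.isinf(params.d0)
        np.testing.assert_allclose(posterior_variances(params), params.s0sq)


class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), 1.0)

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestROC:
    def test_perfect_separation(self):
        labels = np.array(["case"] * 4 + ["control"] * 4)
        scores = np.array([5.0, 6, 7, 8, 1, 2, 3, 4])
        assert roc_auc(scores, labels).auc == 1.0

    def test_interleaved_example(self):
        labels = np.array(["control", "case", "control", "case"])
        r = roc_auc(np.array([1.0, 2, 3, 4]), labels)
        assert r.auc == pytest.approx(0.75)  # 3 of 4 case>control pairs

    def test_anti_separated_reported_down(self):
        labels = np.array(["case"] * 3 + ["control"] * 3)
        r = roc_auc(np.array([1.0, 2, 3, 7, 8, 9]), labels)
        assert r.raw_auc == 0.0 and r.auc == 1.0 and r.direction == "down"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2]), np.array(["case", "case"]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        labels = np.array(["case"] * (n // 2) + ["control"] * (n - n // 2))
        scores = np.round(rng.normal(size=n), 1)  # provoke ties
        r = roc_auc(scores, labels)
        cases = scores[labels == "case"]
        ctrls = scores[labels == "control"]
        wins = sum(
            1.0 if c > u else (0.5 if c == u else 0.0)
            for c, u in itertools.product(cases, ctrls)
        )
        assert r.raw_auc == pytest.approx(wins / (len(cases) * len(ctrls)))


class TestNullCalibration:
    def test_fdr_controlled_on_null_studies(self):
        fracs = []
        for rep in range(20):
            st = _study(seed=200 + rep, n_genes=150)
            rt = differential_expression(st)
            fracs.append((rt.data["bh_fdr"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05
        assert np.median(fracs) == 0.0


class TestCandidateReport:
    def _frame(self, gene, lfc, fdr, auc=0.8):
        return pd.DataFrame(
            {
                "gene": [gene],
                "lfc": [lfc],
                "p": [fdr / 2],
                "bh_fdr": [fdr],
                "auc": [auc],
                "direction": ["up" if lfc >= 0 else "down"],
            }
        )

    def test_concordant_down_regulation(self):
        results = {
            "s1": self._frame("MEIS1", -1.2, 0.001),
            "s2": self._frame("MEIS1", -0.9, 0.01),
        }
        rep = candidate_report(results, ["MEIS1"]).data
        assert set(rep["direction"]) == {"down"}
        assert not rep["discordant_direction"].any()

    def test_tissue_dependent_discordance_flagged(self):
        results = {f"s{i}": self._frame("APOBR", 1.0, 0.001) for i in range(3)}
        results["plasma"] = self._frame("APOBR", -1.0, 0.001)
        rep = candidate_report(results, ["APOBR"]).data
        assert rep["discordant_direction"].all()

    def test_absent_candidate_untested(self):
        rep = candidate_report({"s1": self._frame("X", 1.0, 0.5)}, ["NOTHERE"]).data
        assert rep.iloc[0]["status"] == "untested"
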