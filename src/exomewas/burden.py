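"""Gene-level collapsing association (pathogenicity-weighted weighted-sum).

Variants are collapsed per gene; each individual receives a genotype score
x_i = sum_j g_ij * w'_j, where the Madsen-Browning base weight
w_j = 1/sqrt(n_j^U q_j (1-q_j)) up-weights variants rare in controls
(q_j = (m_j+1)/(2 n_j^U + 2) is the smoothed control allele frequency) and
w'_j additionally carries the variant's DANN deleteriousness score.  The
test statistic is the rank-sum of case scores among all samples (midranks
for ties); significance comes from case/control label permutation, with
p = (1 + #{permuted statistic >= observed}) / (n_perm + 1), so the reported
p never reaches zero.

Because the permutation floor 1/(n_perm+1) can sit above a Bonferroni line,
the scan escalates the permutation count adaptively — only for genes whose
first-stage p is small — and records both stages in metadata.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .assoc import allelic_counts, bonferroni, common_variant_filter
from .core_io import MISSING, GenotypeMatrix, ResultTable, SampleLabels

log = logging.getLogger(__name__)

DANN_MODES = ("weight", "gene_mean", "off")


@dataclass
class GeneVariantSet:
    gene: str
    variant_keys: list[str]
    variant_idx: np.ndarray  # columns into the genotype matrix
    dann: np.ndarray  # per-variant scores, NaN when unscored
    stratum: str  # "all" | "rare"

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)


@dataclass
class GeneBurdenResult:
    gene: str
    n_variants: int
    statistic: float  # rank-sum of case scores
    p_perm: float
    mean_dann: float
    cohort: str
    stratum: str
    n_perm: int
    degenerate: bool = False


def rare_variant_keys(
    G: GenotypeMatrix,
    labels: SampleLabels,
    discovery_cohort: str,
    maf_threshold: float = 0.05,
) -> set[str]:
    """Variant keys with discovery-control MAF strictly below the threshold."""
    tables = allelic_counts(G, labels, discovery_cohort)
    common = {
        t.variant_key for t in common_variant_filter(tables, maf_threshold)
    }
    at_threshold = {
        t.variant_key for t in tables if t.control_maf == maf_threshold
    }
    return {t.variant_key for t in tables} - common - at_threshold


def collapse_by_gene(
    annotations: pd.DataFrame,
    G: GenotypeMatrix,
    labels: SampleLabels,
    stratum: str = "all",
    discovery_cohort: str | None = None,
    maf_threshold: float = 0.05,
) -> list[GeneVariantSet]:
    """Group annotated variants by gene symbol.

    Rows with an empty gene symbol are counted as orphans; variants lacking a
    DANN score stay in the set but are dropped from weighting by the test
    (a gene whose variants are all unscored is excluded).  The rare stratum
    keeps only variants with discovery-control MAF < ``maf_threshold``
    (strict).
    """
    if stratum not in ("all", "rare"):
        raise ValueError("stratum must be 'all' or 'rare'")
    key_to_col = {k: j for j, k in enumerate(G.variant_keys)}
    ann = annotations[annotations["variant_key"].isin(key_to_col)]
    n_orphan_gene = int((ann["gene"] == "").sum())
    if n_orphan_gene:
        log.info("%d variants with empty gene symbol left unassigned", n_orphan_gene)
    ann = ann[ann["gene"] != ""]
    if stratum == "rare":
        if discovery_cohort is None:
            raise ValueError("rare stratum requires a discovery cohort")
        rare = rare_variant_keys(G, labels, discovery_cohort, maf_threshold)
        ann = ann[ann["variant_key"].isin(rare)]
    out: list[GeneVariantSet] = []
    for gene, grp in ann.groupby("gene", sort=True):
        dann = grp["dann"].to_numpy(dtype=float)
        if np.isnan(dann).all():
            log.info("gene %s excluded: no DANN-scored variants", gene)
            continue
        keys = list(grp["variant_key"])
        out.append(
            GeneVariantSet(
                gene=str(gene),
                variant_keys=keys,
                variant_idx=np.array([key_to_col[k] for k in keys]),
                dann=dann,
                stratum=stratum,
            )
        )
    return out


def madsen_browning_weights(
    Xco: np.ndarray,
) -> np.ndarray:
    """Base weights from control genotypes: w_j = 1/sqrt(n_j q_j (1-q_j))
    with q_j = (m_j + 1) / (2 n_j + 2) (controls only, missing excluded)."""
    obs = Xco != MISSING
    m = np.where(obs, Xco, 0).sum(0)
    n_u = obs.sum(0)
    q = (m + 1) / (2 * n_u + 2)
    return 1.0 / np.sqrt(n_u * q * (1 - q))


def _case_rank_sum(scores: np.ndarray, n_case: int) -> float:
    ranks = rankdata(scores)  # midranks
    return float(ranks[:n_case].sum())


def weighted_sum_test(
    gvs: GeneVariantSet,
    G: GenotypeMatrix,
    labels: SampleLabels,
    cohort: str | None = None,
    n_perm: int = 999,
    seed: int = 0,
    dann_mode: str = "weight",
) -> GeneBurdenResult:
    """Rank-sum weighted-sum burden test for one gene, one control cohort."""
    if dann_mode not in DANN_MODES:
        raise ValueError(f"dann_mode must be one of {DANN_MODES}")
    case_ids, ctrl_ids = labels.cases, labels.controls(cohort)
    if not case_ids or len(ctrl_ids) < 10:
        raise ValueError("need >= 1 case and >= 10 controls")
    idx = {s: i for i, s in enumerate(G.sample_ids)}
    rows = np.array([idx[s] for s in case_ids + ctrl_ids])
    X = G.calls[rows][:, gvs.variant_idx].astype(np.float64)
    n_case = len(case_ids)

    scored = ~np.isnan(gvs.dann)
    mean_dann = float(np.nanmean(gvs.dann))
    if dann_mode == "weight":
        X, dann = X[:, scored], gvs.dann[scored]
    else:
        dann = gvs.dann
    w = madsen_browning_weights(X[n_case:])
    if dann_mode == "weight":
        w = w * dann
    elif dann_mode == "gene_mean":
        w = w * mean_dann
    Xs = np.where(X == MISSING, 0.0, X)  # missing contributes no burden
    scores = Xs @ w

    stat = _case_rank_sum(scores, n_case)
    if np.ptp(scores) == 0:
        return GeneBurdenResult(
            gvs.gene, gvs.n_variants, stat, 1.0, mean_dann,
            cohort or "ALL", gvs.stratum, n_perm, degenerate=True,
        )
    rng = np.random.default_rng(seed)
    ranks = rankdata(scores)
    n = len(scores)
    # random n_case-subsets via argpartition of uniform draws
    u = rng.random((n_perm, n))
    sub = np.argpartition(u, n_case - 1, axis=1)[:, :n_case]
    perm_stats = ranks[sub].sum(axis=1)
    p = (1 + int((perm_stats >= stat).sum())) / (n_perm + 1)
    return GeneBurdenResult(
        gvs.gene, gvs.n_variants, stat, p, mean_dann,
        cohort or "ALL", gvs.stratum, n_perm,
    )


def burden_scan(
    G: GenotypeMatrix,
    labels: SampleLabels,
    annotations: pd.DataFrame,
    strata: tuple[str, ...] = ("all", "rare"),
    cohorts: list[str] | None = None,
    discovery_cohort: str | None = None,
    maf_threshold: float = 0.05,
    n_perm: int = 999,
    n_perm_max: int = 49_999,
    escalate_p: float = 0.01,
    seed: int = 0,
    alpha: float = 0.05,
    dann_mode: str = "weight",
) -> ResultTable:
    """Per-gene burden results for each stratum and control cohort.

    Genes whose first-stage permutation p is at most ``escalate_p`` are
    re-tested with ``n_perm_max`` permutations so the attainable p floor
    clears the per-stratum Bonferroni threshold 0.05/(genes tested).
    """
    if cohorts is None:
        cohorts = labels.cohorts or [None]
    if discovery_cohort is None:
        discovery_cohort = cohorts[0]
    ss = np.random.SeedSequence(seed)
    rows = []
    for stratum in strata:
        sets = collapse_by_gene(
            annotations, G, labels, stratum, discovery_cohort, maf_threshold
        )
        if not sets:
            continue
        thr = bonferroni(alpha, len(sets))
        for cohort in cohorts:
            tag = zlib.crc32(f"{stratum}:{cohort}".encode()) % 2**31
            child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(tag,))
            seeds = child.generate_state(2 * len(sets)) % 2**31
            for i, gvs in enumerate(sets):
                res = weighted_sum_test(
                    gvs, G, labels, cohort, n_perm, int(seeds[2 * i]), dann_mode
                )
                if not res.degenerate and res.p_perm <= escalate_p:
                    res = weighted_sum_test(
                        gvs, G, labels, cohort, n_perm_max,
                        int(seeds[2 * i + 1]), dann_mode,
                    )
                rows.append(
                    {
                        "gene": res.gene,
                        "stratum": stratum,
                        "cohort": res.cohort,
                        "n_variants": res.n_variants,
                        "statistic": res.statistic,
                        "p_perm": res.p_perm,
                        "mean_dann": res.mean_dann,
                        "n_perm": res.n_perm,
                        "bonferroni_alpha": thr,
                        "significant_bonferroni": res.p_perm < thr,
                    }
                )
    df = pd.DataFrame(rows).sort_values(["stratum", "cohort", "p_perm"]).reset_index(
        drop=True
    )
    return ResultTable(
        df,
        stage="burden",
        params={
            "strata": ",".join(strata),
            "maf_threshold": maf_threshold,
            "n_perm": n_perm,
            "n_perm_max": n_perm_max,
            "escalate_p": escalate_p,
            "dann_mode": dann_mode,
            "seed": seed,
        },
    )
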