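"""Two-group differential expression with empirical-Bayes moderated t,
Benjamini-Hochberg FDR, and ROC/AUC biomarker evaluation.

The moderated t shrinks each gene's residual variance toward a prior
variance s0^2 with prior degrees of freedom d0; both hyper-parameters are
estimated by matching moments of log s_g^2 to a scaled log-F distribution
(the standard empirical-Bayes derivation).  With d0 = 0 the statistic
reduces to the ordinary pooled two-sample t; with d0 = infinity every gene
uses the common prior variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

from .core_io import ResultTable
from .simulate import ExpressionStudy

log = logging.getLogger(__name__)


@dataclass
class EBayesParams:
    d0: float  # prior df; np.inf = full shrinkage
    s0sq: float
    s2: np.ndarray  # per-gene residual variances
    df_resid: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_ebayes(s2: np.ndarray, df_resid: float) -> EBayesParams:
    """Moment-match (d0, s0^2) from per-gene sample variances.

    Uses the log-variance representation: e_g = log s2_g - digamma(d/2) +
    log(d/2) has mean log s0^2 - digamma(d0/2) + log(d0/2) and excess
    variance trigamma(d0/2) beyond trigamma(d/2).  When the excess is not
    positive, d0 = infinity (variances fully pooled) with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all residual variances are zero")
    if (~pos).any():
        log.warning("%d zero-variance genes ignored in hyper-parameter fit", int((~pos).sum()))
    z = np.log(s2[pos])
    d = df_resid
    e = z - special.digamma(d / 2) + np.log(d / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = evar - float(special.polygamma(1, d / 2))
    if excess > 0:
        d0 = 2 * _trigamma_inverse(excess)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        log.warning("no excess variance in log s^2: d0 set to infinity")
        d0 = np.inf
        s0sq = float(np.exp(emean))
    return EBayesParams(d0, s0sq, s2, df_resid)


def posterior_variances(params: EBayesParams) -> np.ndarray:
    """Shrunken variances (d0*s0^2 + d*s2_g)/(d0 + d)."""
    if np.isinf(params.d0):
        return np.full_like(params.s2, params.s0sq)
    return (params.d0 * params.s0sq + params.df_resid * params.s2) / (
        params.d0 + params.df_resid
    )


def moderated_t(
    study: ExpressionStudy, d0_override: float | None = None
) -> tuple[pd.DataFrame, EBayesParams]:
    """Per-gene two-group moderated t, p, and log fold change.

    lfc = mean(case) - mean(control) on the (log-scale) expression matrix.
    ``d0_override`` forces the prior df (0 recovers the ordinary pooled t).
    """
    case = study.expression[:, study.group == "case"]
    ctrl = study.expression[:, study.group == "control"]
    n1, n0 = case.shape[1], ctrl.shape[1]
    if min(n1, n0) < 2:
        raise ValueError("need >= 2 samples per group")
    lfc = case.mean(1) - ctrl.mean(1)
    df_resid = n1 + n0 - 2
    s2 = ((n1 - 1) * case.var(1, ddof=1) + (n0 - 1) * ctrl.var(1, ddof=1)) / df_resid
    params = fit_ebayes(s2, df_resid)
    if d0_override is not None:
        params = EBayesParams(d0_override, params.s0sq, s2, df_resid)
    s2_post = (
        s2
        if params.d0 == 0
        else posterior_variances(params)
    )
    se = np.sqrt(s2_post * (1 / n1 + 1 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    df_total = df_resid + params.d0
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    df = pd.DataFrame(
        {"gene": study.genes, "lfc": lfc, "t": t, "p": p, "s2": s2, "s2_post": s2_post}
    )
    return df, params


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ROCResult:
    auc: float  # oriented: >= 0.5
    raw_auc: float  # case-vs-control Mann-Whitney AUC as scored
    direction: str  # "up" if cases score higher, else "down"
    fpr: np.ndarray
    tpr: np.ndarray


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC evaluation of one gene's expression as a case biomarker.

    AUC is the Mann-Whitney probability that a random case outscores a
    random control (ties count 1/2).  The reported AUC is oriented to be at
    least 0.5, with the direction flag recording whether the marker is
    case-elevated ("up") or case-reduced ("down").
    """
    labels = np.asarray(labels)
    y = (labels == "case").astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    raw = float(roc_auc_score(y, scores))
    if raw >= 0.5:
        fpr, tpr, _ = roc_curve(y, scores)
        return ROCResult(raw, raw, "up", fpr, tpr)
    fpr, tpr, _ = roc_curve(y, -np.asarray(scores))
    return ROCResult(1 - raw, raw, "down", fpr, tpr)


def differential_expression(
    study: ExpressionStudy, d0_override: float | None = None
) -> ResultTable:
    """Moderated-t scan + BH FDR + per-gene oriented AUC for one study."""
    df, params = moderated_t(study, d0_override)
    df["bh_fdr"] = bh_fdr(df["p"])
    aucs, dirs = [], []
    for i in range(len(df)):
        r = roc_auc(study.expression[i], study.group)
        aucs.append(r.auc)
        dirs.append(r.direction)
    df["auc"] = aucs
    df["direction"] = np.where(df["lfc"] >= 0, "up", "down")
    df["auc_direction"] = dirs
    return ResultTable(
        df,
        stage="dge",
        params={
            "study": study.study,
            "d0": params.d0 if d0_override is None else d0_override,
            "s0sq": params.s0sq,
        },
    )


def candidate_report(
    results: dict[str, pd.DataFrame], candidates: list[str], fdr_alpha: float = 0.05
) -> ResultTable:
    """Cross-study summary for candidate genes.

    One row per candidate per study with direction, BH-FDR significance and
    AUC; a discordance flag marks candidates whose significant directions
    disagree across studies (tissue-dependent regulation).  Candidates
    absent from every study are reported as untested.
    """
    rows = []
    for gene in candidates:
        sig_dirs = set()
        found = False
        for study, df in results.items():
            hit = df[df["gene"] == gene]
            if hit.empty:
                continue
            found = True
            r = hit.iloc[0]
            sig = bool(r["bh_fdr"] < fdr_alpha)
            if sig:
                sig_dirs.add(r["direction"])
            rows.append(
                {
                    "gene": gene,
                    "study": study,
                    "direction": r["direction"],
                    "lfc": r["lfc"],
                    "bh_fdr": r["bh_fdr"],
                    "significant": sig,
                    "auc": r["auc"],
                    "status": "tested",
                }
            )
        if not found:
            rows.append(
                {
                    "gene": gene,
                    "study": "",
                    "direction": "",
                    "lfc": np.nan,
                    "bh_fdr": np.nan,
                    "significant": False,
                    "auc": np.nan,
                    "status": "untested",
                }
            )
        else:
            discordant = len(sig_dirs) > 1
            for row in rows:
                if row["gene"] == gene and row["status"] == "tested":
                    row["discordant_direction"] = discordant
    df = pd.DataFrame(rows)
    if "discordant_direction" not in df.columns:
        df["discordant_direction"] = False
    df["discordant_direction"] = (
        df["discordant_direction"].astype("boolean").fillna(False).astype(bool)
    )
    return ResultTable(df, stage="candidate_report", params={"fdr_alpha": fdr_alpha})
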