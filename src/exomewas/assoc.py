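"""Single-point allelic association.

Cases vs each control cohort on 2x2 allele-count tables: two-sided Fisher
exact p (probability-mass convention), cross-product odds ratio with
Haldane-Anscombe correction for display when a cell is zero, Bonferroni
correction, the genomic inflation factor lambda, and a permutation
QQ-envelope.

Significance testing uses the ordinary exact p.  The inflation factor is
computed from the exact mid-p of the same tables: at very small case counts
the ordinary exact p is conservative (deflating lambda even in a perfectly
homogeneous cohort) while the Pearson chi-square is anti-conservative for
low-MAF variants (inflating it); the mid-p stays near-uniform under the
null across the MAF spectrum, which is what a stratification diagnostic
needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, ResultTable, SampleLabels

log = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549364


@dataclass
class AllelicTable:
    """Allele counts: a/b = case alt/ref, c/d = control alt/ref."""

    variant_key: str
    a: int
    b: int
    c: int
    d: int

    @property
    def case_af(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def control_af(self) -> float:
        return self.c / (self.c + self.d)

    @property
    def control_maf(self) -> float:
        af = self.control_af
        return min(af, 1 - af)


@dataclass
class AssociationSummary:
    n_variants_tested: int
    bonferroni_alpha: float
    lambda_gc: float
    qq_envelope: pd.DataFrame | None = None  # per-rank percentile bands
    n_exceed_upper: int = 0
    exceeding_keys: list[str] = field(default_factory=list)


def allelic_counts(
    G: GenotypeMatrix, labels: SampleLabels, cohort: str | None = None
) -> list[AllelicTable]:
    """Build per-variant 2x2 allele-count tables, excluding missing calls.

    a = summed case alt alleles over non-missing cases, b = remaining case
    alleles; c/d likewise over the cohort's controls (``cohort=None`` or
    ``"ALL"`` pools every control).  Variants with all calls missing in
    either group are excluded and logged.
    """
    labels.validate_against(G)
    case_ids = labels.cases
    ctrl_ids = labels.controls(cohort)
    if not case_ids or not ctrl_ids:
        raise ValueError("need >= 1 case and >= 1 control")
    idx = {s: i for i, s in enumerate(G.sample_ids)}
    Xca = G.calls[[idx[s] for s in case_ids]]
    Xco = G.calls[[idx[s] for s in ctrl_ids]]
    out: list[AllelicTable] = []
    n_dropped = 0
    obs_ca, obs_co = Xca != MISSING, Xco != MISSING
    a = np.where(obs_ca, Xca, 0).sum(0)
    c = np.where(obs_co, Xco, 0).sum(0)
    n_ca, n_co = obs_ca.sum(0), obs_co.sum(0)
    for j, key in enumerate(G.variant_keys):
        if n_ca[j] == 0 or n_co[j] == 0:
            n_dropped += 1
            continue
        out.append(
            AllelicTable(
                key,
                int(a[j]),
                int(2 * n_ca[j] - a[j]),
                int(c[j]),
                int(2 * n_co[j] - c[j]),
            )
        )
    if n_dropped:
        log.info("excluded %d variants with a fully missing group", n_dropped)
    return out


def common_variant_filter(
    tables: list[AllelicTable], maf_threshold: float = 0.05
) -> list[AllelicTable]:
    """Keep variants with control minor-allele frequency strictly above the
    threshold (computed in the supplied — discovery — control cohort)."""
    if not 0 < maf_threshold < 0.5:
        raise ValueError("maf_threshold must lie in (0, 0.5)")
    return [t for t in tables if t.control_maf > maf_threshold]


@lru_cache(maxsize=1_000_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_exact(t: AllelicTable) -> tuple[float, float]:
    """Two-sided Fisher exact p and cross-product odds ratio.

    p sums hypergeometric probabilities of all tables with the observed
    margins that are at most as probable as the observed one.  The odds
    ratio is (a*d)/(b*c); when any cell is zero, 0.5 is added to every cell
    for display (Haldane-Anscombe) — never for the p-value.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("zero margin: exact test undefined")
    p = _fisher_p(a, b, c, d)
    if min(a, b, c, d) == 0:
        or_ = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        or_ = a * d / (b * c)
    return p, or_


@lru_cache(maxsize=1_000_000)
def _fisher_midp(a: int, b: int, c: int, d: int) -> float:
    n, r, k = a + b + c + d, a + b, a + c
    lo, hi = max(0, r + k - n), min(r, k)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, n, r, k)
    p_obs = pmf[a - lo]
    less = pmf[pmf < p_obs * (1 - 1e-7)].sum()
    eq = pmf[np.abs(pmf - p_obs) <= p_obs * 1e-7].sum()
    return float(min(1.0, less + 0.5 * eq))


def fisher_midp(t: AllelicTable) -> float:
    """Two-sided exact mid-p: half the probability of tables exactly as
    probable as the observed one is counted.

    At 16 case alleles the ordinary exact p is conservative (deflating
    lambda) and the Pearson chi-square is anti-conservative at low MAF
    (inflating it); the mid-p is close to uniform under the null across the
    whole MAF spectrum, so it feeds the inflation-factor diagnostic."""
    if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0:
        raise ValueError("zero margin: exact test undefined")
    return max(_fisher_midp(t.a, t.b, t.c, t.d), 1e-300)


def bonferroni(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def genomic_lambda(pvals) -> float:
    """Inflation factor: median of qchisq_1(1-p) over the chi-square median."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.median(stats.chi2.isf(p, 1)) / CHI2_MEDIAN_1DF)


def association_scan(
    G: GenotypeMatrix,
    labels: SampleLabels,
    cohort: str | None = None,
    maf_threshold: float = 0.05,
    alpha: float = 0.05,
    discovery_tables: list[AllelicTable] | None = None,
) -> tuple[ResultTable, AssociationSummary]:
    """Full single-point scan of cases vs one control cohort.

    The common-variant filter is applied on the *discovery* cohort's control
    MAF when ``discovery_tables`` is given (pseudo-replication against other
    cohorts tests the same variant set), else on this cohort's own.
    Returns a per-variant table (Manhattan-ready) and a summary with the
    Bonferroni threshold and mid-p-based lambda.
    """
    tables = allelic_counts(G, labels, cohort)
    ref = discovery_tables if discovery_tables is not None else tables
    keep_keys = {t.variant_key for t in common_variant_filter(ref, maf_threshold)}
    tested = [t for t in tables if t.variant_key in keep_keys]
    if not tested:
        raise ValueError("no variants pass the common-variant filter")
    thr = bonferroni(alpha, len(tested))
    rows = []
    mid_ps = []
    key_to_pos = dict(zip(G.variant_keys, zip(G.chrom, G.pos)))
    for t in tested:
        p, or_ = fisher_exact(t)
        p_mid = fisher_midp(t)
        mid_ps.append(p_mid)
        chrom, pos = key_to_pos[t.variant_key]
        rows.append(
            {
                "variant_key": t.variant_key,
                "chrom": chrom,
                "pos": pos,
                "case_af": t.case_af,
                "control_maf": t.control_maf,
                "or": or_,
                "p": p,
                "p_mid": p_mid,
                "significant_bonferroni": p < thr,
                "cohort": cohort or "ALL",
            }
        )
    df = pd.DataFrame(rows)
    summary = AssociationSummary(
        n_variants_tested=len(tested),
        bonferroni_alpha=thr,
        lambda_gc=genomic_lambda(mid_ps),
    )
    rt = ResultTable(
        df,
        stage="assoc",
        params={"cohort": cohort or "ALL", "maf_threshold": maf_threshold, "alpha": alpha},
    )
    return rt, summary


def _scan_pvals_fast(
    Xca: np.ndarray, Xco: np.ndarray
) -> np.ndarray:
    """Fisher p per variant for a case/control genotype split (vectorized
    bookkeeping, memoized exact test)."""
    obs_ca, obs_co = Xca != MISSING, Xco != MISSING
    a = np.where(obs_ca, Xca, 0).sum(0)
    c = np.where(obs_co, Xco, 0).sum(0)
    n_ca, n_co = obs_ca.sum(0), obs_co.sum(0)
    out = np.ones(Xca.shape[1])
    for j in range(Xca.shape[1]):
        if n_ca[j] == 0 or n_co[j] == 0:
            continue
        out[j] = _fisher_p(
            int(a[j]), int(2 * n_ca[j] - a[j]), int(c[j]), int(2 * n_co[j] - c[j])
        )
    return out


def qq_envelope(
    G: GenotypeMatrix,
    labels: SampleLabels,
    cohort: str | None = None,
    maf_threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AssociationSummary:
    """Permutation QQ-envelope for the single-point scan.

    Case/control labels are permuted ``n_perm`` times preserving group
    sizes; the Fisher scan is re-run per permutation on the common-filtered
    variant set; per-rank 2.5/97.5 percentiles of sorted -log10 p form the
    envelope.  Observed variants whose -log10 p exceeds the upper band at
    their rank are reported.
    """
    if n_perm < 100:
        log.warning("n_perm=%d < 100: envelope unstable", n_perm)
    tables = allelic_counts(G, labels, cohort)
    keep = {t.variant_key for t in common_variant_filter(tables, maf_threshold)}
    keep_idx = [j for j, k in enumerate(G.variant_keys) if k in keep]
    Gc = G.subset_variants(np.array(keep_idx))
    idx = {s: i for i, s in enumerate(Gc.sample_ids)}
    case_ids, ctrl_ids = labels.cases, labels.controls(cohort)
    rows = np.array([idx[s] for s in case_ids + ctrl_ids])
    X = Gc.calls[rows]
    n_case = len(case_ids)

    obs_p = _scan_pvals_fast(X[:n_case], X[n_case:])
    obs_sorted = np.sort(-np.log10(obs_p))[::-1]

    rng = np.random.default_rng(seed)
    perm_sorted = np.empty((n_perm, X.shape[1]))
    for r in range(n_perm):
        perm = rng.permutation(X.shape[0])
        p = _scan_pvals_fast(X[perm[:n_case]], X[perm[n_case:]])
        perm_sorted[r] = np.sort(-np.log10(p))[::-1]
    lo, hi = np.percentile(perm_sorted, [2.5, 97.5], axis=0)
    order = np.argsort(obs_p)
    exceed = obs_sorted > hi
    exceeding = [Gc.variant_keys[order[r]] for r in np.flatnonzero(exceed)]
    env = pd.DataFrame(
        {
            "rank": np.arange(1, X.shape[1] + 1),
            "observed_neglog10p": obs_sorted,
            "lower": lo,
            "upper": hi,
        }
    )
    mid_ps = [fisher_midp(t) for t in tables if t.variant_key in keep]
    return AssociationSummary(
        n_variants_tested=X.shape[1],
        bonferroni_alpha=bonferroni(alpha, X.shape[1]),
        lambda_gc=genomic_lambda(mid_ps),
        qq_envelope=env,
        n_exceed_upper=int(exceed.sum()),
        exceeding_keys=exceeding,
    )
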