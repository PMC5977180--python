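"""Population-structure QC.

Pairwise identity-by-state (IBS), classical (Torgerson) multidimensional
scaling of the 1-IBS distance matrix, a supervised least-squares ancestry
estimator against reference-panel allele frequencies, and PLINK-style
method-of-moments relatedness screening (pi-hat).

The ancestry estimator deliberately replaces an unsupervised ADMIXTURE-style
maximum-likelihood fit: the QC question here is confirmatory ("are the cases
European?"), the reference panels are known, and a simplex-constrained
least-squares projection of allele dosages onto reference frequencies
answers it deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class IBSMatrix:
    sample_ids: list[str]
    similarity: np.ndarray  # (n, n), NaN where no shared loci
    n_loci_used: np.ndarray  # (n, n) int

    def distance(self) -> np.ndarray:
        return 1.0 - self.similarity


@dataclass
class MDSResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n, k), column j scaled by sqrt(eigenvalue j)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    k: int


@dataclass
class AncestryEstimate:
    sample_id: str
    proportions: dict[str, float]
    degenerate: bool = False


@dataclass
class RelatednessEstimate:
    sample_a: str
    sample_b: str
    ibs0: float
    ibs1: float
    ibs2: float
    pi_hat: float


def ibs_matrix(G: GenotypeMatrix) -> IBSMatrix:
    """Mean per-locus allele sharing (2 - |g_a - g_b|)/2 over jointly
    non-missing loci for every sample pair.

    Vectorized through one-hot genotype indicators: the count of pair-loci
    with genotypes (k, l) is H_k H_l^T, so both the shared-locus count and
    the summed allele distance are nine matrix products.
    """
    X = G.calls
    H = [(X == k).astype(np.float64) for k in (0, 1, 2)]
    n = G.n_samples
    n_shared = np.zeros((n, n))
    dist_sum = np.zeros((n, n))
    for k in range(3):
        for l in range(3):
            C = H[k] @ H[l].T
            n_shared += C
            dist_sum += abs(k - l) * C
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (2 * n_shared - dist_sum) / (2 * n_shared)
    empty = n_shared == 0
    if empty.any():
        log.warning("%d sample pairs share no genotyped loci", int(empty.sum() / 2))
        sim[empty] = np.nan
    np.fill_diagonal(sim, 1.0)
    return IBSMatrix(list(G.sample_ids), sim, n_shared.astype(np.int64))


def classical_mds(D: np.ndarray, k: int, sample_ids: list[str] | None = None) -> MDSResult:
    """Torgerson scaling: double-center -D^2/2, eigendecompose, embed.

    Negative eigenvalues (non-Euclidean distances) are reported but never
    used for coordinates; ``k`` is truncated to the number of positive
    eigenvalues with a warning.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-12).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        log.warning("MDS k truncated from %d to %d positive eigenvalues", k, k_eff)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    if k_eff == 0:
        coords = np.zeros((n, max(k, 1)))
        k_eff = coords.shape[1]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return MDSResult(list(sample_ids), coords, evals, k_eff)


def supervised_ancestry(
    g: np.ndarray, ref_freqs: pd.DataFrame, sample_id: str = ""
) -> AncestryEstimate:
    """Estimate ancestry proportions of one genotype row.

    Minimizes || g/2 - F^T w ||^2 over the probability simplex, where F is
    the (population x variant) reference allele-frequency table.  Missing
    genotypes are dropped.  Deterministic (SLSQP from the barycenter).
    """
    pops = list(ref_freqs.index)
    F = ref_freqs.to_numpy(dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    keep = g != MISSING
    g, F = g[keep], F[:, keep]
    if g.size < 50:
        raise ValueError("need >= 50 variants with reference frequencies")
    degenerate = False
    if len(pops) > 1:
        d = np.max(np.abs(F[:, None, :] - F[None, :, :]), axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-12:
            degenerate = True
            log.warning("identical reference frequency rows: ancestry not identifiable")
    target = g / 2.0
    K = len(pops)
    w0 = np.full(K, 1.0 / K)

    def obj(w):
        r = F.T @ w - target
        return r @ r

    def grad(w):
        return 2 * F @ (F.T @ w - target)

    res = minimize(
        obj,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0, None)
    w /= w.sum()
    return AncestryEstimate(sample_id, dict(zip(pops, w)), degenerate)


def _ibs_class_expectations(p: np.ndarray) -> np.ndarray:
    """Per-locus P(IBS=i | IBD=j) summed over loci.

    Returns a 3x3 array E[i, j] = sum_loci P(IBS=i | IBD=j) for alt-allele
    frequency p per locus (no small-sample correction; pooled-sample
    frequencies are used, which is adequate at >= 100 samples).
    """
    q = 1 - p
    E = np.zeros((3, 3))
    E[0, 0] = (2 * p**2 * q**2).sum()
    E[1, 0] = (4 * p**3 * q + 4 * p * q**3).sum()
    E[2, 0] = (p**4 + q**4 + 4 * p**2 * q**2).sum()
    E[0, 1] = 0.0
    E[1, 1] = (2 * p * q).sum()
    E[2, 1] = (p**2 + q**2).sum()
    E[0, 2] = 0.0
    E[1, 2] = 0.0
    E[2, 2] = float(len(p))
    return E


def relatedness(G: GenotypeMatrix, min_maf: float = 0.05) -> list[RelatednessEstimate]:
    """PLINK-style method-of-moments IBD estimation for all sample pairs.

    Observed counts of IBS sharing classes (0/1/2) per pair are matched to
    their expectations under IBD states z0/z1/z2 computed from pooled-sample
    allele frequencies at common loci; estimates are clamped to the simplex
    and summarized as pi_hat = z1/2 + z2.
    """
    X = G.calls.astype(np.float64)
    obs = X != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(obs, X, 0).sum(0) / (2 * obs.sum(0).clip(min=1))
    maf = np.minimum(p, 1 - p)
    keep = (maf > min_maf) & (obs.all(0))
    if keep.sum() == 0:
        raise ValueError("no common polymorphic loci for relatedness estimation")
    if keep.sum() < 200:
        log.warning("only %d common loci; pi_hat estimates unstable", int(keep.sum()))
    Xc, pc = X[:, keep], p[keep]
    E = _ibs_class_expectations(pc)
    n = G.n_samples
    out: list[RelatednessEstimate] = []
    # IBS class counts via one-hot products (|ga-gb| = 2 -> IBS0, etc.)
    H = [(Xc == k).astype(np.float64) for k in (0, 1, 2)]
    N2 = H[0] @ H[0].T + H[1] @ H[1].T + H[2] @ H[2].T
    N0 = H[0] @ H[2].T + H[2] @ H[0].T
    m = keep.sum()
    for i in range(n):
        for j in range(i + 1, n):
            n2, n0 = N2[i, j], N0[i, j]
            n1 = m - n2 - n0
            z0 = n0 / E[0, 0] if E[0, 0] > 0 else 0.0
            z1 = (n1 - z0 * E[1, 0]) / E[1, 1] if E[1, 1] > 0 else 0.0
            z0c, z1c = np.clip(z0, 0, 1), np.clip(z1, 0, 1)
            z2c = np.clip(1 - z0c - z1c, 0, 1)
            s = z0c + z1c + z2c
            z0c, z1c, z2c = z0c / s, z1c / s, z2c / s
            pi = float(np.clip(z1c / 2 + z2c, 0, 1))
            out.append(
                RelatednessEstimate(
                    G.sample_ids[i],
                    G.sample_ids[j],
                    n0 / m,
                    n1 / m,
                    n2 / m,
                    pi,
                )
            )
    return out


def mds_from_genotypes(G: GenotypeMatrix, k: int = 10) -> tuple[IBSMatrix, MDSResult]:
    """Convenience: IBS similarity -> 1-IBS distance -> classical MDS."""
    ibs = ibs_matrix(G)
    D = ibs.distance()
    if np.isnan(D).any():
        raise ValueError("cannot run MDS with sample pairs lacking shared loci")
    return ibs, classical_mds(D, k, sample_ids=ibs.sample_ids)
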