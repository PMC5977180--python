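"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by EM (double-heterozygotes
split between cis and trans phase proportionally to current haplotype
frequency products), giving D, D' and r^2.  Confidence intervals on |D'|
follow the Wall-Pritchard likelihood convention used for Gabriel-style
block calling: the genotype likelihood is profiled on a 101-point |D'| grid
with allele frequencies fixed at their observed values, normalized to a
discrete posterior, and the one-sided 5%/95% bounds are read off the
cumulative mass.  Blocks are contiguous spans in which at least 95% of
informative pairs are in strong LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import MISSING, GenotypeMatrix

EM_TOL = 1e-10
EM_MAX_ITER = 1000

# Gabriel-style classification thresholds (CI on |D'|)
STRONG_LD_LOWER = 0.70
STRONG_LD_UPPER = 0.98
RECOMB_UPPER = 0.90
BLOCK_STRONG_FRACTION = 0.95


class MonomorphicError(ValueError):
    pass


@dataclass
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes (AB, Ab, aB, ab);
    'A'/'B' denote the alternate alleles."""

    f_ab: np.ndarray  # length 4: [AB, Ab, aB, ab]
    loglik: float
    n_iter: int
    monomorphic: bool = False

    @property
    def p_a(self) -> float:
        return float(self.f_ab[0] + self.f_ab[1])

    @property
    def p_b(self) -> float:
        return float(self.f_ab[0] + self.f_ab[2])


@dataclass
class LDPair:
    i: int
    j: int
    D: float
    Dmax: float
    dprime: float
    r2: float
    ci_lower: float | None = None
    ci_upper: float | None = None

    @property
    def strong_ld(self) -> bool:
        return (
            self.ci_lower is not None
            and self.ci_lower >= STRONG_LD_LOWER
            and self.ci_upper >= STRONG_LD_UPPER
        )

    @property
    def strong_recombination(self) -> bool:
        return self.ci_upper is not None and self.ci_upper < RECOMB_UPPER

    @property
    def informative(self) -> bool:
        return self.strong_ld or self.strong_recombination


@dataclass
class LDBlock:
    start_idx: int  # inclusive variant indices
    end_idx: int
    n_informative_pairs: int
    fraction_strong_ld: float


def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    if g1.size < 2:
        raise ValueError("need >= 2 jointly non-missing samples")
    n = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            n[a, b] = int(((g1 == a) & (g2 == b)).sum())
    return n


def _genotype_probs(f: np.ndarray) -> np.ndarray:
    """P(g1, g2) for the nine unphased genotype pairs given haplotype freqs
    f = [AB, Ab, aB, ab]."""
    fAB, fAb, faB, fab = f
    P = np.zeros((3, 3))
    # haplotype per (allele1, allele2): (1,1)->AB, (1,0)->Ab, (0,1)->aB, (0,0)->ab
    h = {(1, 1): fAB, (1, 0): fAb, (0, 1): faB, (0, 0): fab}
    for a1 in (0, 1):
        for b1 in (0, 1):
            for a2 in (0, 1):
                for b2 in (0, 1):
                    pr = h[(a1, b1)] * h[(a2, b2)]
                    P[a1 + a2, b1 + b2] += pr
    return P


def _loglik(n: np.ndarray, f: np.ndarray) -> float:
    P = _genotype_probs(f)
    mask = n > 0
    if (P[mask] <= 0).any():
        return -np.inf
    return float((n[mask] * np.log(P[mask])).sum())


def em_haplotypes(g1: np.ndarray, g2: np.ndarray) -> HaplotypeFreqs:
    """EM estimate of two-locus haplotype frequencies from unphased calls.

    Initialized at linkage equilibrium (product of observed allele
    frequencies); the double-heterozygote class is split between cis and
    trans phase by current frequency products each iteration.  The
    log-likelihood is non-decreasing; convergence at max frequency change
    below 1e-10 or 1000 iterations.
    """
    n = _pair_counts(np.asarray(g1), np.asarray(g2))
    N = n.sum()
    p1 = (n * np.arange(3)[:, None]).sum() / (2 * N)
    p2 = (n * np.arange(3)[None, :]).sum() / (2 * N)
    mono = p1 in (0.0, 1.0) or p2 in (0.0, 1.0)
    f = np.array(
        [p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)], dtype=float
    )
    if mono:
        return HaplotypeFreqs(f, _loglik(n, f), 0, monomorphic=True)

    # fixed haplotype contributions from unambiguous genotype classes:
    # class (g1,g2) contributes g1 copies of allele A and g2 of B across its
    # two haplotypes; only (1,1) is phase-ambiguous.
    def fixed_counts() -> np.ndarray:
        c = np.zeros(4)
        for a in range(3):
            for b in range(3):
                if (a, b) == (1, 1) or n[a, b] == 0:
                    continue
                # haplotype 1 carries min(a,1)/min(b,1)? enumerate directly:
                # genotype (a,b) with a,b in {0,1,2}, not both 1 -> unique diplotype
                h1 = (1 if a >= 1 else 0, 1 if b >= 1 else 0)
                h2 = (1 if a == 2 else 0, 1 if b == 2 else 0)
                for (x, y) in (h1, h2):
                    k = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(x, y)]
                    c[k] += n[a, b]
        return c

    base = fixed_counts()
    n_dh = n[1, 1]
    ll_prev = -np.inf
    it = 0
    for it in range(1, EM_MAX_ITER + 1):
        fAB, fAb, faB, fab = f
        denom = fAB * fab + fAb * faB
        pi_cis = 0.5 if denom == 0 else fAB * fab / denom
        c = base.copy()
        c[0] += n_dh * pi_cis
        c[3] += n_dh * pi_cis
        c[1] += n_dh * (1 - pi_cis)
        c[2] += n_dh * (1 - pi_cis)
        f_new = c / (2 * N)
        ll = _loglik(n, f_new)
        if ll < ll_prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        delta = np.abs(f_new - f).max()
        f, ll_prev = f_new, ll
        if delta < EM_TOL:
            break
    return HaplotypeFreqs(f, ll_prev, it)


def ld_stats(h: HaplotypeFreqs, i: int = 0, j: int = 1) -> LDPair:
    """D, Dmax, signed D' and r^2 from haplotype frequencies."""
    if h.monomorphic:
        raise MonomorphicError("LD undefined for a monomorphic locus")
    pA, pB = h.p_a, h.p_b
    qA, qB = 1 - pA, 1 - pB
    D = float(h.f_ab[0] - pA * pB)
    if D > 0:
        Dmax = min(pA * qB, qA * pB)
    else:
        Dmax = min(pA * pB, qA * qB)
    dprime = 0.0 if Dmax == 0 else D / Dmax
    r2 = D * D / (pA * qA * pB * qB)
    return LDPair(i, j, D, Dmax, float(dprime), float(r2))


def dprime_ci(
    g1: np.ndarray, g2: np.ndarray, grid: int = 101
) -> tuple[float, float]:
    """Wall-Pritchard one-sided 5%/95% likelihood bounds on |D'|.

    The genotype likelihood is evaluated on a uniform |D'| grid (sign taken
    from the EM point estimate, allele frequencies fixed at observed
    values), normalized to a discrete posterior under a flat prior; lower /
    upper are the smallest grid values whose cumulative mass reaches 0.05 /
    0.95.
    """
    g1, g2 = np.asarray(g1), np.asarray(g2)
    n = _pair_counts(g1, g2)
    h = em_haplotypes(g1, g2)
    if h.monomorphic:
        raise MonomorphicError("D' CI undefined for a monomorphic locus")
    pA, pB = h.p_a, h.p_b
    qA, qB = 1 - pA, 1 - pB
    point = ld_stats(h)
    sign = 1.0 if point.D >= 0 else -1.0
    Dmax = min(pA * qB, qA * pB) if sign > 0 else min(pA * pB, qA * qB)
    dgrid = np.linspace(0, 1, grid)
    lls = np.full(grid, -np.inf)
    for k, dp in enumerate(dgrid):
        D = sign * dp * Dmax
        f = np.array(
            [pA * pB + D, pA * qB - D, qA * pB - D, qA * qB + D]
        )
        f = np.clip(f, 0.0, 1.0)
        s = f.sum()
        if s <= 0:
            continue
        lls[k] = _loglik(n, f / s)
    post = np.exp(lls - lls.max())
    post /= post.sum()
    cum = np.cumsum(post)
    lower = float(dgrid[int(np.searchsorted(cum, 0.05))])
    upper = float(dgrid[int(np.searchsorted(cum, 0.95))])
    return lower, upper


def ld_pair(G: GenotypeMatrix, i: int, j: int) -> LDPair:
    """Full LD summary (EM stats + D' CI) for one variant pair."""
    g1, g2 = G.calls[:, i], G.calls[:, j]
    h = em_haplotypes(g1, g2)
    if h.monomorphic:
        return LDPair(i, j, 0.0, 0.0, 0.0, 0.0, None, None)
    pair = ld_stats(h, i, j)
    pair.ci_lower, pair.ci_upper = dprime_ci(g1, g2)
    return pair


def compute_ld_pairs(
    G: GenotypeMatrix,
    variant_idx: list[int] | np.ndarray,
    window_bp: int = 500_000,
) -> list[LDPair]:
    """All within-window LD pairs among the given variant columns."""
    variant_idx = sorted(variant_idx, key=lambda v: (str(G.chrom[v]), int(G.pos[v])))
    pairs = []
    for ii in range(len(variant_idx)):
        for jj in range(ii + 1, len(variant_idx)):
            vi, vj = variant_idx[ii], variant_idx[jj]
            if G.chrom[vi] != G.chrom[vj]:
                continue
            if abs(int(G.pos[vj]) - int(G.pos[vi])) > window_bp:
                continue
            pairs.append(ld_pair(G, vi, vj))
    return pairs


def gabriel_blocks(pairs: list[LDPair], n_variants: int | None = None) -> list[LDBlock]:
    """Call LD blocks from classified pairs.

    A candidate block is a contiguous index span (length >= 2) whose
    informative pairs are at least 95% strong LD (and at least one
    informative pair exists); overlapping candidates are resolved
    longest-first (ties: leftmost).  Pair indices refer to positions in the
    sorted variant list used to build them.
    """
    if not pairs:
        return []
    idx = sorted({p.i for p in pairs} | {p.j for p in pairs})
    order = {v: r for r, v in enumerate(idx)}
    m = len(idx)
    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for p in pairs:
        a, b = order[p.i], order[p.j]
        informative[a, b] = informative[b, a] = p.informative
        strong[a, b] = strong[b, a] = p.strong_ld
    candidates: list[LDBlock] = []
    for a in range(m):
        for b in range(a + 1, m):
            sub_inf = informative[a : b + 1, a : b + 1]
            sub_str = strong[a : b + 1, a : b + 1]
            n_inf = int(np.triu(sub_inf, 1).sum())
            if n_inf == 0:
                continue
            n_str = int(np.triu(sub_str, 1).sum())
            frac = n_str / n_inf
            if frac >= BLOCK_STRONG_FRACTION:
                candidates.append(LDBlock(idx[a], idx[b], n_inf, frac))
    candidates.sort(key=lambda bl: (-(bl.end_idx - bl.start_idx), bl.start_idx))
    chosen: list[LDBlock] = []
    used: set[int] = set()
    for bl in candidates:
        span = set(range(order[bl.start_idx], order[bl.end_idx] + 1))
        if span & used:
            continue
        chosen.append(bl)
        used |= span
    chosen.sort(key=lambda bl: bl.start_idx)
    return chosen
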