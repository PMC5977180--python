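"""Synthetic cohort generator.

Emulates the statistical structure of a small case-control exome study:
a handful of cases against several European-like reference control cohorts,
~1e4-1e5 exonic biallelic SNVs with a Balding-Nichols population-structure
model, a few injected single-point risk variants, a few genes carrying a
case-enriched burden of rare, high-DANN variants, and two-group expression
matrices for the validation stage.

Population-specific allele frequencies follow Balding-Nichols: given an
ancestral frequency p and differentiation F, the per-population frequency is
Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes are then Binomial(2, freq).  All
randomness flows from a single integer seed through named spawned
sub-streams, so each stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    GenotypeMatrix,
    SampleLabels,
    write_annotation,
    write_labels,
    write_vcf,
)

#: Control cohort sizes emulating the 1000 Genomes European panels.
DEFAULT_COHORTS = {"IBS": 107, "TSI": 107, "GBR": 91, "CEU": 99}


class ConfigError(ValueError):
    pass


@dataclass
class RiskVariant:
    """A single-point association signal: distinct case/control frequencies."""

    index: int
    case_freq: float
    control_freq: float


@dataclass
class BurdenGene:
    """A gene whose rare variants are preferentially carried by cases."""

    gene: str
    n_rare_variants: int
    enrichment: float = 10.0  # case allele frequency = enrichment x control
    dann_beta: tuple[float, float] = (8.0, 2.0)
    control_freq_range: tuple[float, float] = (0.002, 0.03)


@dataclass
class SimConfig:
    """Genotype-cohort simulation settings.

    Defaults mirror the study design: 8 cases against four European-like
    control panels, intra-European differentiation F=0.005, an ancestral
    frequency distribution giving roughly the observed common/rare split at
    control MAF 0.05, high-DANN Beta(8,2) scores on burden-gene variants
    against a Beta(2,2) background.
    """

    n_cases: int = 8
    n_controls_per_cohort: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORTS)
    )
    n_variants: int = 10_000
    # Beta(a, b) ancestral frequencies; (0.15, 0.7) puts ~38% of variants at
    # folded MAF > 0.05, matching the exome common/rare split the scan sees
    maf_distribution: tuple[float, float] = (0.15, 0.7)
    maf_range: tuple[float, float] | None = None  # optional truncation
    fst: dict[str, float] | float = 0.005
    case_population: str = "IBS"  # cases drawn from this cohort's frequencies
    risk_variants: list[RiskVariant] = field(default_factory=list)
    burden_genes: list[BurdenGene] = field(default_factory=list)
    null_dann: tuple[float, float] = (2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v.index >= self.n_variants for v in self.risk_variants):
            raise ConfigError("risk variant index exceeds n_variants")
        if len(self.risk_variants) > self.n_variants:
            raise ConfigError("more risk variants than variants")
        for v in self.risk_variants:
            if not (0 < v.case_freq < 1 and 0 < v.control_freq < 1):
                raise ConfigError("risk frequencies must lie in (0,1)")
        fsts = self.fst.values() if isinstance(self.fst, dict) else [self.fst]
        if any(not (0 <= f < 1) for f in fsts):
            raise ConfigError("fst must lie in [0,1)")


@dataclass
class ExpressionSimConfig:
    """Two-group expression study settings (log2-scale Gaussian matrix).

    ``var_prior_df`` draws per-gene variances from a scaled inverse
    chi-square around ``noise_sd**2`` (the empirical-Bayes variance model
    real array data follows); None keeps every gene at ``noise_sd``.
    """

    n_genes: int = 1000
    n_per_group: tuple[int, int] = (10, 10)
    de_genes: list[tuple[str, float]] = field(default_factory=list)  # (gene, log2FC)
    noise_sd: float = 1.0
    var_prior_df: float | None = None
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ConfigError("need >= 2 samples per group")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.var_prior_df is not None and self.var_prior_df <= 0:
            raise ConfigError("var_prior_df must be positive")


@dataclass
class ExpressionStudy:
    """Genes x samples log-expression with two-group labels."""

    genes: list[str]
    expression: np.ndarray  # (n_genes, n_samples)
    group: np.ndarray  # "case"/"control" per sample
    sample_ids: list[str]
    study: str = "synthetic"
    truth: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.expression, index=self.genes, columns=self.sample_ids)
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.6g")


def _fst_for(cfg: SimConfig, pop: str) -> float:
    if isinstance(cfg.fst, dict):
        return cfg.fst.get(pop, 0.0)
    return float(cfg.fst)


def _bn_freq(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols population frequency draw; F=0 returns p unchanged."""
    if F == 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)


def gen_genotypes(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, SampleLabels, pd.DataFrame]:
    """Simulate a structured case-control cohort.

    Returns the genotype matrix, sample labels (cases tagged with no cohort,
    controls with their cohort id and population), and an annotation table
    with gene assignment, functional class and DANN score per variant.
    Background variants are assigned placeholder gene symbols in blocks of 20
    so the burden scan has a realistic gene universe.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_freq, rng_geno, rng_dann, rng_burden = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    n_bg = cfg.n_variants
    a, b = cfg.maf_distribution
    anc = rng_freq.beta(a, b, size=n_bg)
    if cfg.maf_range is not None:
        lo, hi = cfg.maf_range
        out = (anc < lo) | (anc > hi)
        while out.any():
            anc[out] = rng_freq.beta(a, b, size=int(out.sum()))
            out = (anc < lo) | (anc > hi)
    anc = np.clip(anc, 1e-4, 1 - 1e-4)

    pops = list(cfg.n_controls_per_cohort)
    pop_freq = {p: _bn_freq(rng_freq, anc, _fst_for(cfg, p)) for p in pops}
    case_base = pop_freq.get(cfg.case_population, anc).copy()

    # risk variants override frequencies in every population
    for rv in cfg.risk_variants:
        case_base[rv.index] = rv.case_freq
        for p in pops:
            pop_freq[p][rv.index] = rv.control_freq

    # burden genes append extra rare variants with case enrichment
    burden_keys: list[tuple[str, float, float]] = []  # (gene, ctrl_freq, case_freq)
    for bg in cfg.burden_genes:
        lo, hi = bg.control_freq_range
        ctrl = rng_burden.uniform(lo, hi, size=bg.n_rare_variants)
        case = np.minimum(0.5, ctrl * bg.enrichment)
        burden_keys += [(bg.gene, c, q) for c, q in zip(ctrl, case)]

    m_total = n_bg + len(burden_keys)

    sample_ids: list[str] = [f"case{i+1}" for i in range(cfg.n_cases)]
    status = ["case"] * cfg.n_cases
    cohort = [""] * cfg.n_cases
    population = [cfg.case_population] * cfg.n_cases
    for p in pops:
        n = cfg.n_controls_per_cohort[p]
        sample_ids += [f"{p}_{i+1}" for i in range(n)]
        status += ["control"] * n
        cohort += [p] * n
        population += [p] * n

    calls = np.empty((len(sample_ids), m_total), dtype=np.int8)
    row = 0
    for grp_freq, n in [(case_base, cfg.n_cases)] + [
        (pop_freq[p], cfg.n_controls_per_cohort[p]) for p in pops
    ]:
        if burden_keys:
            is_case_block = row == 0
            extra = np.array(
                [q if is_case_block else c for (_, c, q) in burden_keys]
            )
            freqs = np.concatenate([grp_freq, extra])
        else:
            freqs = grp_freq
        calls[row : row + n] = rng_geno.binomial(
            2, freqs[None, :].repeat(n, axis=0)
        ).astype(np.int8)
        row += n

    # variant bookkeeping: background variants in gene blocks of 20
    chroms = [str(1 + (j % 22)) for j in range(m_total)]
    pos = np.arange(1, m_total + 1) * 1000
    keys = [f"{chroms[j]}:{pos[j]}:A:G" for j in range(m_total)]
    genes = [f"GENE{j // 20:05d}" for j in range(n_bg)] + [g for (g, _, _) in burden_keys]

    dann = rng_dann.beta(*cfg.null_dann, size=m_total)
    offset = n_bg
    for bg in cfg.burden_genes:
        k = bg.n_rare_variants
        dann[offset : offset + k] = rng_dann.beta(*bg.dann_beta, size=k)
        offset += k

    G = GenotypeMatrix(sample_ids, keys, calls, np.array(chroms, dtype=object), pos)
    labels = SampleLabels(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "status": status,
                "cohort": cohort,
                "population": population,
            }
        )
    )
    ann = pd.DataFrame(
        {
            "variant_key": keys,
            "gene": genes,
            "func_class": "exonic",
            "dann": dann,
        }
    )
    # generator bookkeeping: configured frequencies per stratum, so tests and
    # downstream truth checks never re-derive the random streams
    if burden_keys:
        extra_case = np.array([q for (_, _, q) in burden_keys])
        extra_ctrl = np.array([c for (_, c, _) in burden_keys])
    else:
        extra_case = extra_ctrl = np.empty(0)
    ann["sim_freq_case"] = np.concatenate([case_base, extra_case])
    for p in pops:
        ann[f"sim_freq_{p}"] = np.concatenate([pop_freq[p], extra_ctrl])
    return G, labels, ann


def true_control_freqs(cfg: SimConfig, cohort: str) -> np.ndarray | None:
    """Configured (not realized) control frequencies for risk variants."""
    if not cfg.risk_variants:
        return None
    return np.array([rv.control_freq for rv in cfg.risk_variants])


def gen_expression(cfg: ExpressionSimConfig, study: str = "synthetic") -> ExpressionStudy:
    """Simulate a two-group log-scale expression study.

    DE genes get their configured log2 fold change added to the case group;
    everything else is exchangeable Gaussian noise around the baseline.
    """
    rng = np.random.default_rng(cfg.seed)
    n1, n0 = cfg.n_per_group
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    de_map = dict(cfg.de_genes)
    for g in de_map:
        if g not in genes:
            genes[_stable_slot(g, cfg.n_genes)] = g  # replace a background gene
    if cfg.var_prior_df is not None:
        d0 = cfg.var_prior_df
        gene_sd = cfg.noise_sd * np.sqrt(d0 / rng.chisquare(d0, size=cfg.n_genes))
    else:
        gene_sd = np.full(cfg.n_genes, cfg.noise_sd)
    mat = rng.normal(
        cfg.baseline_mean, gene_sd[:, None], size=(cfg.n_genes, n1 + n0)
    )
    group = np.array(["case"] * n1 + ["control"] * n0)
    for g, lfc in de_map.items():
        i = genes.index(g)
        mat[i, :n1] += lfc
    ids = [f"s{i+1}" for i in range(n1 + n0)]
    return ExpressionStudy(genes, mat, group, ids, study=study, truth={"de": de_map})


def _stable_slot(name: str, n: int) -> int:
    # process-independent (str hash() is salted per interpreter run)
    return zlib.crc32(name.encode()) % n


def write_cohort(
    G: GenotypeMatrix,
    labels: SampleLabels,
    ann: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit VCF + annotation TSV + labels TSV into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "annotation": out / "annotation.tsv",
        "labels": out / "labels.tsv",
    }
    write_vcf(G, paths["vcf"])
    write_annotation(ann, paths["annotation"])
    write_labels(labels, paths["labels"])
    return paths
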