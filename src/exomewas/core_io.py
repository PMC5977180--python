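"""Shared data model and file I/O.

The pipeline's central object is a dense genotype matrix of alternate-allele
counts (samples x biallelic variants, codes 0/1/2 with -1 for missing), read
from VCF via :mod:`cyvcf2`.  Variant annotations (gene, functional class,
DANN deleteriousness score) and sample labels travel as pandas DataFrames;
all results are written as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = -1

#: Functional-class vocabulary for exonic annotation (ANNOVAR-style).
FUNC_CLASSES = frozenset(
    {
        "downstream",
        "exonic",
        "exonic_splicing",
        "intergenic",
        "intronic",
        "ncRNA_exonic",
        "ncRNA_exonic_splicing",
        "ncRNA_intronic",
        "ncRNA_splicing",
        "splicing",
        "upstream",
        "upstream_downstream",
        "3UTR",
        "5UTR",
        "5UTR_3UTR",
        "nonsynonymous_SNV",
        "stopgain",
        "stoploss",
        "synonymous_SNV",
        "unknown",
    }
)

_CLASS_ALIASES = {
    "exonic;splicing": "exonic_splicing",
    "exonic/splicing": "exonic_splicing",
    "ncrna_exonic;splicing": "ncRNA_exonic_splicing",
    "upstream;downstream": "upstream_downstream",
    "3'-utr": "3UTR",
    "3utr": "3UTR",
    "utr3": "3UTR",
    "5'-utr": "5UTR",
    "5utr": "5UTR",
    "utr5": "5UTR",
    "5'-utr5/3'-utr": "5UTR_3UTR",
    "5utr_3utr": "5UTR_3UTR",
    "nonsynonymous snv": "nonsynonymous_SNV",
    "non-synonymous snv": "nonsynonymous_SNV",
    "synonymous snv": "synonymous_SNV",
}


class VCFFormatError(ValueError):
    """Raised when a VCF lacks required fields or cannot be parsed."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing mandatory columns."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants, alternate-allele dosage coding.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, in file order.
    variant_keys : list of str
        Unique ``"chrom:pos:ref:alt"`` keys (1-based positions as in VCF).
    calls : ndarray of int8, shape (n_samples, n_variants)
        Alternate-allele counts in {0, 1, 2}; ``MISSING`` (-1) for no-calls
        and half-calls.
    chrom, pos : arrays
        Per-variant chromosome label and 1-based position.
    """

    sample_ids: list[str]
    variant_keys: list[str]
    calls: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.calls.shape
        if n != len(self.sample_ids) or m != len(self.variant_keys):
            raise ValueError("calls shape does not match sample/variant lists")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids not unique")
        if len(set(self.variant_keys)) != m:
            raise ValueError("variant_keys not unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls outside {0,1,2,missing}")
        if (self.pos < 1).any():
            raise ValueError("positions must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def subset_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.variant_keys),
            self.calls[idx],
            self.chrom,
            self.pos,
        )

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.variant_keys[i] for i in idx],
            self.calls[:, idx],
            self.chrom[idx],
            self.pos[idx],
        )


@dataclass
class SampleLabels:
    """Case/control status plus optional cohort and reference-population tags."""

    table: pd.DataFrame  # columns: sample_id, status, cohort, population

    def __post_init__(self) -> None:
        required = {"sample_id", "status"}
        if not required.issubset(self.table.columns):
            raise SchemaError(f"label table needs columns {sorted(required)}")
        bad = set(self.table["status"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in labels")
        for col in ("cohort", "population"):
            if col not in self.table.columns:
                self.table[col] = ""
        self.table = self.table.fillna({"cohort": "", "population": ""})

    @property
    def cases(self) -> list[str]:
        t = self.table
        return list(t.loc[t.status == "case", "sample_id"])

    def controls(self, cohort: str | None = None) -> list[str]:
        t = self.table[self.table.status == "control"]
        if cohort is not None and cohort != "ALL":
            t = t[t.cohort == cohort]
        return list(t["sample_id"])

    @property
    def cohorts(self) -> list[str]:
        vals = self.table.loc[self.table.status == "control", "cohort"]
        return sorted(set(vals))

    def validate_against(self, G: GenotypeMatrix) -> None:
        missing = set(G.sample_ids) - set(self.table["sample_id"])
        if missing:
            raise ValueError(f"{len(missing)} samples lack labels")


@dataclass
class ResultTable:
    """Rectangular results with provenance metadata (stage, parameters, seed)."""

    data: pd.DataFrame
    stage: str
    params: dict = field(default_factory=dict)

    def write(self, path: str | Path, float_fmt: str = "%.6g") -> None:
        write_results(self, path, float_fmt=float_fmt)


def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read genotype dosages from a VCF 4.x file (gzip-transparent).

    Multi-allelic records are split into one biallelic key per alternate
    allele unless ``biallelic_only`` is set, in which case they are skipped.
    ``./.`` and half-calls become the missing code.  Non-autosomal records
    are kept but flagged in the log (downstream association excludes them
    through the common-variant filter if requested).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VCFFormatError(f"{path}: no samples / no GT field")
    keys: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        alts = rec.ALT or []
        if not alts:
            continue
        if biallelic_only and len(alts) > 1:
            continue
        # genotypes: [allele0, allele1, phased]; -1 encodes '.'
        gts = np.asarray([g[:2] for g in rec.genotypes], dtype=np.int32)
        for ai, alt in enumerate(alts, start=1):
            dose = (gts == ai).sum(axis=1).astype(np.int8)
            dose[(gts < 0).any(axis=1)] = MISSING
            keys.append(f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}")
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            cols.append(dose)
    vcf.close()
    calls = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, keys, calls, np.array(chroms, dtype=object), np.array(poss))


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes (simulator output)."""
    path = Path(path)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, key in enumerate(G.variant_keys):
            chrom, pos, ref, alt = key.split(":")
            row = "\t".join(gt_str[int(g)] for g in G.calls[:, j])
            fh.write(f"{chrom}\t{pos}\t{key}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{row}\n")


def normalize_func_class(label: str) -> str:
    label = label.strip()
    if label in FUNC_CLASSES:
        return label
    alias = _CLASS_ALIASES.get(label.lower())
    if alias:
        return alias
    lowered = label.lower().replace(" ", "_").replace(";", "_")
    for cls in FUNC_CLASSES:
        if cls.lower() == lowered:
            return cls
    return "unknown"


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a variant annotation TSV: variant_key, gene, func_class, dann.

    Rows with a DANN score outside [0, 1] are rejected (count logged); an
    empty/missing dann field parses as NaN and is kept — downstream burden
    weighting drops unscored variants itself.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str, "gene": str})
    required = {"variant_key", "gene", "func_class", "dann"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"annotation file missing columns: {sorted(missing)}")
    df["gene"] = df["gene"].fillna("")
    df["func_class"] = df["func_class"].astype(str).map(normalize_func_class)
    df["dann"] = pd.to_numeric(df["dann"], errors="coerce")
    bad = df["dann"].notna() & ((df["dann"] < 0) | (df["dann"] > 1))
    if bad.any():
        log.warning("rejected %d annotation rows with DANN outside [0,1]", int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def read_labels(path: str | Path) -> SampleLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleLabels(df)


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    labels.table.to_csv(path, sep="\t", index=False)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_results(table: ResultTable, path: str | Path, float_fmt: str = "%.6g") -> None:
    """Write a ResultTable as TSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# stage: {table.stage}\n")
        for k, v in sorted(table.params.items()):
            fh.write(f"# {k}: {v}\n")
        table.data.to_csv(fh, sep="\t", index=False, float_format=float_fmt)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def orphan_annotations(ann: pd.DataFrame, G: GenotypeMatrix) -> pd.Series:
    """Boolean mask of annotation rows whose key matches no genotype column."""
    return ~ann["variant_key"].isin(set(G.variant_keys))
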