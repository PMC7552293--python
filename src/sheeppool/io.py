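"""Readers and writers for genotype/trait tables and a minimal indel VCF.

Genotype CSVs carry one row per individual with columns ``id, breed, sex``
and one column per locus; genotype strings "II"/"ID"/"DD" (case-insensitive)
and dosage codes 0/1/2 are both accepted.  The optional VCF path writes a
single biallelic deletion record (VCF 4.2, one line per cohort) and reads
any minimal biallelic-indel VCF back through cyvcf2.  Internally positions
are 0-based half-open; VCF stays 1-based on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "LocusMeta",
    "DEL8_CHCHD7",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_trait_csv",
    "read_minimal_vcf",
    "write_minimal_vcf",
]

_GENO_STR = {"II": 0, "ID": 1, "DD": 2}
_RESERVED = ("id", "breed", "sex")


@dataclass(frozen=True)
class LocusMeta:
    """Locus metadata carried through to VCF output (1-based POS on disk)."""

    name: str
    contig: str
    pos: int  # 0-based start of the anchor base
    ref: str
    alt: str
    variant_id: str

    @property
    def pos_vcf(self) -> int:
        return self.pos + 1


# the motivating 8-bp deletion, metadata only (coordinates as published)
DEL8_CHCHD7 = LocusMeta(
    name="chchd7_del8",
    contig="NC_040260.1",
    pos=36219993,
    ref="NGTTACAAG",
    alt="N",
    variant_id="rs593501397",
)


def _parse_genotype(value, row: int, col: str) -> int:
    s = str(value).strip().upper()
    if s in _GENO_STR:
        return _GENO_STR[s]
    if s in {"0", "1", "2"}:
        return int(s)
    raise ValueError(f"malformed genotype {value!r} in column {col!r} at row {row}")


def read_genotype_csv(path) -> pd.DataFrame:
    """Validated genotype table; locus columns coerced to 0/1/2 dosage."""
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no records")
    for col in _RESERVED:
        if col not in df.columns:
            df[col] = "unknown"
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate individual id {dup!r}")
    loci = [c for c in df.columns if c not in _RESERVED]
    if not loci:
        raise ValueError(f"{path}: no genotype columns")
    for col in loci:
        df[col] = [
            _parse_genotype(v, i, col) for i, v in enumerate(df[col], start=2)
        ]
        df[col] = df[col].astype(np.int64)
    return df.loc[:, list(_RESERVED) + loci]


def write_genotype_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trait_csv(path) -> pd.DataFrame:
    """Trait table: ``id`` plus numeric trait columns (``breed/sex/genotype`` kept)."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"{path}: trait table needs an 'id' column")
    if df.empty:
        raise ValueError(f"{path}: no records")
    return df


def write_minimal_vcf(
    df: pd.DataFrame,
    path,
    locus: LocusMeta = DEL8_CHCHD7,
    genotype_col: str = "genotype",
) -> None:
    """One-record VCF 4.2 with a GT column per individual."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = df["id"].tolist()
    calls = [gt[int(g)] for g in df[genotype_col]]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={locus.contig}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
        f"{locus.contig}\t{locus.pos_vcf}\t{locus.variant_id}\t{locus.ref}\t"
        f"{locus.alt}\t.\t.\t.\tGT\t" + "\t".join(calls),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_minimal_vcf(path) -> pd.DataFrame:
    """Biallelic indel genotypes from a VCF; one locus column per kept site.

    Multi-allelic sites are skipped with a warning; samples with missing GT
    at a site get a missing value there (excluded from downstream counts).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    meta: dict[str, LocusMeta] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"{path}: skipping multi-allelic site {var.CHROM}:{var.POS}"
            )
            continue
        if len(var.REF) == len(var.ALT[0]):
            continue  # indel input only
        name = var.ID or f"{var.CHROM}_{var.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        codes = np.array(
            [{0: 0, 1: 1, 3: 2}.get(t, -1) for t in var.gt_types], dtype=float
        )
        codes[codes < 0] = np.nan
        data[name] = codes
        meta[name] = LocusMeta(
            name=name,
            contig=var.CHROM,
            pos=var.POS - 1,
            ref=var.REF,
            alt=var.ALT[0],
            variant_id=var.ID or ".",
        )
    if not data:
        raise ValueError(f"{path}: no biallelic indel records")
    df = pd.DataFrame({"id": samples, "breed": "unknown", "sex": "unknown", **data})
    df.attrs["loci"] = meta
    return df
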