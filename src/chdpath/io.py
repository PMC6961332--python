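"""Readers and writers for the tabular formats used throughout the pipeline.

Coordinate conventions are centralized here: DNV tables and exon tables are
1-based inclusive in memory (VCF convention); BED files on disk are 0-based
half-open and converted on read/write.
"""

from __future__ import annotations

import textwrap
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: Column order of the DNV TSV dialect. Empty cell = value absent.
DNV_COLUMNS = [
    "sample_id", "cohort", "phenotype1", "phenotype2", "gene", "chrom",
    "pos", "ref", "alt", "mol_class", "pb_tot", "pb_alt", "f_ref",
    "f_altratio", "m_ref", "m_altratio", "cohort_af", "cadd",
    "maf_exac", "maf_esp", "maf_gnomad", "maf_1kg", "sex",
]

#: Optional columns appended when present.
DNV_OPTIONAL_COLUMNS = ["blacklisted"]

ANNOTATION_COLUMNS = [
    "gene", "gdi_class", "msc", "heart_expr_percentile",
    "known_chd_human", "known_chd_mouse", "tissue_class",
]

_DNV_FLOAT_COLS = [
    "cohort_af", "cadd", "maf_exac", "maf_esp", "maf_gnomad", "maf_1kg",
    "f_altratio", "m_altratio",
]
_DNV_INT_COLS = ["pos", "pb_tot", "pb_alt", "f_ref", "m_ref"]


def read_dnv_table(path: str | Path) -> pd.DataFrame:
    """Read a DNV TSV (header required). Empty cells become NaN."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DNV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DNV table {path} lacks required columns: {missing}")
    df = df.replace("", pd.NA)
    for col in _DNV_FLOAT_COLS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in _DNV_INT_COLS:
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    if "blacklisted" in df.columns:
        df["blacklisted"] = df["blacklisted"].fillna("0").isin(
            ["1", "true", "True"])
    return df


def write_dnv_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in DNV_COLUMNS + DNV_OPTIONAL_COLUMNS if c in df.columns]
    out = df[cols].copy()
    if "blacklisted" in out.columns:
        out["blacklisted"] = out["blacklisted"].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks columns: {missing}")
    df["known_chd_human"] = df["known_chd_human"].astype(bool)
    df["known_chd_mouse"] = df["known_chd_mouse"].astype(bool)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    out = df[ANNOTATION_COLUMNS].copy()
    out["known_chd_human"] = out["known_chd_human"].astype(int)
    out["known_chd_mouse"] = out["known_chd_mouse"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; 1-based inclusive in memory)

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 6-column BED into a 1-based inclusive exon table."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("BED strand column must be '+' or '-'")
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def write_bed(exons: pd.DataFrame, path: str | Path) -> None:
    out = exons.copy()
    out["start"] = out["start"].astype(int) - 1
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    if "score" not in out.columns:
        out["score"] = 0
    out[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 70)) + "\n")
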