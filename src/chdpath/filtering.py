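"""Variant- and gene-level filtering of trio de novo variant (DNV) calls.

The cascade turns raw per-trio DNV tables into the case and control gene
sets used by enrichment, network and prioritization stages:

1. trio read-support hard filters (in-cohort AF, proband depth/ratio,
   parental contamination, exonic/canonical-splice class),
2. molecular-class split (six damaging classes vs synonymous),
3. population MAF < 0.001 across ExAC/ESP/gnomAD/1000G (absent passes),
4. gene damage index (GDI): high-GDI genes removed,
5. CADD >= gene-specific mutation significance cutoff (MSC),
6. X-linked-recessive exclusion,
7. case/control gene burden selection (strategies a-d).

All record-level filters are idempotent and commute with each other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

#: The six molecular classes treated as likely damaging, in priority order.
DAMAGING_CLASSES = (
    "frameshift", "nonsense", "splice", "start_loss", "missense",
    "nonfs_indel",
)
ALL_CLASSES = DAMAGING_CLASSES + ("synonymous",)

MAF_COLUMNS = ("maf_exac", "maf_esp", "maf_gnomad", "maf_1kg")

#: hg19 X-chromosome pseudoautosomal regions (1-based inclusive).
PAR1_HG19 = (60_001, 2_699_520)
PAR2_HG19 = (154_931_044, 155_260_560)

_READ_SUPPORT_COLS = (
    "pb_tot", "pb_alt", "f_ref", "f_altratio", "m_ref", "m_altratio",
    "cohort_af",
)


class UnannotatedGeneError(KeyError):
    """A record's gene has no row in the gene annotation table."""


def apply_hard_filters(
    records: pd.DataFrame,
    cohort_af_max: float = 4e-4,
    return_dropped: bool = False,
):
    """Trio read-support hard filters on called DNVs.

    Retains records satisfying all of: in-cohort allele frequency
    <= ``cohort_af_max``; proband >= 10 total reads and >= 5 alternate
    reads; proband alternate-allele ratio >= 0.20 when alternate reads
    >= 10, else >= 0.28; both parents >= 10 reference reads with
    alternate ratio < 0.035; molecular class exonic or canonical splice.
    Records with a missing read-support field are rejected with reason
    ``missing_field``.
    """
    df = records
    reason = pd.Series("", index=df.index, dtype=object)

    missing = df[list(_READ_SUPPORT_COLS)].isna().any(axis=1)
    reason[missing] = "missing_field"

    with np.errstate(invalid="ignore"):
        ratio = df["pb_alt"].astype(float) / df["pb_tot"].astype(float)
    checks = [
        ("cohort_af", df["cohort_af"] <= cohort_af_max),
        ("proband_depth", (df["pb_tot"] >= 10) & (df["pb_alt"] >= 5)),
        ("proband_ratio",
         np.where(df["pb_alt"].astype(float) >= 10,
                  ratio >= 0.20, ratio >= 0.28)),
        ("parent_support",
         (df["f_ref"] >= 10) & (df["m_ref"] >= 10)
         & (df["f_altratio"] < 0.035) & (df["m_altratio"] < 0.035)),
        ("mol_class", df["mol_class"].isin(ALL_CLASSES)),
    ]
    keep = ~missing
    for name, ok in checks:
        if isinstance(ok, np.ndarray):
            ok = pd.Series(ok, index=df.index)
        ok = ok.astype("boolean").fillna(False).astype(bool) & ~missing
        newly_failed = keep & ~ok
        reason[newly_failed & (reason == "")] = name
        keep &= ok

    n_drop = int((~keep).sum())
    if n_drop:
        counts = reason[~keep].value_counts().to_dict()
        logger.info("hard filters removed %d/%d records: %s",
                    n_drop, len(df), counts)
    kept = df[keep].copy()
    if return_dropped:
        dropped = df[~keep].copy()
        dropped["reason"] = reason[~keep]
        return kept, dropped
    return kept


def filter_molecular_class(records: pd.DataFrame):
    """Split records into (damaging, synonymous) tables.

    The damaging table contains exactly the six priority classes; the
    synonymous track is analyzed separately for splicing-enhancer
    disruption. Unknown class labels raise ValueError.
    """
    unknown = sorted(set(records["mol_class"]) - set(ALL_CLASSES))
    if unknown:
        raise ValueError(f"unknown molecular class labels: {unknown}")
    damaging = records[records["mol_class"].isin(DAMAGING_CLASSES)].copy()
    synonymous = records[records["mol_class"] == "synonymous"].copy()
    return damaging, synonymous


def filter_population_maf(
    records: pd.DataFrame, threshold: float = 0.001, strict: bool = False
) -> pd.DataFrame:
    """Keep records rare in every population database where a value exists.

    A record absent from all four databases passes by default (the variant
    may simply never have been observed); ``strict=True`` inverts that
    convention for sensitivity analysis.
    """
    maf = records[list(MAF_COLUMNS)]
    if (maf < 0).any().any():
        raise ValueError("negative population MAF")
    rare_where_present = ((maf < threshold) | maf.isna()).all(axis=1)
    absent_everywhere = maf.isna().all(axis=1)
    keep = rare_where_present & (~absent_everywhere if strict else True)
    return records[keep].copy()


def _gene_lookup(records, annotations, column, on_missing):
    mapping = annotations.set_index("gene")[column]
    values = records["gene"].map(mapping)
    missing = values.isna() & ~records["gene"].isin(mapping.index)
    if missing.any():
        genes = sorted(records.loc[missing, "gene"].unique())
        if on_missing == "error":
            raise UnannotatedGeneError(
                f"genes missing from annotation table: {genes[:10]}"
                + ("..." if len(genes) > 10 else ""))
        logger.warning("%d records in unannotated genes passed through: %s",
                       int(missing.sum()), genes[:10])
    return values, missing


def filter_gdi(
    records: pd.DataFrame, annotations: pd.DataFrame,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Drop records in genes with a high gene damage index (GDI).

    Highly damaged genes in the general population are unlikely disease
    causes; low and medium GDI genes are retained.
    """
    gdi, missing = _gene_lookup(records, annotations, "gdi_class", on_missing)
    return records[(gdi != "high") | missing].copy()


def filter_cadd_msc(
    records: pd.DataFrame, annotations: pd.DataFrame,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Keep variants with CADD >= the gene's mutation significance cutoff.

    The boundary is inclusive: a CADD score exactly at the MSC passes.
    """
    msc, missing = _gene_lookup(records, annotations, "msc", on_missing)
    return records[(records["cadd"] >= msc.astype(float)) | missing].copy()


def _in_par(pos: pd.Series) -> pd.Series:
    return (pos.between(*PAR1_HG19)) | (pos.between(*PAR2_HG19))


def exclude_x_linked_recessive(records: pd.DataFrame) -> pd.DataFrame:
    """Remove X-chromosome DNVs consistent with X-linked recessive inheritance.

    Operational rule: drop non-pseudoautosomal X records in male probands
    whose alternate-allele ratio is hemizygous-consistent (>= 0.8).
    Heterozygous female X records and all autosomal records are kept.
    """
    chrom = records["chrom"].astype(str).str.removeprefix("chr")
    on_x = chrom == "X"
    ratio = records["pb_alt"].astype(float) / records["pb_tot"].astype(float)
    xlr = (
        on_x
        & (records["sex"] == "male")
        & (ratio >= 0.8)
        & ~_in_par(records["pos"].astype(int))
    )
    return records[~xlr].copy()


def filter_blacklist(records: pd.DataFrame, blacklist: set) -> pd.DataFrame:
    """Drop records whose (chrom, pos, ref, alt) key is blacklisted."""
    if not blacklist:
        return records.copy()
    keys = list(zip(records["chrom"].astype(str),
                    records["pos"].astype(int),
                    records["ref"], records["alt"]))
    mask = pd.Series([k in blacklist for k in keys], index=records.index)
    if mask.any():
        logger.info("blacklist removed %d records", int(mask.sum()))
    return records[~mask].copy()


# ---------------------------------------------------------------------------
# Gene burden selection


def gene_burden_counts(
    case_records: pd.DataFrame, control_records: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene variant counts in cases and controls."""
    n_cases = case_records.groupby("gene").size()
    n_controls = control_records.groupby("gene").size()
    burden = (
        pd.DataFrame({"n_cases": n_cases, "n_controls": n_controls})
        .fillna(0).astype(int)
        .rename_axis("gene").reset_index().sort_values("gene")
        .reset_index(drop=True)
    )
    return burden


def select_genes(
    case_records: pd.DataFrame,
    control_records: pd.DataFrame,
    strategy: str = "d",
    margin: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Select genes whose mutational burden is case-specific.

    Strategies (the margin-based one is the default):

    - ``a``: two-sided Fisher's exact test on the 2x2 table
      [variants in gene vs all other genes] x [case vs control] over all
      genes with any variant, B-H corrected.
    - ``b``: as ``a`` but tested only over genes with >= 1 case variant.
    - ``c``: genes with >= 1 case variant and no control variants.
    - ``d``: genes with ``n_cases - n_controls >= margin``.

    Swapping the case and control arguments yields the mirrored control
    gene set.
    """
    if margin < 1:
        raise ValueError(f"margin must be >= 1, got {margin}")
    if strategy not in "abcd" or len(strategy) != 1:
        raise ValueError(f"unknown strategy {strategy!r}")

    burden = gene_burden_counts(case_records, control_records)
    burden["strategy"] = strategy

    if strategy == "d":
        burden["selected"] = burden["n_cases"] - burden["n_controls"] >= margin
        return burden
    if strategy == "c":
        burden["selected"] = (burden["n_cases"] >= 1) & (burden["n_controls"] == 0)
        return burden

    total_case = int(burden["n_cases"].sum())
    total_ctrl = int(burden["n_controls"].sum())
    tested = burden if strategy == "a" else burden[burden["n_cases"] >= 1]
    pvals = [
        stats.fisher_exact(
            [[x, y], [total_case - x, total_ctrl - y]], alternative="two-sided"
        ).pvalue
        for x, y in zip(tested["n_cases"], tested["n_controls"])
    ]
    burden["p_raw"] = np.nan
    burden["fdr"] = np.nan
    burden.loc[tested.index, "p_raw"] = pvals
    burden.loc[tested.index, "fdr"] = bh_adjust(pvals)
    burden["selected"] = burden["fdr"] < alpha
    return burden


def extend_control_set(
    control_burden: pd.DataFrame,
    pool_diff1: pd.DataFrame,
    k: int,
    seed: int,
) -> pd.DataFrame:
    """Grow the control gene set with a seeded draw from the diff-1 pool.

    ``pool_diff1`` must hold only genes with exactly one more control than
    case variant; ``k`` of them are sampled uniformly without replacement
    and unioned with the base control set.
    """
    diff = pool_diff1["n_controls"] - pool_diff1["n_cases"]
    if not (diff == 1).all():
        raise ValueError("pool must contain only n_controls - n_cases == 1 genes")
    pool_genes = sorted(set(pool_diff1["gene"]) - set(control_burden["gene"]))
    if k > len(pool_genes):
        raise ValueError(f"k={k} exceeds pool size {len(pool_genes)}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(pool_genes, size=k, replace=False))
    extra = pool_diff1[pool_diff1["gene"].isin(chosen)].copy()
    out = (
        pd.concat([control_burden, extra], ignore_index=True)
        .drop_duplicates(subset="gene")
        .sort_values("gene").reset_index(drop=True)
    )
    return out
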