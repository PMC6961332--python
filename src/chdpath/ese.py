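"""Exonic splicing enhancer (ESE) disruption scanning of synonymous DNVs.

Synonymous variants are usually discarded as benign, but a substitution
inside an exonic splicing enhancer motif near a canonical splice site can
abolish splicing-factor binding and cause aberrant splicing. This module
locates synonymous variants relative to the nearest canonical splice
site, finds every ESE motif occurrence spanning the variant base on the
transcript (sense) strand, and flags occurrences the alternate allele
destroys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import filtering

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifCollection:
    """Unique uppercase DNA motifs with per-motif source provenance."""

    motifs: list[str] = field(default_factory=list)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    @property
    def max_length(self) -> int:
        return max((len(m) for m in self.motifs), default=0)


def load_motifs(sources: Sequence[str | Path]) -> MotifCollection:
    """Case-folded union of motif files with cross-source duplicates removed.

    One motif per line; blank lines and '#' comments are skipped. A
    non-ACGT character raises, naming the offending file and line.
    Loading the same file twice is a no-op.
    """
    coll = MotifCollection()
    seen = set(coll.motifs)
    for src in sources:
        name = str(src)
        for lineno, line in enumerate(Path(src).read_text().splitlines(), 1):
            motif = line.split("#")[0].strip().upper()
            if not motif:
                continue
            if set(motif) - set("ACGT"):
                raise ValueError(
                    f"{name}:{lineno}: non-ACGT character in motif {motif!r}")
            if motif not in seen:
                seen.add(motif)
                coll.motifs.append(motif)
                coll.provenance[motif] = []
            if name not in coll.provenance[motif]:
                coll.provenance[motif].append(name)
    return coll


@dataclass
class EseHit:
    """One ESE motif occurrence spanning a variant base."""

    variant_key: str
    motif: str
    motif_start: int       # 1-based start of the occurrence in the context
    offset_in_motif: int   # which motif base the variant hits (1-based)
    splice_offset: int | None = None
    site_type: str | None = None
    disrupted: bool = False


def splice_proximity(
    pos: int, exons: pd.DataFrame, chrom: str | None = None
) -> tuple[int, str]:
    """Signed offset of a variant from its nearest canonical splice site.

    Offsets are counted in transcript orientation: +1 is the first exonic
    base downstream of the splice acceptor, -1 the last exonic base
    before the donor. The nearer site is reported (ties go to the
    acceptor). Exon coordinates are 1-based inclusive; for minus-strand
    exons the acceptor sits at the higher genomic coordinate.
    """
    ex = exons
    if chrom is not None:
        ex = ex[ex["chrom"].astype(str) == str(chrom)]
    hit = ex[(ex["start"] <= pos) & (pos <= ex["end"])]
    if hit.empty:
        raise ValueError(f"position {pos} lies outside every exon")
    exon = hit.iloc[0]
    if exon["strand"] == "+":
        acc = pos - int(exon["start"]) + 1
        don = -(int(exon["end"]) - pos + 1)
    else:
        acc = int(exon["end"]) - pos + 1
        don = -(pos - int(exon["start"]) + 1)
    if acc <= -don:
        return acc, "acceptor"
    return don, "donor"


def scan_variant(
    context: str,
    var_index: int,
    ref: str,
    alt: str,
    motifs: MotifCollection,
    variant_key: str = "",
) -> list[EseHit]:
    """Every motif occurrence in the reference context spanning the variant.

    ``context`` is transcript-strand reference sequence with the variant
    base at 0-based ``var_index``; it must extend at least
    ``max motif length - 1`` bases on both sides of the variant. A hit is
    ``disrupted`` when substituting the alternate allele abolishes that
    occurrence (for degenerate motifs matching both alleles it stays
    false).
    """
    context = context.upper()
    ref = ref.upper()
    alt = alt.upper()
    need = motifs.max_length - 1
    if var_index < need or len(context) - var_index - 1 < need:
        raise ValueError(
            f"context must cover the variant +/- {need} bases")
    if context[var_index] != ref:
        raise ValueError(
            f"reference allele {ref!r} does not match context base "
            f"{context[var_index]!r} at index {var_index}")
    alt_context = context[:var_index] + alt + context[var_index + 1:]

    hits = []
    for motif in motifs:
        L = len(motif)
        for start in range(var_index - L + 1, var_index + 1):
            if context[start:start + L] == motif:
                hits.append(EseHit(
                    variant_key=variant_key,
                    motif=motif,
                    motif_start=start + 1,
                    offset_in_motif=var_index - start + 1,
                    disrupted=alt_context[start:start + L] != motif,
                ))
    return hits


def extract_context(
    sequence: str, pos: int, ref: str, alt: str, strand: str, flank: int
) -> tuple[str, int, str, str]:
    """Transcript-strand context of width ``2*flank + 1`` around a variant.

    ``pos`` is 1-based on the genomic plus strand. Minus-strand exons are
    reverse-complemented so that scanning always runs on the sense
    strand; returns (context, variant index in context, ref, alt) in
    transcript orientation.
    """
    i = pos - 1
    if i < flank or i + flank >= len(sequence):
        raise ValueError("variant too close to the contig edge for the "
                         f"requested flank {flank}")
    window = sequence[i - flank:i + flank + 1].upper()
    if strand == "+":
        return window, flank, ref.upper(), alt.upper()
    return (revcomp(window), flank,
            revcomp(ref.upper()), revcomp(alt.upper()))


def variant_key(row) -> str:
    return f"{row['chrom']}-{row['pos']}-{row['ref']}-{row['alt']}"


def synonymous_track(
    case_records: pd.DataFrame,
    control_records: pd.DataFrame,
    annotations: pd.DataFrame,
    exons: pd.DataFrame,
    sequences: Mapping[str, str],
    motifs: MotifCollection,
    window: int = 50,
    maf_threshold: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case-specific synonymous genes and their ESE disruption report.

    The synonymous tables first pass the same population-MAF, GDI and
    CADD>=MSC filters as the damaging track. Genes with at least two
    case synonymous variants and none in controls are retained; each of
    their case variants lying within ``window`` bases of a canonical
    splice site is scanned for overlapping ESE motifs.

    Returns ``(gene_table, hits)`` where ``gene_table`` has per-gene
    counts plus the heart-expression flag and ``hits`` one row per motif
    occurrence spanning a variant.
    """
    def prefilter(df):
        df = filtering.filter_population_maf(df, threshold=maf_threshold)
        df = filtering.filter_gdi(df, annotations)
        df = filtering.filter_cadd_msc(df, annotations)
        return df

    case = prefilter(case_records)
    ctrl = prefilter(control_records)
    n_case = case.groupby("gene").size()
    n_ctrl = ctrl.groupby("gene").size()
    genes = sorted(
        g for g, k in n_case.items() if k >= 2 and n_ctrl.get(g, 0) == 0)

    pct = annotations.set_index("gene")["heart_expr_percentile"]
    flank = max(motifs.max_length - 1, 0)
    hit_rows = []
    gene_rows = []
    for gene in genes:
        sub = case[case["gene"] == gene]
        n_hits = 0
        for _, row in sub.iterrows():
            key = variant_key(row)
            gene_exons = exons[exons["name"] == gene]
            try:
                offset, site = splice_proximity(
                    int(row["pos"]), gene_exons, chrom=row["chrom"])
            except ValueError:
                logger.warning("variant %s outside exon model; skipped", key)
                continue
            if abs(offset) > window or len(motifs) == 0:
                continue
            seq = sequences[str(row["chrom"])]
            strand = gene_exons.iloc[0]["strand"]
            context, idx, ref, alt = extract_context(
                seq, int(row["pos"]), row["ref"], row["alt"], strand, flank)
            for hit in scan_variant(context, idx, ref, alt, motifs, key):
                hit.splice_offset = offset
                hit.site_type = site
                hit_rows.append(hit)
                n_hits += 1
        gene_rows.append({
            "gene": gene,
            "n_case_synonymous": int(n_case[gene]),
            "n_control_synonymous": 0,
            "n_ese_hits": n_hits,
            "hhe": bool(pct.get(gene, 0) >= 75.0),
        })

    gene_table = pd.DataFrame(gene_rows, columns=[
        "gene", "n_case_synonymous", "n_control_synonymous",
        "n_ese_hits", "hhe"])
    hits = pd.DataFrame(
        [vars(h) for h in hit_rows],
        columns=["variant_key", "motif", "motif_start", "offset_in_motif",
                 "splice_offset", "site_type", "disrupted"])
    return gene_table, hits
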