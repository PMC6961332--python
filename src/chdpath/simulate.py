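"""Seeded synthetic cohorts with planted disease signal.

The generator emulates the statistical structure of a trio de novo
variant (DNV) study of a heterogeneous congenital disorder: per-gene DNV
counts are Poisson, a small set of disease genes (known genes plus
planted "novel" candidates) carries an elevated case rate, the molecular
class mix of damaging variants follows the observed cohort composition
(missense : nonsense : frameshift : splice : start-loss at
232 : 37 : 36 : 14 : 1), population allele frequencies concentrate on
"absent" with a rare tail, and every gene carries GDI / MSC /
heart-expression annotations. Companion generators emit gene-set
collections with one planted disease pathway, a scale-free interactome
with a planted dense disease community, and exon sequences with embedded
splicing-enhancer motifs. All outputs are deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import PpiGraph
from .enrichment import GeneSetCollection
from .io import DNV_COLUMNS

MOL_CLASSES = ("missense", "nonsense", "frameshift", "splice",
               "start_loss", "nonfs_indel", "synonymous")

#: Damaging-class proportions of the emulated cohort (missense, nonsense,
#: frameshift, canonical splice, start loss, non-frameshift indel).
DAMAGING_MIX = (232, 37, 36, 14, 1, 0)

PLANTED_SET_ID = "planted_disease_pathway"

#: Example splicing-enhancer hexamer/octamer motifs used as the default
#: planted motif set for sequence simulation.
DEFAULT_ESE_MOTIFS = (
    "GATCAA", "ATCAAG", "CAAGAA", "TCAAGA",
    "CAAGAAGA", "TCAAGAAG", "ATCAAGAA",
)


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _default_class_mix() -> dict[str, float]:
    synonymous = 0.28
    total = sum(DAMAGING_MIX)
    mix = {
        cls: (1 - synonymous) * w / total
        for cls, w in zip(MOL_CLASSES[:-1], DAMAGING_MIX)
    }
    mix["synonymous"] = synonymous
    return mix


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Cohort shape defaults to the emulated study scaled down 10x
    (264 case / 179 control trios); DNV rates are expected counts per
    gene per cohort.
    """

    n_case_trios: int = 264
    n_control_trios: int = 179
    n_genes: int = 1000
    n_known_genes: int = 30
    n_planted_candidates: int = 10
    dnv_rate_background: float = 0.3
    dnv_rate_planted: float = 5.0
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    maf_spec: dict = field(default_factory=lambda: {
        "p_absent": 0.7, "p_common": 0.05,
        "rare_log10_range": (-6.0, -3.05),
        "common_range": (2e-3, 1e-2),
    })
    gdi_class_probs: dict[str, float] = field(default_factory=lambda: {
        "low": 0.6, "medium": 0.3, "high": 0.1})
    cadd_spec: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "missense": (25.0, 4.0), "nonsense": (38.0, 4.0),
        "frameshift": (35.0, 4.0), "splice": (28.0, 4.0),
        "start_loss": (30.0, 4.0), "nonfs_indel": (20.0, 4.0),
        "synonymous": (8.0, 3.0)})
    msc_spec: tuple[float, float] = (12.0, 4.0)
    graph_spec: dict = field(default_factory=lambda: {
        "m": 2, "conf_range": (0.4, 1.0),
        "community_density": 0.3, "community_conf_range": (0.901, 1.0)})
    n_gene_sets: int = 100
    set_size_range: tuple[int, int] = (10, 60)
    planted_set_size: int = 30
    frac_hard_filter_fail: float = 0.05
    frac_x_chrom: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case_trios", "n_control_trios", "n_genes",
                     "n_known_genes", "n_planted_candidates", "n_gene_sets",
                     "planted_set_size"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be > 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise SimConfigError("class_mix must sum to 1 within 1e-9")
        unknown = set(self.class_mix) - set(MOL_CLASSES)
        if unknown:
            raise SimConfigError(f"class_mix has unknown classes: {unknown}")
        if self.dnv_rate_planted < self.dnv_rate_background:
            raise SimConfigError(
                "dnv_rate_planted must be >= dnv_rate_background")
        if self.n_known_genes + self.n_planted_candidates > self.n_genes:
            raise SimConfigError(
                "n_known_genes + n_planted_candidates exceeds n_genes")
        if abs(sum(self.gdi_class_probs.values()) - 1.0) > 1e-9:
            raise SimConfigError("gdi_class_probs must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted signal."""

    planted_genes: list[str]
    known_genes: list[str]
    planted_set_id: str
    planted_community: list[str]
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1,
                                         sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def gene_universe(config: SimConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def _pick_disease_genes(config: SimConfig):
    rng = np.random.default_rng([config.seed, 11])
    genes = gene_universe(config)
    total = config.n_known_genes + config.n_planted_candidates
    chosen = [str(g) for g in rng.choice(genes, size=total, replace=False)]
    known = sorted(chosen[:config.n_known_genes])
    planted = sorted(chosen[config.n_known_genes:])
    return genes, known, planted


def _draw_maf(rng, spec) -> dict[str, float]:
    cols = ("maf_exac", "maf_esp", "maf_gnomad", "maf_1kg")
    common = rng.random() < spec["p_common"]
    out = {}
    present_any = False
    for col in cols:
        if rng.random() < spec["p_absent"]:
            out[col] = math.nan
            continue
        present_any = True
        if common:
            out[col] = rng.uniform(*spec["common_range"])
        else:
            lo, hi = spec["rare_log10_range"]
            out[col] = 10.0 ** rng.uniform(lo, hi)
    if common and not present_any:  # a common variant is observed somewhere
        lo, hi = spec["common_range"]
        out["maf_gnomad"] = rng.uniform(lo, hi)
    return out


def _read_support(rng, hemizygous: bool, fail_mode: str | None):
    pb_tot = int(rng.integers(20, 81))
    frac = rng.uniform(0.85, 0.98) if hemizygous else rng.uniform(0.35, 0.60)
    pb_alt = max(5, int(round(pb_tot * frac)))
    rec = {
        "pb_tot": pb_tot, "pb_alt": min(pb_alt, pb_tot),
        "f_ref": int(rng.integers(20, 61)),
        "f_altratio": rng.uniform(0.0, 0.03),
        "m_ref": int(rng.integers(20, 61)),
        "m_altratio": rng.uniform(0.0, 0.03),
        "cohort_af": rng.uniform(0.0, 3.9e-4),
    }
    if fail_mode == "low_depth":
        rec["pb_tot"], rec["pb_alt"] = 8, 3
    elif fail_mode == "low_ratio":
        rec["pb_tot"], rec["pb_alt"] = 60, 9
    elif fail_mode == "parent":
        rec["f_altratio"] = 0.10
    elif fail_mode == "cohort_af":
        rec["cohort_af"] = 1.2e-3
    return rec


def _annotations(config, rng, genes, disease_genes, known) -> pd.DataFrame:
    gdi_classes = list(config.gdi_class_probs)
    gdi_p = np.array([config.gdi_class_probs[c] for c in gdi_classes])
    nd_p = gdi_p.copy()
    nd_p[[c == "high" for c in gdi_classes]] = 0.0
    nd_p = nd_p / nd_p.sum()
    disease = set(disease_genes)
    known = set(known)
    rows = []
    for gene in genes:
        is_disease = gene in disease
        gdi = rng.choice(gdi_classes, p=nd_p if is_disease else gdi_p)
        msc = max(0.0, rng.normal(*config.msc_spec))
        pct = rng.uniform(75.0, 100.0) if is_disease else rng.uniform(0.0, 100.0)
        if gene in known:
            r = rng.random()
            human, mouse = r < 0.45, r >= 0.30
        else:
            human = mouse = False
        tissue_enhanced = rng.random() < (0.325 if is_disease else 0.46)
        rows.append({
            "gene": gene, "gdi_class": gdi, "msc": round(msc, 3),
            "heart_expr_percentile": round(pct, 2),
            "known_chd_human": human, "known_chd_mouse": mouse,
            "tissue_class": "enhanced" if tissue_enhanced else "all_mixed",
        })
    return pd.DataFrame(rows)


def generate_cohort(config: SimConfig):
    """Generate (DNV table, gene annotation table, truth).

    Disease genes (known + planted) receive Poisson case counts at the
    elevated rate; every gene draws control counts at the background rate
    scaled by relative cohort size. Read support is drawn to pass the
    trio hard filters except for a configured fraction of intended
    failures (recorded in ``truth.extras``).
    """
    config.validate()
    genes, known, planted = _pick_disease_genes(config)
    disease = sorted(set(known) | set(planted))
    rng = np.random.default_rng([config.seed, 12])

    annotations = _annotations(config, rng, genes, disease, known)
    msc_map = annotations.set_index("gene")["msc"]

    case_ids = [f"CASE{i:04d}" for i in range(1, config.n_case_trios + 1)]
    ctrl_ids = [f"CTRL{i:04d}" for i in range(1, config.n_control_trios + 1)]
    sex = {s: ("male" if rng.random() < 0.5 else "female")
           for s in case_ids + ctrl_ids}
    pheno1 = {s: ("isolated" if rng.random() < 0.29 else "syndromic")
              for s in case_ids}
    p2_labels = ["CTD", "d-TGA", "HTX", "LVO", "other"]
    p2_probs = [0.275, 0.07, 0.075, 0.33, 0.25]
    pheno2 = {s: str(rng.choice(p2_labels, p=p2_probs)) for s in case_ids}

    classes = list(config.class_mix)
    class_p = np.array([config.class_mix[c] for c in classes])
    ctrl_scale = config.n_control_trios / config.n_case_trios
    damaging_load: dict[str, int] = {}
    rows = []
    hardfail_keys = []

    for cohort, samples, rate_map in (
        ("case", case_ids,
         {g: (config.dnv_rate_planted if g in set(disease)
              else config.dnv_rate_background) for g in genes}),
        ("control", ctrl_ids,
         {g: config.dnv_rate_background * ctrl_scale for g in genes}),
    ):
        for gene in genes:
            n_var = rng.poisson(rate_map[gene])
            for _ in range(n_var):
                mol = classes[int(rng.choice(len(classes), p=class_p))]
                damaging = mol != "synonymous"
                if damaging:
                    eligible = [s for s in samples
                                if damaging_load.get(s, 0) < 2]
                    sample = (eligible[int(rng.integers(len(eligible)))]
                              if eligible
                              else samples[int(rng.integers(len(samples)))])
                    damaging_load[sample] = damaging_load.get(sample, 0) + 1
                else:
                    sample = samples[int(rng.integers(len(samples)))]
                on_x = rng.random() < config.frac_x_chrom
                chrom = "X" if on_x else str(int(rng.integers(1, 23)))
                hemi = (on_x and sex[sample] == "male"
                        and rng.random() < 0.5)
                fail = None
                if rng.random() < config.frac_hard_filter_fail:
                    fail = ["low_depth", "low_ratio", "parent",
                            "cohort_af"][int(rng.integers(4))]
                support = _read_support(rng, hemi, fail)
                pos = int(rng.integers(3_000_000, 100_000_000))
                bases = ["A", "C", "G", "T"]
                ref = bases[int(rng.integers(4))]
                alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
                if mol in ("frameshift", "nonfs_indel"):
                    ins = "".join(bases[int(rng.integers(4))] for _ in
                                  range(1 if mol == "frameshift" else 3))
                    alt = ref + ins
                mean, sd = config.cadd_spec[mol]
                cadd = max(0.0, rng.normal(mean, sd))
                rec = {
                    "sample_id": sample, "cohort": cohort,
                    "phenotype1": pheno1.get(sample, ""),
                    "phenotype2": pheno2.get(sample, ""),
                    "gene": gene, "chrom": chrom, "pos": pos,
                    "ref": ref, "alt": alt, "mol_class": mol,
                    "cadd": round(cadd, 2), "sex": sex[sample],
                    "blacklisted": False,
                    **support, **_draw_maf(rng, config.maf_spec),
                }
                rows.append(rec)
                if fail is not None:
                    hardfail_keys.append(f"{chrom}-{pos}-{ref}-{alt}")

    dnvs = pd.DataFrame(rows, columns=DNV_COLUMNS + ["blacklisted"])
    truth = SyntheticTruth(
        planted_genes=planted,
        known_genes=known,
        planted_set_id=PLANTED_SET_ID,
        planted_community=disease,
        extras={
            "intended_hard_filter_failures": sorted(hardfail_keys),
            "msc_mean": float(msc_map.mean()),
        },
    )
    return dnvs, annotations, truth


def generate_genesets(config: SimConfig,
                      truth: SyntheticTruth) -> GeneSetCollection:
    """Gene-set collection with one planted disease pathway.

    The planted set holds >= 80% of the planted genes (90% by default)
    topped up with known genes and random filler; the remaining sets are
    uniform random draws from the universe.
    """
    config.validate()
    genes = gene_universe(config)
    if config.planted_set_size > config.n_genes:
        raise SimConfigError("planted_set_size exceeds the gene universe")
    rng = np.random.default_rng([config.seed, 13])

    planted = list(truth.planted_genes)
    n_incl = min(len(planted),
                 max(int(np.ceil(0.9 * len(planted))), 1),
                 config.planted_set_size)
    members = sorted(rng.choice(planted, size=n_incl, replace=False))
    room = config.planted_set_size - len(members)
    known_pool = [g for g in truth.known_genes if g not in members]
    take = min(room, len(known_pool))
    if take:
        members += sorted(rng.choice(known_pool, size=take, replace=False))
    room = config.planted_set_size - len(members)
    if room > 0:
        filler_pool = sorted(set(genes) - set(members))
        members += sorted(rng.choice(filler_pool, size=room, replace=False))

    sets = {PLANTED_SET_ID: ("planted disease pathway", sorted(members))}
    lo, hi = config.set_size_range
    for i in range(1, config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        m = sorted(rng.choice(genes, size=size, replace=False))
        sets[f"SET_{i:04d}"] = (f"random set {i}", m)
    return GeneSetCollection(sets=sets, background=frozenset(genes),
                             source_tag="synthetic")


def generate_ppi(config: SimConfig, truth: SyntheticTruth) -> PpiGraph:
    """Scale-free interactome with a dense planted disease community.

    The background is a preferential-attachment (Barabasi-Albert) graph
    with confidences drawn uniformly from the configured range; pairs
    inside the planted community (known + planted genes) are additionally
    wired with the configured density at high confidence.
    """
    config.validate()
    genes = gene_universe(config)
    spec = config.graph_spec
    rng = np.random.default_rng([config.seed, 14])
    ba_seed = int((config.seed * 2654435761 + 14) % (2**31 - 1))
    ba = nx.barabasi_albert_graph(config.n_genes, spec["m"], seed=ba_seed)

    lo, hi = spec["conf_range"]
    edges = {}
    for u, v in ba.edges():
        a, b = sorted((genes[u], genes[v]))
        edges[(a, b)] = float(rng.uniform(lo, hi))

    clo, chi = spec["community_conf_range"]
    community = sorted(truth.planted_community)
    for i, a in enumerate(community):
        for b in community[i + 1:]:
            if rng.random() < spec["community_density"]:
                edges[(a, b)] = float(rng.uniform(clo, chi))
    return PpiGraph.from_edges(
        (a, b, conf) for (a, b), conf in sorted(edges.items()))


# ---------------------------------------------------------------------------
# Sequence / splicing-enhancer simulation

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _count_overlaps(context: str, idx: int, motifs: Sequence[str]) -> int:
    """Motif occurrences spanning position ``idx`` (direct enumeration)."""
    total = 0
    for m in motifs:
        L = len(m)
        for s in range(max(idx - L + 1, 0), idx + 1):
            if context[s:s + L] == m:
                total += 1
    return total


@dataclass
class SequenceSim:
    """Exon models, contig sequences and planted synonymous variants."""

    exons: pd.DataFrame
    sequences: dict[str, str]
    dnvs: pd.DataFrame
    truth: pd.DataFrame
    annotations: pd.DataFrame


def generate_sequences(config: SimConfig,
                       motifs: Sequence[str] = DEFAULT_ESE_MOTIFS,
                       context: str = "GATCAAGAAGA",
                       context_var_index: int = 3) -> SequenceSim:
    """Exon sequences with synonymous variants planted at known offsets.

    Ten two-exon genes on alternating strands are simulated. The first
    three carry two case-specific synonymous variants each: one embedded
    in a splicing-enhancer context +41 bp from the splice acceptor of the
    second exon, one +10 bp into the first exon; the first gene carries
    an extra variant 500 bp from any splice site. Further genes carry
    case+control or singleton variants so the case-specific rule has
    negatives. The truth table records each planted variant's intended
    motif-overlap count (by direct enumeration on the final sequence) and
    splice-site offset.
    """
    config.validate()
    motifs = [m.upper() for m in motifs]
    exon1 = (301, 500)
    exon2 = (1001, 2200)
    exon_min = exon1[1] - exon1[0] + 1
    for m in motifs:
        if len(m) > exon_min:
            raise SimConfigError(f"motif {m!r} longer than the shortest exon")
    if motifs and _count_overlaps(context.upper(), context_var_index,
                                  motifs) == 0:
        # context carries no planted motif: allowed, overlap truth will be 0
        pass

    rng = np.random.default_rng([config.seed, 15])
    n_genes = 10
    genes = [f"SG{i:02d}" for i in range(1, n_genes + 1)]
    contig_len = 3000
    flank = max((len(m) for m in motifs), default=7) - 1

    sequences = {}
    exon_rows = []
    dnv_rows = []
    truth_rows = []
    sample_counter = [0]

    def new_sample(cohort):
        sample_counter[0] += 1
        return f"SEQ{cohort.upper()}{sample_counter[0]:03d}"

    def add_variant(gene, contig, pos, cohort, ref=None, alt=None):
        seq = sequences[contig]
        base = seq[pos - 1]
        if ref is None:
            ref = base
        assert ref == base
        if alt is None:
            order = "ACGT"
            alt = order[(order.index(ref) + 1) % 4]
        dnv_rows.append({
            "sample_id": new_sample(cohort), "cohort": cohort,
            "phenotype1": "", "phenotype2": "",
            "gene": gene, "chrom": contig, "pos": pos,
            "ref": ref, "alt": alt, "mol_class": "synonymous",
            "pb_tot": 50, "pb_alt": 22, "f_ref": 40, "f_altratio": 0.0,
            "m_ref": 40, "m_altratio": 0.0, "cohort_af": 1e-5,
            "cadd": 25.0, "maf_exac": math.nan, "maf_esp": math.nan,
            "maf_gnomad": math.nan, "maf_1kg": math.nan,
            "sex": "female", "blacklisted": False,
        })
        return ref, alt

    for gi, gene in enumerate(genes):
        contig = f"ctg_{gene}"
        strand = "+" if gi % 2 == 0 else "-"
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=contig_len))
        sequences[contig] = seq
        for start, end in (exon1, exon2):
            exon_rows.append({"chrom": contig, "start": start, "end": end,
                              "name": gene, "score": 0, "strand": strand})

        def genomic_pos(offset_from_acceptor, exon):
            start, end = exon
            if strand == "+":
                return start + offset_from_acceptor - 1
            return end - offset_from_acceptor + 1

        planted = gi < 3
        if planted and motifs:
            # embed the enhancer context so the variant sits +41 of the
            # second exon's acceptor, in transcript orientation
            pos = genomic_pos(41, exon2)
            ctx = context.upper()
            if strand == "+":
                g_start = pos - context_var_index
                sequences[contig] = (seq[:g_start - 1] + ctx
                                     + seq[g_start - 1 + len(ctx):])
            else:
                g_end = pos + context_var_index
                g_start = g_end - len(ctx) + 1
                sequences[contig] = (seq[:g_start - 1] + _revcomp(ctx)
                                     + seq[g_start - 1 + len(ctx):])

        if planted:
            # variant 1: inside the enhancer context, C->T style change
            pos = genomic_pos(41, exon2)
            seq_now = sequences[contig]
            base = seq_now[pos - 1]
            if strand == "+":
                ref, alt = base, ("T" if base == "C" else
                                  "ACGT"[("ACGT".index(base) + 1) % 4])
            else:
                sense = _revcomp(base)
                sense_alt = ("T" if sense == "C" else
                             "ACGT"[("ACGT".index(sense) + 1) % 4])
                ref, alt = base, _revcomp(sense_alt)
            add_variant(gene, contig, pos, "case", ref, alt)
            truth_rows.append(_truth_row(
                contig, pos, ref, alt, gene, sequences[contig], strand,
                motifs, flank, splice_offset=41, near_splice=True))
            # variant 2: +10 into the first exon
            pos2 = genomic_pos(10, exon1)
            ref2, alt2 = add_variant(gene, contig, pos2, "case")
            truth_rows.append(_truth_row(
                contig, pos2, ref2, alt2, gene, sequences[contig], strand,
                motifs, flank, splice_offset=10, near_splice=True))
            if gi == 0:
                # variant 3: 500 bp from any splice site (window misses it)
                pos3 = genomic_pos(500, exon2)
                ref3, alt3 = add_variant(gene, contig, pos3, "case")
                truth_rows.append(_truth_row(
                    contig, pos3, ref3, alt3, gene, sequences[contig],
                    strand, motifs, flank, splice_offset=500,
                    near_splice=False))
        elif gi < 6:
            # 2 case + 1 control: excluded by the case-specific rule
            add_variant(gene, contig, genomic_pos(20, exon1), "case")
            add_variant(gene, contig, genomic_pos(30, exon2), "case")
            add_variant(gene, contig, genomic_pos(25, exon2), "control")
        else:
            cohort = "case" if gi % 2 == 0 else "control"
            add_variant(gene, contig, genomic_pos(15, exon1), cohort)

    annotations = pd.DataFrame([{
        "gene": g, "gdi_class": "low", "msc": 3.313,
        "heart_expr_percentile": 90.0 if i < 3 else 50.0,
        "known_chd_human": False, "known_chd_mouse": False,
        "tissue_class": "all_mixed",
    } for i, g in enumerate(genes)])

    return SequenceSim(
        exons=pd.DataFrame(exon_rows),
        sequences=sequences,
        dnvs=pd.DataFrame(dnv_rows, columns=DNV_COLUMNS + ["blacklisted"]),
        truth=pd.DataFrame(truth_rows),
        annotations=annotations,
    )


def _truth_row(contig, pos, ref, alt, gene, seq, strand, motifs, flank,
               splice_offset, near_splice):
    lo = max(pos - 1 - flank, 0)
    hi = min(pos + flank, len(seq))
    window = seq[lo:hi]
    idx = pos - 1 - lo
    if strand == "-":
        window = _revcomp(window)
        idx = len(window) - 1 - idx
    return {
        "variant_key": f"{contig}-{pos}-{ref}-{alt}",
        "gene": gene,
        "intended_overlap_count": _count_overlaps(window, idx, motifs),
        "splice_offset": splice_offset,
        "near_splice": near_splice,
    }
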