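"""End-to-end orchestration: filter -> enrich -> network -> prioritize -> ESE.

The pipeline runs the case and control arms through identical code paths,
supports stratified reruns on phenotype subgroups, and derives every
source of randomness from a single seed via named substreams so a run is
reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, filtering
from .connectome import PpiGraph, minimum_subnetwork, top1_connectome
from .enrichment import GeneSetCollection, run_ora, significant_sets
from .ese import MotifCollection, synonymous_track
from .prioritize import score_genes, select_candidates, two_sample_t

logger = logging.getLogger(__name__)

_SUBSTREAMS = {"control_extension": 21, "t_test": 22, "bootstrap": 23,
               "negative_control": 24}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream of the pipeline seed."""
    return np.random.default_rng([seed, _SUBSTREAMS[name]])


@dataclass
class PipelineConfig:
    """Input paths, thresholds and run options.

    Thresholds default to the printed study values: in-cohort allele
    frequency 4e-4, population MAF 1e-3, FDR 0.05, burden margin 2,
    subnetwork confidence floors 0.9 (high) and 0.4 (medium), splicing
    window 50 bp.
    """

    dnv_path: str | None = None
    annotation_path: str | None = None
    geneset_path: str | None = None
    interactome_path: str | None = None
    exon_path: str | None = None
    fasta_path: str | None = None
    seq_dnv_path: str | None = None
    motif_paths: list[str] = field(default_factory=list)
    known_gene_paths: list[str] = field(default_factory=list)
    blacklist_path: str | None = None

    cohort_af_max: float = 4e-4
    pop_maf_threshold: float = 1e-3
    fdr_alpha: float = 0.05
    burden_margin: int = 2
    strategy: str = "d"
    confidence_floors: tuple[float, float] = (0.9, 0.4)
    top_fraction: float = 0.01
    ese_window: int = 50
    stratify: bool = False
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        for name in ("cohort_af_max", "pop_maf_threshold", "fdr_alpha",
                     "burden_margin", "ese_window", "top_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RunReport:
    """Per-stage record counts plus every result table of a run."""

    config: dict
    seed: int
    version: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.10g")
        # the destination directory is self-evident and would make
        # otherwise-identical runs differ
        config_echo = {k: v for k, v in self.config.items() if k != "outdir"}
        meta = {"config": config_echo, "seed": self.seed,
                "version": self.version, "stage_counts": self.stage_counts,
                "summary": self.summary}
        (outdir / "report.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True, default=str))


def filter_arm(records: pd.DataFrame, annotations: pd.DataFrame,
               cfg: PipelineConfig, blacklist: set | None = None,
               counts: dict | None = None, label: str = ""):
    """The record-level filter cascade for one cohort arm.

    Returns (damaging, synonymous) tables; the synonymous track receives
    only the hard filters here (its gene-level filters are applied inside
    the splicing-enhancer stage).
    """
    counts = counts if counts is not None else {}
    counts[f"{label}_input"] = len(records)
    kept = filtering.apply_hard_filters(records, cfg.cohort_af_max)
    counts[f"{label}_hard_filtered"] = len(kept)
    damaging, synonymous = filtering.filter_molecular_class(kept)
    counts[f"{label}_damaging"] = len(damaging)
    counts[f"{label}_synonymous"] = len(synonymous)
    damaging = filtering.filter_population_maf(damaging, cfg.pop_maf_threshold)
    damaging = filtering.filter_gdi(damaging, annotations)
    damaging = filtering.filter_cadd_msc(damaging, annotations)
    damaging = filtering.exclude_x_linked_recessive(damaging)
    if blacklist:
        damaging = filtering.filter_blacklist(damaging, blacklist)
    counts[f"{label}_damaging_filtered"] = len(damaging)
    return damaging, synonymous


def analyze(
    dnvs: pd.DataFrame,
    annotations: pd.DataFrame,
    collection: GeneSetCollection,
    graph: PpiGraph,
    known: set[str],
    cfg: PipelineConfig,
    blacklist: set | None = None,
    label: str = "all",
) -> RunReport:
    """Run the full case/control analysis on in-memory inputs."""
    cfg.validate()
    report = RunReport(config=asdict(cfg), seed=cfg.seed, version=__version__)
    counts = report.stage_counts

    case = dnvs[dnvs["cohort"] == "case"]
    ctrl = dnvs[dnvs["cohort"] == "control"]
    case_dmg, case_syn = filter_arm(case, annotations, cfg, blacklist,
                                    counts, f"{label}_case")
    ctrl_dmg, ctrl_syn = filter_arm(ctrl, annotations, cfg, blacklist,
                                    counts, f"{label}_control")

    case_burden = filtering.select_genes(
        case_dmg, ctrl_dmg, cfg.strategy, cfg.burden_margin, cfg.fdr_alpha)
    ctrl_burden = filtering.select_genes(
        ctrl_dmg, case_dmg, cfg.strategy, cfg.burden_margin, cfg.fdr_alpha)
    case_genes = sorted(case_burden.loc[case_burden["selected"], "gene"])
    ctrl_genes = sorted(ctrl_burden.loc[ctrl_burden["selected"], "gene"])
    counts[f"{label}_case_genes"] = len(case_genes)
    counts[f"{label}_control_genes"] = len(ctrl_genes)
    report.tables[f"{label}_case_burden"] = case_burden
    report.tables[f"{label}_control_burden"] = ctrl_burden

    # enrichment, both arms
    case_ora = (run_ora(case_genes, collection, cfg.fdr_alpha)
                if case_genes else pd.DataFrame())
    ctrl_ora = (run_ora(ctrl_genes, collection, cfg.fdr_alpha)
                if ctrl_genes else pd.DataFrame())
    report.tables[f"{label}_case_enrichment"] = case_ora
    report.tables[f"{label}_control_enrichment"] = ctrl_ora
    sig = significant_sets(case_ora, collection) if len(case_ora) else {}
    counts[f"{label}_case_significant_sets"] = len(sig)
    counts[f"{label}_control_significant_sets"] = int(
        ctrl_ora["significant"].sum()) if len(ctrl_ora) else 0

    # networks at the configured confidence floors
    subnetworks = []
    sub_rows = []
    if case_genes:
        for floor in cfg.confidence_floors:
            try:
                sub = minimum_subnetwork(case_genes, graph, floor, known)
            except ValueError:
                continue
            subnetworks.append(set(sub.nodes))
            sub_rows.append({
                "confidence_floor": floor, "n_nodes": len(sub.nodes),
                "n_focus": len(sub.focus_genes),
                "n_known": sub.known_count,
                "n_dropped_seeds": len(sub.dropped_seeds),
                "nodes": ";".join(sub.nodes),
            })
    report.tables[f"{label}_subnetworks"] = pd.DataFrame(
        sub_rows, columns=["confidence_floor", "n_nodes", "n_focus",
                           "n_known", "n_dropped_seeds", "nodes"])

    # connectome top percentile per case gene (full graph)
    top1 = {g: top1_connectome(g, graph, cfg.top_fraction)
            for g in case_genes if g in graph}

    scores = score_genes(case_genes, sig, subnetworks, top1, known,
                         annotations)
    report.tables[f"{label}_scores"] = scores
    selection = None
    if scores["gene"].isin(known).any():
        selection = select_candidates(scores, known)
        report.summary[f"{label}_known_score_range"] = list(
            selection.known_score_range)
        report.summary[f"{label}_selected"] = selection.selected
        counts[f"{label}_selected_candidates"] = len(selection.selected)

    # scoring validation: known genes vs control-excess genes
    ctrl_pool = sorted(ctrl_burden.loc[
        ctrl_burden["n_controls"] > ctrl_burden["n_cases"], "gene"])
    known_in = sorted(set(case_genes) & known)
    if len(known_in) >= 2 and len(ctrl_pool) >= 2:
        rng = substream(cfg.seed, "t_test")
        k_sample = sorted(rng.choice(known_in,
                                     size=min(100, len(known_in)),
                                     replace=False))
        c_sample = sorted(rng.choice(ctrl_pool,
                                     size=min(100, len(ctrl_pool)),
                                     replace=False))
        score_map = scores.set_index("gene")["score"]
        ctrl_scores = score_genes(c_sample, sig, subnetworks,
                                  {g: top1_connectome(g, graph,
                                                      cfg.top_fraction)
                                   for g in c_sample if g in graph},
                                  known, annotations)
        k_vec = [float(score_map[g]) for g in k_sample]
        c_vec = ctrl_scores["score"].astype(float).tolist()
        if len(k_vec) >= 2 and len(c_vec) >= 2:
            t, p = two_sample_t(k_vec, c_vec)
            report.summary[f"{label}_score_t_test"] = {"t": t, "p": p}

    return report


def run_pipeline(
    cfg: PipelineConfig,
    inputs: Mapping | None = None,
) -> RunReport:
    """Run the full analysis from files (or pre-loaded ``inputs``).

    ``inputs`` may carry in-memory objects under the keys ``dnvs``,
    ``annotations``, ``collection``, ``graph``, ``known``, ``blacklist``,
    ``exons``, ``sequences``, ``motifs``, ``seq_annotations``; anything
    absent is loaded from the corresponding config path.
    """
    from . import io

    cfg.validate()
    inputs = dict(inputs or {})

    def load(key, loader, path):
        if key not in inputs and path:
            inputs[key] = loader(path)
        return inputs.get(key)

    dnvs = load("dnvs", io.read_dnv_table, cfg.dnv_path)
    annotations = load("annotations", io.read_annotations, cfg.annotation_path)
    collection = load("collection", GeneSetCollection.from_gmt,
                      cfg.geneset_path)
    graph = load("graph", PpiGraph.from_tsv, cfg.interactome_path)
    if dnvs is None or annotations is None:
        raise ValueError("DNV and annotation inputs are required")

    known = inputs.get("known")
    if known is None:
        known = set()
        for path in cfg.known_gene_paths:
            known |= set(io.read_gene_list(path))
        if not known:
            known = set(annotations.loc[
                annotations["known_chd_human"]
                | annotations["known_chd_mouse"], "gene"])
    known = set(known)

    blacklist = inputs.get("blacklist")
    if blacklist is None and cfg.blacklist_path:
        bl = pd.read_csv(cfg.blacklist_path, sep="\t")
        blacklist = set(zip(bl["chrom"].astype(str), bl["pos"].astype(int),
                            bl["ref"], bl["alt"]))

    report = analyze(dnvs, annotations, collection, graph, known, cfg,
                     blacklist, label="all")

    if cfg.stratify:
        strata = [("phenotype1", v) for v in ("isolated", "syndromic")]
        strata += [("phenotype2", v) for v in ("CTD", "LVO")]
        for col, value in strata:
            mask = (dnvs[col] == value) | (dnvs["cohort"] == "control")
            sub = dnvs[mask]
            if (sub["cohort"] == "case").sum() == 0:
                continue
            sub_rep = analyze(sub, annotations, collection, graph, known,
                              cfg, blacklist, label=value)
            report.stage_counts.update(sub_rep.stage_counts)
            report.tables.update(sub_rep.tables)
            report.summary.update(sub_rep.summary)

    # synonymous splicing-enhancer track
    exons = load("exons", io.read_bed, cfg.exon_path)
    sequences = load("sequences", io.read_fasta, cfg.fasta_path)
    motifs = inputs.get("motifs")
    if motifs is None and cfg.motif_paths:
        from .ese import load_motifs
        motifs = load_motifs(cfg.motif_paths)
    if exons is not None and sequences is not None and motifs is not None:
        seq_ann = inputs.get("seq_annotations", annotations)
        seq_dnvs = inputs.get("seq_dnvs", dnvs)
        if cfg.seq_dnv_path and "seq_dnvs" not in inputs:
            seq_dnvs = io.read_dnv_table(cfg.seq_dnv_path)
        case = seq_dnvs[seq_dnvs["cohort"] == "case"]
        ctrl = seq_dnvs[seq_dnvs["cohort"] == "control"]
        case_syn = case[case["mol_class"] == "synonymous"]
        ctrl_syn = ctrl[ctrl["mol_class"] == "synonymous"]
        gene_table, hits = synonymous_track(
            case_syn, ctrl_syn, seq_ann, exons, sequences, motifs,
            window=cfg.ese_window, maf_threshold=cfg.pop_maf_threshold)
        report.tables["ese_genes"] = gene_table
        report.tables["ese_hits"] = hits
        report.stage_counts["ese_candidate_genes"] = len(gene_table)
        report.stage_counts["ese_hits"] = len(hits)

    if cfg.outdir:
        report.write(cfg.outdir)
    return report


def negative_control_run(
    dnvs: pd.DataFrame,
    collection: GeneSetCollection,
    graph: PpiGraph,
    known: set[str],
    cfg: PipelineConfig,
    n_random_genes: int,
    seed: int | None = None,
) -> dict:
    """Enrichment + network stages on a random gene draw (specificity check).

    Genes are sampled uniformly from the unfiltered DNV gene universe;
    the summary states whether any set passed FDR and the known-gene
    content of the resulting subnetwork.
    """
    universe = sorted(dnvs["gene"].unique())
    if n_random_genes > len(universe):
        raise ValueError("n_random_genes exceeds the unfiltered universe")
    if n_random_genes == 0:
        return {"genes": [], "n_significant_sets": 0,
                "any_significant": False, "subnetwork_known_count": 0}
    rng = np.random.default_rng(
        [seed if seed is not None else cfg.seed,
         _SUBSTREAMS["negative_control"]])
    genes = sorted(rng.choice(universe, size=n_random_genes, replace=False))
    ora = run_ora(genes, collection, cfg.fdr_alpha)
    n_sig = int(ora["significant"].sum()) if len(ora) else 0
    sub_known = 0
    try:
        sub = minimum_subnetwork(genes, graph, cfg.confidence_floors[0],
                                 known)
        sub_known = sub.known_count
    except ValueError:
        pass
    return {
        "genes": genes,
        "n_significant_sets": n_sig,
        "any_significant": n_sig > 0,
        "subnetwork_known_count": sub_known,
    }
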