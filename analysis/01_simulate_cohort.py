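#!/usr/bin/env python
"""Generate the default synthetic cohort and all companion inputs.

Writes the DNV table, gene annotations, gene sets (GMT), interactome,
exon models + sequences + motif list for the splicing track, and the
ground-truth JSON under results/synthetic/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "synthetic"

from chdpath import io, simulate  # noqa: E402


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = simulate.SimConfig(seed=seed)
    dnvs, annotations, truth = simulate.generate_cohort(config)
    collection = simulate.generate_genesets(config, truth)
    graph = simulate.generate_ppi(config, truth)
    seqs = simulate.generate_sequences(config)

    io.write_dnv_table(dnvs, OUT / "dnvs.tsv")
    io.write_annotations(annotations, OUT / "annotations.tsv")
    collection.to_gmt(OUT / "genesets.gmt")
    graph.to_tsv(OUT / "interactome.tsv")
    io.write_bed(seqs.exons, OUT / "exons.bed")
    io.write_fasta(seqs.sequences, OUT / "sequences.fa")
    io.write_dnv_table(seqs.dnvs, OUT / "synonymous_dnvs.tsv")
    io.write_annotations(seqs.annotations, OUT / "seq_annotations.tsv")
    seqs.truth.to_csv(OUT / "sequence_truth.tsv", sep="\t", index=False)
    truth.to_json(OUT / "truth.json")
    (OUT / "motifs.txt").write_text(
        "".join(f"{m}\n" for m in simulate.DEFAULT_ESE_MOTIFS))

    n_case = (dnvs["cohort"] == "case").sum()
    n_ctrl = (dnvs["cohort"] == "control").sum()
    print(f"cohort: {config.n_case_trios} case / "
          f"{config.n_control_trios} control trios, "
          f"{n_case} case and {n_ctrl} control DNVs over "
          f"{config.n_genes} genes")
    print(f"planted signal: {len(truth.known_genes)} known + "
          f"{len(truth.planted_genes)} novel disease genes, "
          f"pathway '{truth.planted_set_id}'")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
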