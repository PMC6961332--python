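#!/usr/bin/env python
"""Filter the trio DNV calls down to case and control gene sets.

Applies the trio read-support hard filters, the molecular-class split,
population MAF, GDI, CADD>=MSC and X-linked-recessive filters, then
selects genes with a case excess of at least two variants (and the
mirrored control set). Writes burden tables under results/filtering/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "filtering"

from chdpath import filtering, io  # noqa: E402
from chdpath.pipeline import PipelineConfig, filter_arm  # noqa: E402


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dnvs = io.read_dnv_table(IN / "dnvs.tsv")
    annotations = io.read_annotations(IN / "annotations.tsv")
    cfg = PipelineConfig(seed=0)

    counts: dict = {}
    case_dmg, case_syn = filter_arm(dnvs[dnvs["cohort"] == "case"],
                                    annotations, cfg, counts=counts,
                                    label="case")
    ctrl_dmg, ctrl_syn = filter_arm(dnvs[dnvs["cohort"] == "control"],
                                    annotations, cfg, counts=counts,
                                    label="control")
    case_burden = filtering.select_genes(case_dmg, ctrl_dmg, "d", 2)
    ctrl_burden = filtering.select_genes(ctrl_dmg, case_dmg, "d", 2)
    case_burden.to_csv(OUT / "case_burden.tsv", sep="\t", index=False)
    ctrl_burden.to_csv(OUT / "control_burden.tsv", sep="\t", index=False)
    io.write_dnv_table(case_dmg, OUT / "case_damaging.tsv")
    io.write_dnv_table(ctrl_dmg, OUT / "control_damaging.tsv")

    for stage, n in counts.items():
        print(f"{stage}: {n}")
    n_case = case_burden["selected"].sum()
    n_ctrl = ctrl_burden["selected"].sum()
    print(f"selected {n_case} case genes and {n_ctrl} control genes "
          f"(margin >= 2)")


if __name__ == "__main__":
    main()
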