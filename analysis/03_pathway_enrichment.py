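#!/usr/bin/env python
"""Hypergeometric over-representation of the case and control gene sets.

Expects 01 and 02 to have run. Writes full enrichment tables under
results/enrichment/ and prints the top case pathways; under the planted
synthetic signal the planted disease pathway should lead the table while
the control arm stays empty.
"""

import pandas as pd
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SYN = ROOT / "results" / "synthetic"
FILT = ROOT / "results" / "filtering"
OUT = ROOT / "results" / "enrichment"

from chdpath.enrichment import GeneSetCollection, run_ora  # noqa: E402


def load_selected(path):
    burden = pd.read_csv(path, sep="\t")
    return sorted(burden.loc[burden["selected"], "gene"])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    collection = GeneSetCollection.from_gmt(SYN / "genesets.gmt")
    for arm in ("case", "control"):
        genes = load_selected(FILT / f"{arm}_burden.tsv")
        if not genes:
            print(f"{arm}: no selected genes, skipping")
            continue
        result = run_ora(genes, collection)
        result.to_csv(OUT / f"{arm}_enrichment.tsv", sep="\t", index=False)
        sig = result[result["significant"]]
        print(f"{arm}: {len(genes)} query genes, "
              f"{len(sig)} sets at FDR < 0.05")
        for _, row in sig.head(3).iterrows():
            print(f"  {row['set_id']}: k={row['overlap_k']}/"
                  f"{row['set_size_K']}, FDR={row['fdr']:.3g}")


if __name__ == "__main__":
    main()
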