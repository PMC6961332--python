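"""Hypergeometric over-representation analysis (ORA) with B-H FDR control.

Given a query gene list (e.g. the filtered case genes) and a collection of
named gene sets over a background universe, each set is tested for
over-representation of the query by the upper tail of the hypergeometric
distribution, and p-values are adjusted with the Benjamini-Hochberg
step-up procedure across all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways, GO terms) over a declared background.

    ``sets`` maps a set id to ``(description, member list)``. Members must
    lie inside the background universe and no set may be empty.
    """

    sets: dict[str, tuple[str, list[str]]]
    background: frozenset[str]
    source_tag: str = ""

    def __post_init__(self):
        self.background = frozenset(self.background)
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")
            stray = set(members) - self.background
            if stray:
                raise ValueError(
                    f"gene set {set_id!r} has members outside the "
                    f"background: {sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> set[str]:
        return set(self.sets[set_id][1])

    @classmethod
    def from_gmt(cls, path: str | Path, background: Iterable[str] | None = None,
                 source_tag: str = "") -> "GeneSetCollection":
        """Read a GMT file (tab-separated: id, description, members...)."""
        sets: dict[str, tuple[str, list[str]]] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: GMT line has <3 fields")
            set_id, desc, members = fields[0], fields[1], fields[2:]
            if set_id in sets:
                raise ValueError(f"{path}:{i}: duplicate set id {set_id!r}")
            sets[set_id] = (desc, members)
        if background is None:
            background = {g for _, m in sets.values() for g in m}
        return cls(sets=sets, background=frozenset(background),
                   source_tag=source_tag or str(path))

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for set_id, (desc, members) in self.sets.items():
                fh.write("\t".join([set_id, desc, *members]) + "\n")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts members of a size-``K`` category in a size-``n`` draw without
    replacement from a universe of ``N`` genes.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    min_overlap: int = 1,
    min_set_size: int = 2,
    include_zero_overlap: bool = True,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every set of ``collection``.

    Query genes outside the background are dropped (logged). Sets smaller
    than ``min_set_size`` after background intersection are skipped. By
    default every eligible set is tested and enters the B-H multiplicity
    ``m`` (zero-overlap sets included, which keeps the false discovery
    rate controlled for small queries); ``include_zero_overlap=False``
    restricts the multiplicity to sets overlapping the query.

    Returns one row per tested set with overlap >= ``min_overlap``,
    sorted by (fdr, p_raw, set_id), with a ``significant`` flag at
    ``fdr < alpha``.
    """
    query = set(query)
    in_bg = query & collection.background
    dropped = len(query) - len(in_bg)
    if dropped:
        logger.info("dropped %d query genes outside the background", dropped)
    if not in_bg:
        raise ValueError("query is empty after background intersection")

    N = len(collection.background)
    n = len(in_bg)
    rows = []
    for set_id in sorted(collection.sets):
        desc, members = collection.sets[set_id]
        mem = set(members)  # already within background by construction
        if len(mem) < min_set_size:
            logger.debug("skipping %s: %d members < %d",
                         set_id, len(mem), min_set_size)
            continue
        overlap = sorted(in_bg & mem)
        if not overlap and not include_zero_overlap:
            continue
        rows.append({
            "set_id": set_id,
            "description": desc,
            "overlap_k": len(overlap),
            "set_size_K": len(mem),
            "query_n": n,
            "background_N": N,
            "p_raw": hypergeom_tail(len(overlap), len(mem), n, N),
            "overlap_genes": ";".join(overlap),
        })
    if not rows:
        return pd.DataFrame(columns=[
            "set_id", "description", "overlap_k", "set_size_K", "query_n",
            "background_N", "p_raw", "fdr", "significant", "overlap_genes"])

    result = pd.DataFrame(rows)
    result["fdr"] = bh_adjust(result["p_raw"].to_numpy())
    result = result[result["overlap_k"] >= min_overlap]
    result["significant"] = result["fdr"] < alpha
    result = result.sort_values(
        ["fdr", "p_raw", "set_id"], kind="mergesort"
    ).reset_index(drop=True)
    cols = ["set_id", "description", "overlap_k", "set_size_K", "query_n",
            "background_N", "p_raw", "fdr", "significant", "overlap_genes"]
    return result[cols]


def significant_sets(result: pd.DataFrame,
                     collection: GeneSetCollection) -> dict[str, set[str]]:
    """Member sets of the significant ORA rows, keyed by set id."""
    return {
        set_id: collection.members(set_id)
        for set_id in result.loc[result["significant"], "set_id"]
    }
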