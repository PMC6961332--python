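"""Composite priority scoring of candidate disease genes.

A gene's priority score is the total number of known disease-causing
genes found in (i) the significantly enriched gene sets containing the
gene, counted per set with multiplicity, (ii) the retained interaction
subnetworks containing the gene, and (iii) the closest 1% of the gene's
connectome. Candidates are selected when their score falls inside the
closed range spanned by the known genes' scores and the gene is highly
expressed in the developing heart (top quartile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Heart-expression percentile at or above which a gene counts as highly
#: expressed during heart development (top quarter of expressed genes).
HHE_PERCENTILE = 75.0


@dataclass
class PriorityRecord:
    """Per-gene evidence tallies and composite score."""

    gene: str
    pathway_known_count: int
    network_known_count: int
    connectome_known_count: int
    hits: int  # number of significant sets containing the gene
    hhe: bool = False
    known: bool = False
    rank: int | None = None

    @property
    def score(self) -> int:
        return (self.pathway_known_count + self.network_known_count
                + self.connectome_known_count)


def priority_score(
    gene: str,
    significant_sets: Mapping[str, set[str]] | Sequence[set[str]],
    subnetworks: Sequence[set[str]],
    connectome_top1: Mapping[str, set[str]],
    known: set[str],
    unique: bool = False,
) -> PriorityRecord:
    """Score one gene by its proximity to known disease genes.

    ``significant_sets`` are the memberships of sets enriched at
    FDR < alpha; ``subnetworks`` the node sets of retained subnetworks;
    ``connectome_top1`` maps a gene to the closest 1% of its connectome.
    Known genes are counted per evidence set (with repetition across
    sets); ``unique=True`` counts each known gene at most once per
    component instead.
    """
    if isinstance(significant_sets, Mapping):
        significant_sets = list(significant_sets.values())
    containing = [s for s in significant_sets if gene in s]
    nets = [s for s in subnetworks if gene in s]
    top1 = connectome_top1.get(gene, set())
    if unique:
        pathway = len(set().union(*[s & known for s in containing])
                      if containing else set())
        network = len(set().union(*[s & known for s in nets])
                      if nets else set())
    else:
        pathway = sum(len(s & known) for s in containing)
        network = sum(len(s & known) for s in nets)
    return PriorityRecord(
        gene=gene,
        pathway_known_count=pathway,
        network_known_count=network,
        connectome_known_count=len(top1 & known),
        hits=len(containing),
        known=gene in known,
    )


def score_genes(
    genes: Iterable[str],
    significant_sets: Mapping[str, set[str]] | Sequence[set[str]],
    subnetworks: Sequence[set[str]],
    connectome_top1: Mapping[str, set[str]],
    known: set[str],
    annotations: pd.DataFrame | None = None,
    unique: bool = False,
) -> pd.DataFrame:
    """Score every gene; returns a ranked table.

    Ranking is by score descending with ties broken by gene symbol; the
    ``hhe`` flag comes from the annotation table's heart-expression
    percentile (>= 75).
    """
    columns = ["gene", "pathway_known_count", "network_known_count",
               "connectome_known_count", "score", "hits", "known", "hhe",
               "rank"]
    records = [
        priority_score(g, significant_sets, subnetworks, connectome_top1,
                       known, unique=unique)
        for g in sorted(set(genes))
    ]
    if not records:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame([{
        "gene": r.gene,
        "pathway_known_count": r.pathway_known_count,
        "network_known_count": r.network_known_count,
        "connectome_known_count": r.connectome_known_count,
        "score": r.score,
        "hits": r.hits,
        "known": r.known,
    } for r in records])
    if annotations is not None:
        pct = annotations.set_index("gene")["heart_expr_percentile"]
        df["hhe"] = df["gene"].map(pct).ge(HHE_PERCENTILE).fillna(False)
    else:
        df["hhe"] = False
    df = df.sort_values(["score", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class SelectionReport:
    """Candidate selection against the known genes' score range."""

    known_score_range: tuple[float, float]
    selected: list[str]
    score_table: pd.DataFrame = field(repr=False)

    def to_json_dict(self) -> dict:
        return {
            "known_score_range": list(self.known_score_range),
            "selected": self.selected,
            "n_scored": int(len(self.score_table)),
        }


def select_candidates(records: pd.DataFrame,
                      known: set[str]) -> SelectionReport:
    """Select non-known, heart-expressed genes scoring like known genes.

    The selection window is the closed [min, max] range of the known
    genes' scores; candidates must additionally be highly expressed in
    the developing heart (``hhe``).
    """
    records = records.copy()
    records["known"] = records["gene"].isin(known)
    known_scores = records.loc[records["known"], "score"]
    if known_scores.empty:
        raise ValueError("no known gene present in the score table")
    lo, hi = float(known_scores.min()), float(known_scores.max())
    sel = records[
        ~records["known"]
        & records["hhe"]
        & records["score"].between(lo, hi)
    ]
    sel = sel.sort_values(["score", "gene"], ascending=[False, True],
                          kind="mergesort")
    return SelectionReport(
        known_score_range=(lo, hi),
        selected=sel["gene"].tolist(),
        score_table=records,
    )


def two_sample_t(group1, group2, mode: str = "welch") -> tuple[float, float]:
    """Independent two-sample t test (two-sided).

    Each group is either a raw score vector or an ``(n, mean, sd)``
    summary triple; Welch's unequal-variance form is the default
    (``mode='pooled'`` for the classical pooled test). Two degenerate
    zero-variance groups with equal means return ``(0.0, 1.0)``.
    """
    if mode not in ("welch", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    equal_var = mode == "pooled"

    def as_stats(g):
        # summary triples are passed as tuples; vectors as lists/arrays
        if isinstance(g, tuple) and len(g) == 3 and np.isscalar(g[0]):
            n, mean, sd = g
            if n < 2 or sd < 0:
                raise ValueError("need n >= 2 and sd >= 0")
            return float(n), float(mean), float(sd)
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError("need n >= 2")
        return float(arr.size), float(arr.mean()), float(arr.std(ddof=1))

    n1, m1, s1 = as_stats(group1)
    n2, m2, s2 = as_stats(group2)
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                      equal_var=equal_var)
    return float(t), float(p)


def yates_chi2(table, correction: bool = True) -> tuple[float, float]:
    """Chi-squared test of independence on a 2x2 table, 1 df.

    With ``correction`` (default) the Yates continuity correction
    ``N(|ad-bc| - N/2)^2 / (r1 r2 c1 c2)`` is applied, clamped at zero;
    without it the classical ``N(ad-bc)^2 / (r1 r2 c1 c2)``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    (a, b), (c, d) = t
    N = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero marginal total")
    num = abs(a * d - b * c)
    if correction:
        num = max(num - N / 2.0, 0.0)
    chi2 = N * num ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def score_percentile_ci(
    scores, level: float = 0.95, n_boot: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """Bootstrap percentile confidence interval of the mean score."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; interval will be noisy")
    rng = np.random.default_rng(seed)
    means = rng.choice(scores, size=(n_boot, scores.size), replace=True
                       ).mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)
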