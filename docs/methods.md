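# Methods

This note records the models, conventions and numerical choices behind
`chdpath`, and what the synthetic experiments do and do not demonstrate.

## Filtering model

The filter cascade operates at two levels. Record-level filters are
predicates on a single DNV call and therefore commute and are
idempotent (a property the test suite checks by permuting them):

- **Trio hard filters.** In-cohort allele frequency ≤ 4×10⁻⁴ (boundary
  inclusive); proband ≥ 10 total reads, ≥ 5 alternate reads, alternate
  ratio ≥ 0.20 when alternate reads ≥ 10 and ≥ 0.28 otherwise; each
  parent ≥ 10 reference reads with alternate ratio < 0.035; molecular
  class exonic or canonical splice (±2 bp only; extended splice regions
  are not treated as splice class). Records missing a read-support field
  are rejected with reason `missing_field` rather than guessed at.
- **Population MAF.** A record passes when MAF < 10⁻³ in *every*
  database where a value exists; a record absent from all four databases
  passes, since absence from large population panels is itself evidence
  of rarity. A strict mode inverts this for sensitivity analysis.
- **CADD ≥ MSC** is inclusive at the boundary. Unannotated genes raise
  by default (silent pass-through would bias burden counts); a
  pass-with-warning mode exists for exploratory runs.
- **X-linked recessive.** The inheritance pattern must be inferred from
  the available fields. Rule: drop non-pseudoautosomal X records in male
  probands with alternate-allele ratio ≥ 0.8 (hemizygous-consistent);
  keep heterozygous female and all pseudoautosomal records. PAR
  boundaries are the hg19 standard (60,001–2,699,520 and
  154,931,044–155,260,560).

Gene-level selection defaults to the margin rule
(*n*<sub>cases</sub> − *n*<sub>controls</sub> ≥ 2). The Fisher
strategies build the 2×2 table [variants in gene vs variants in all
other genes] × [case vs control], two-sided, B-H corrected over the
tested genes — a construction chosen because it needs only the counts
the pipeline already has. Coordinates are 1-based inclusive in DNV and
exon tables; BED on disk is 0-based half-open, converted in the I/O
layer only.

## Enrichment

`hypergeom_tail(k, K, n, N)` is the upper tail P(X ≥ k) of the
hypergeometric distribution (scipy's survival function; validated
against exact integer enumeration for every configuration with N ≤ 25).
B-H adjustment is the standard step-up (statsmodels), order-preserving.

Two conventions matter for FDR behaviour:

- The background universe defaults to the annotation universe (all
  genes in the annotation table), overridable; member lists are
  intersected with it and sets below 2 members are skipped.
- **Every eligible set enters the multiplicity *m*, including sets with
  zero query overlap.** Restricting *m* to overlapping sets (an
  alternative kept behind `include_zero_overlap=False`) is
  anticonservative for small queries — with ~13-gene queries against 99
  sets it produced spurious discoveries in roughly a fifth of null
  cohorts, while the default keeps the empirical false-discovery rate at
  or below nominal in the 500-simulation null experiment.

Result ordering is (fdr, p_raw, set_id) so ties are deterministic.

## Connectome

Direct edge distance is the reciprocal of interaction confidence
(confidence scaled to (0, 1]; STRING-style 0–1000 scores are divided by
1000 on ingest, auto-detected from the maximum). Reciprocal confidence
reproduces the granularity of published degree-1 biological distances
(confidence 0.8 → 1.25, 0.9 → 1.11); −log(confidence) is available as
an alternative for multiplicative semantics. Percentile p of a gene in
another's connectome is rank / reachable-count with tied distances
sharing the maximal rank of their block; top-1% membership (p ≤ 0.01)
is the significance rule.

The minimum subnetwork is the classical greedy Steiner 2-approximation:
after removing edges at or below the confidence floor (strictly
greater-than survives), the tree grows from the lexicographically first
seed of the component holding the most seeds, repeatedly attaching the
nearest unconnected seed via its shortest path. Seeds outside that
component are dropped and reported. The suite verifies connectivity and
the 2× bound against a brute-force Steiner optimum on ≤ 10-node
instances.

UPGMA is implemented directly (rather than through a generic linkage
routine) to guarantee lexicographic tie-breaking and exact Newick
control; heights are half the merge distance, so the output is
ultrametric by construction. Unreachable pairs in a distance matrix are
capped at twice the largest finite distance, which places disconnected
genes in an outgroup rather than failing.

## Priority score

The score sums, over the three evidence channels, the number of known
disease genes co-occurring with the gene: significantly enriched sets
containing it (counted per set, with multiplicity — the published score
magnitudes are only reachable if a known gene in several pathways
counts several times; a unique-counting mode exists for sensitivity),
retained subnetworks containing it (both confidence floors by default),
and its top-1% connectome. The number of significant sets containing
the gene is exposed separately as `hits` without asserting equivalence
to the score. Selection takes non-known genes inside the closed known
score range with heart-expression percentile ≥ 75 ("high heart
expression", the top quartile of genes expressed in the E14.5
developing heart).

Validation statistics: the two-sample t defaults to Welch (robust to
the extreme variance ratio between known and control scores; pooled and
Welch coincide at equal n and sd), accepts either raw vectors or
(n, mean, sd) summaries, and returns (0, 1) for the degenerate
zero-variance equal-means case. The chi-squared uses the Yates
continuity correction by default, clamped at zero, with the uncorrected
statistic behind a flag. The "95th percentile confidence interval" of a
score group is a seeded bootstrap percentile CI of the group mean
(10,000 resamples by default).

## ESE scanning

Motif collections are case-folded unions with duplicates removed and
per-motif provenance kept. Splice-site offsets are 1-based in
transcript orientation: +1 is the first exonic base after the acceptor,
−1 the last before the donor, and the nearer site is reported (ties to
the acceptor). "Near a splice site" defaults to a 50 bp window
(exposed as a flag; the motivating worked example sits at +41 bp).
Scanning runs on the transcript sense strand — minus-strand contexts
are reverse-complemented on extraction — and requires the supplied
context to cover the variant ± (longest motif − 1) bases; a hit is an
exact motif occurrence spanning the variant base, `disrupted` when the
alternate allele breaks the occurrence (degenerate motifs matching both
alleles are hits but not disruptions).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the biology of any particular cohort:

- **Counts.** Per-gene DNV counts are Poisson — the natural law for
  rare independent events and analytically convenient. Disease genes
  (30 known + 10 planted novel by default) draw case counts at an
  elevated rate (5.0 expected DNVs per gene per cohort vs 0.3
  background); controls draw at the background rate scaled by relative
  cohort size. The cohort shape is the emulated study scaled down
  tenfold (264 case / 179 control trios, 1000 genes). At this scale the
  per-gene absolute counts, not per-trio rates, carry the pathway-level
  power, so the planted rate keeps disease-gene counts comparable to
  the most recurrently hit genes of the full-scale study; the expected
  case−control excess per planted gene is ≥ 2 by construction.
- **Classes.** Damaging molecular classes follow the observed cohort
  composition (missense : nonsense : frameshift : splice : start-loss =
  232 : 37 : 36 : 14 : 1) with a 0.28 synonymous fraction; damaging
  variants are capped at two per sample, reproducing the reported
  single/double-carrier pattern.
- **Annotations.** GDI classes are drawn at (low, medium, high) =
  (0.6, 0.3, 0.1) with disease genes redrawn among low/medium (a
  high-GDI disease gene would contradict the filter's premise); MSC is
  truncated normal (12 ± 4); per-class CADD means put damaging classes
  well above typical MSC and synonymous below. Disease genes draw
  heart-expression percentiles in [75, 100] so that the expression gate
  is informative rather than lethal to power.
- **Population MAFs** are absent per database with probability 0.7,
  otherwise a rare log-uniform tail; 5% of variants are made common
  (≥ 2×10⁻³) to exercise the MAF filter, and 5% carry read-support
  defects drawn from four failure modes, recorded in the truth object.
- **Gene sets.** One planted pathway of 30 genes holds 90% of the
  planted novel genes topped up with known genes; the other 99 sets are
  uniform draws (10–60 genes).
- **Interactome.** Barabási–Albert preferential attachment (m = 2)
  gives the scale-free background; pairs inside the planted community
  (known + planted genes) are additionally wired at density 0.3 with
  confidence > 0.9, so the community survives high-confidence
  thresholding the way a real disease module concentrates
  high-confidence interactions.
- **Sequences.** Ten two-exon genes on alternating strands; three carry
  case-specific synonymous pairs, one variant of each embedded in a
  stacked-motif enhancer context +41 bp from a splice acceptor, plus one
  variant 500 bp from any splice site to exercise the window rule.
  Intended motif-overlap counts are recorded in the truth table by
  direct enumeration on the final sequence.

What passing the synthetic experiments shows: the pipeline recovers a
planted convergent signal of this strength and stays empty on matched
null cohorts. What it does not show: performance on real cohorts, where
DNV rates vary per gene with sequence context and length, gene sets
overlap hierarchically, interactome confidence is biased by study
effort, and annotations are incomplete — none of which the generator
models.

## Problem sizes and determinism

Default experiment sizes (1000 genes, ~500–750 DNVs per cohort, 100
gene sets, ~2200-edge interactome, 10 seeds for power and 10 for
specificity, 500 null ORA simulations) were chosen so every analysis
step remains exact rather than approximated while a full run of the
suite completes in well under an hour on one core. All randomness flows
from a single seed through named substreams (cohort, gene sets, graph,
sequences, control extension, t-test sampling, bootstrap, negative
control), so any run — including the full pipeline report — is
reproducible byte for byte.

## Known limitations

- Strategies a/b (Fisher) are provided but the margin rule is the
  analysis default; with heterogeneous signal the Fisher tests are
  underpowered at realistic counts, which is the design reason the
  margin rule exists.
- The empirical percentile rule (top 1%) stands in for a parametric
  connectome p-value; with small reachable sets the granularity of
  rank/reachable can make the 1% set empty.
- The ESE scanner requires motif occurrences to lie inside the supplied
  context and does not model splice-site strength, branch points, or
  silencer (ESS) motifs.
- The priority score treats evidence channels additively with equal
  weight; no calibration against a gold standard is attempted.
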