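# Methods

## Expression substrate and replicate collapsing

The analysis substrate is a genes × samples matrix of FPKM values with a
sample → tissue assignment (typically 27 tissues, a few samples per
tissue). Values must be finite and non-negative; the format has no NA
convention, so absent measurements must be written as 0 upstream. Tissue
labels are case-sensitive and stripped of surrounding whitespace.
Replicates are collapsed by the arithmetic mean of raw FPKM per tissue —
averaging happens before any log transform, so a tissue's mean estimates
its total expression level on the original scale. Matrices are written
with `%.6g` precision; a write→read→write cycle is a fixed point, which
is what makes pipeline reruns byte-identical.

## Specificity classification

Each gene is assigned exactly one category relative to the target tissue
from its per-tissue means, with these thresholds (all configurable via
`ClassificationConfig`):

- **detection limit** 1 FPKM, *strict* inequality (detected ⇔ mean > 1);
  1 FPKM corresponds roughly to one mRNA copy per cell.
- **fold cutoffs** ≥ 50× (highly enriched) and ≥ 5× (moderately
  enriched, group enriched, enhanced), inclusive — a score of exactly
  50 falls in the highly enriched tier. Inclusivity matters at the
  boundary: a catalogued gene at 52.2-fold belongs to the ≥ 50 tier.
- **group sizes** 2–7 tissues including the target.
- **expressed-in-all split** at 10 FPKM (all tissues ≥ 10 → high band).

The precedence chain is: not-detected → highly → moderately → group →
expressed-in-all (high, then low) → enhanced → mixed. Two ordering
choices deserve note:

1. *Enrichment before expressed-in-all.* A gene detected everywhere that
   still clears an enrichment criterion is reported as enriched; the
   categories are exclusive and specificity is the more informative
   label.
2. *Expressed-in-all before enhanced.* An enhanced call therefore
   implies the gene is not detected in every tissue or not 5× above the
   across-tissue average while being ubiquitous. The enhanced
   denominator is the mean over **all** tissues, target included.

The enrichment tiers and the enhanced tier additionally require the
target tissue itself to be detected: a gene below 1 FPKM in the target
cannot be called target-elevated no matter how silent the other tissues
are. The same logic requires every member of an enriched group to be
detected — a "group" expressing a gene below the detection limit is
biologically meaningless.

"Not detected" means not detected in *any* tissue. A gene silent in the
target but expressed elsewhere is classified mixed (or expressed-in-all
if ubiquitous), never not-detected.

**Tissue-specific score.** Score = target mean / max other-tissue mean.
When the denominator is 0 the score is +inf if the target expresses the
gene (classified highly enriched when the target is detected) and 0 when
the gene is absent everywhere. The score is invariant to rescaling the
whole matrix; only the detection and 10-FPKM boundaries are
scale-dependent.

**Group search.** For each k from 2 to 7 the candidate group is the
target plus the k−1 highest-expressing other tissues, ties broken by
tissue label for determinism. The smallest accepted k wins. Top-k
candidates are optimal: among groups of size k containing the target,
taking the largest other tissues simultaneously maximises the group mean
and minimises the excluded maximum, and if a top-k member is undetected
then every size-k group contains an undetected member. The test suite
checks this equivalence against exhaustive subset enumeration on
matrices of up to 10 tissues.

**Census.** Per-category counts and fractions, plus a four-way rollup:
not detected / mixed / expressed-in-all / elevated (highly + moderately +
group + enhanced).

## Correlation analysis

Pairwise coefficients between samples or tissue means are computed on
log2(FPKM + 1); the +1 pseudo-count keeps zeros finite and maps them to
0\. Spearman uses mid-ranks (average ranks on ties) of the transformed
values, Pearson the transformed values themselves. All genes enter — no
detection filter — matching genome-wide scatterplot practice. Columns
with zero variance have no defined coefficient; the affected pairs are
reported as NaN sentinels while the rest of the matrix is unaffected.
Constant columns are detected by zero range rather than a floating-point
variance test.

## Co-enrichment network

From the classification results, one combo node per distinct enriched
group (weight = gene count, restricted to groups of ≤ `max_combo`
tissues, default 4 — a display convention), linked to its member tissue
nodes; the target node carries the highly+moderately enriched gene count
as its weight. Per-tissue sharing tallies (genes whose group contains
both that tissue and the target) are computed over *all* group sizes, so
the tallies and the displayed network deliberately differ when groups
larger than `max_combo` exist. Export is GraphML plus an edge-list TSV.

## IHC marker evaluation

Staining intensity is scored 0–3 (0 none, 1 faint, 2 moderate, 3 strong
reactivity in > 30% of epithelial cells) and dichotomized at 2: scores
0/1 are marker-negative, 2/3 positive. Replicate cores per case are
collapsed by the maximum score (the common TMA convention — a case is
positive if any core is; `mean` collapsing is available). Cases are
treated as independent units. Histology is split benign vs. tumor +
metastasis for the 2×2 table; the full negative/positive × {benign, GG2,
GG3, GG4, GG5, metastasis} breakdown is also emitted.

All 2×2 statistics use closed forms with **no continuity correction**
(validated in the tests by exact reproduction of published chi-square
values from printed counts, and against scipy's uncorrected
implementation):

- χ² = n(ad−bc)²/(r₁r₂c₁c₂), p from the df=1 upper tail;
- G = 2ΣO·ln(O/E) with empty cells contributing 0 (the 0·ln 0 limit);
- φ = (ad−bc)/√(r₁r₂c₁c₂); rows are ordered negative→positive and
  columns benign→tumor, so a benign-specific marker yields negative φ.
  On binary×binary data Spearman's ρ equals φ and is reported
  identically. χ² = n·φ² holds algebraically and is asserted on random
  tables.

The *condition* of the diagnostic test is the benign gland: sensitivity
is the positive fraction among benign cases, specificity the negative
fraction among tumor cases. A single-threshold binary test has ROC AUC
= (sensitivity + specificity)/2; for the un-dichotomized 0–3 score a
tie-corrected Mann–Whitney AUC (P(score_benign > score_tumor) + ½P(=),
computed from mid-ranks) is provided, which reduces to the binary AUC on
dichotomized scores. Undefined statistics (zero margin, empty class) are
returned as NaN sentinels and serialized as JSON null; a one-class
cohort evaluates with a warning, not an error. p-values below are
reported as computed; a printed "0.000" in legacy software output should
be read as p < 0.0005.

## Synthetic data

**Matrices.** The generator emulates a 27-tissue FPKM compendium: 4
samples per tissue, detection limit 1 FPKM, dynamic range ≈ 10⁴. For
each requested gene a vector of expected tissue means is planted to
satisfy its category's inequality with a margin strictly inside the
threshold, then sample values multiply the mean by 2^N(0, σ) with σ =
0.2 on the log2 scale by default (≈ ±15% typical measurement noise).
Margins: highly enriched planted at 70–700× (vs. the 50× cutoff),
moderately at 7–35× (inside [5, 50)), group and enhanced at ≥ ~7× (vs.
5×); expressed-in-all-low genes sit in 3–9 FPKM, -high in 15–60 FPKM,
keeping within-gene tissue ratios below 5 so no enrichment tier fires;
mixed genes either silence the target or express it at the level of ≥ 14
peer tissues. Group genes draw their size uniformly from 2–7, always
include the target, and keep members within 2× of each other so no
single member is individually enriched. Default per-category counts
mirror, at ~100-gene desk scale, a genome that is ~30% not detected,
~23% mixed, ~46% expressed-in-all and ~1% target-elevated (the elevated
classes are inflated to 2 genes each so they are represented at all).
Zero noise gives exact recovery of planted labels; at σ = 0.2 recovery
is ≥ 95% (both regression-tested at fixed seeds). Infeasible margins
(e.g. a moderate fold range crossing the 50× cutoff) are rejected at
construction.

**Cohorts.** One latent 0–3 score per case is drawn from a per-class
categorical distribution; all replicate cores of a case carry that score,
so the planted per-class positivity P(score ≥ 2) is exactly the per-case
truth after max-collapse (an independent per-core draw would inflate
positivity under the max convention). Defaults emulate a four-cohort
prostate TMA study: 156 benign, 3/76/62/21 tumors of Gleason grades 2–5,
15 metastases, duplicate cores, benign positivity 0.814 and per-grade
tumor positivities of 0.0/0.224/0.113/0.095/0.20 — a strongly
benign-specific membranous marker. All generators use a single seeded
NumPy generator per call; identical specs give bit-identical output.

## What the synthetic data does and does not show

The generator plants clean multiplicative noise around well-separated
category margins and cohorts with exactly the intended positivity rates.
Passing tests therefore demonstrate that the classification, search and
statistics are implemented correctly — not that real tissue panels are
this well behaved. Real FPKM matrices have correlated samples,
compositional and length biases, and genes genuinely straddling the fold
cutoffs, where category calls are sensitive to measurement error in a
way the planted margins deliberately avoid. Published genome-wide gene
lists (e.g. how many genes fall in each tier of a specific 27-tissue
compendium) depend on the underlying cohort and are not reproducible
from synthetic data; what is reproducible — and what the acceptance
script and tests recompute — are the score and statistic definitions
applied to printed per-gene and per-table values.

## Numerical and design notes

- Problem sizes in the tests (≈ 100–200 planted genes, cohorts up to
  10,000 cases per class for convergence checks, 1,000 random tables for
  the χ² = n·φ² identity) keep the full suite around ten seconds while
  leaving Monte-Carlo bounds (±0.02 on sensitivity/specificity at
  n = 10⁴) comfortably tight.
- Ties in the top-k group selection and all output orderings are broken
  lexicographically; no wall-clock, locale or machine state enters any
  output, so reruns are byte-identical.
- The score's infinity sentinel propagates through TSV round-trips via
  pandas' `inf` representation.
- Known limitations: no plotting (networks are exported for external
  layout tools, e.g. Cytoscape); no survival analysis; no modeling of
  read-level RNA-seq — the generator works at FPKM level only; the CLI
  reads whole matrices into memory, which is fine for genome-scale
  (2×10⁴ genes) panels but not for single-cell-scale column counts.
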