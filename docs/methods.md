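# Methods

This note records the models and procedures the package implements, the
decisions taken where the design was genuinely open, and what the
synthetic fixtures do and do not demonstrate.

## Locus assembly from RepeatMasker fragments

RepeatMasker's `.out` dialect is parsed line by line: three header
lines, whitespace-separated columns, `C` for complement-strand hits
(whose consensus coordinates are printed as `(left) end begin` and are
reordered so `r_start ≤ r_end`), and an optional trailing `*` marking a
hit overlapped by a higher-scoring one. All genomic coordinates are
1-based inclusive throughout the package — RepeatMasker and GTF agree on
this convention, so nothing is ever shifted.

Assembly happens in two steps:

1. **ID linkage.** Fragments sharing the integer ID column on one
   reference are one interrupted element and are bundled unconditionally
   — this is RepeatMasker's own statement of identity and needs no
   heuristic.
2. **Adjacency merging.** ID-linked groups are walked in genomic order
   and consecutive groups are fused into one locus when *all* of the
   following hold (the `MergePolicy` defaults):
   - both groups are LTR-class (`merge_scope="ltr_only"`);
   - same strand (`require_same_strand=True`);
   - the gap between the running locus end and the next group's start is
     at most `max_gap = 100` bp;
   - of the two fragments facing the junction, at least one is an
     internal-region model, recognized by the name suffixes
     `-int`, `_I`, `-I`, `_int`.

The internal-suffix rule is the load-bearing heuristic. No curated table
pairing each LTR model with its internal model is available, so the
package relies on adjacency plus the naming convention instead: an LTR
next to an internal segment is treated as one provirus, while two
neighbouring solo LTRs — a common arrangement — are never fused. Testing
the *junction-facing* fragments rather than "any fragment in either
group" is what makes merging idempotent: a complete LTR–internal–LTR
locus presents terminal repeats at both ends, so re-running the merger
on its own output (or next to another complete provirus) changes
nothing. `max_gap = 100` bp is a deliberately tight default: the gaps
between a provirus's annotated segments are short sequence stretches the
masker failed to attribute, whereas a 100+ bp unannotated stretch more
likely separates independent elements. Both the gap and the suffix list
are configurable.

Fragments flagged `*` are kept by default (dropping a real overlapped
annotation loses signal; duplicated assignment is prevented downstream
by unique counting anyway); `--drop-overlapped` removes them. With
`merge_scope="all_classes"` the same adjacency rule applies within every
top-level repeat class rather than only LTR; the default is LTR-only
because LTR/internal fragmentation is the phenomenon the merger exists
for, and non-LTR elements are already handled by ID linkage.

A merged locus is named `class|names|chrom|start|end`, where `names`
chains the constituent repeat models internal-first (`MuLV-int~RLTR4_Mm`),
de-duplicated in order of first genomic appearance, and `start`/`end`
span the full merged extent. The parser also accepts the typeset `∼`
variant of the separator. The codec is exercised as a bijection in the
tests.

## Unique-assignment counting

A *countable unit* is a primary, mapped alignment record — or, in the
default `fragment` pairing mode, the union of both mates' aligned blocks
(one count per template). Secondary and supplementary records are always
skipped; there is no MAPQ filter by default (`--min-mapq` exists). Only
aligned match/deletion blocks are tested for overlap, so a spliced read
does not touch features under its skipped introns.

Assignment uses a ≥ 1 bp overlap rule against an interval index: a unit
overlapping no feature is *unassigned*, exactly one feature is
*assigned*, more than one is *ambiguous* and counted nowhere. Per
sample, `assigned + ambiguous + unassigned` equals the number of
countable units — an exact conservation law asserted in the tests.

Genes and repeat loci are counted in two independent passes over the
same alignments, each against its own annotation. A read overlapping one
gene and one repeat locus is therefore assigned in both passes; the two
matrices answer different questions and are not meant to partition the
reads between them.

The merging motivation is checked quantitatively: on fixtures where a
configurable fraction of reads spans a former LTR/internal junction, the
merged locus always collects strictly more reads than its pre-merge
parts summed, because junction-straddling reads are ambiguous (or fall
into the unannotated gap) before merging.

## Normalization and differential calls

Features with zero counts in every sample are discarded first. Size
factors use the median-of-ratios estimator: with counts `k_ij`,
`s_j = median_i k_ij / (Π_j k_ij)^(1/m)` over the features positive in
all samples. TPM/RPKM are intentionally absent: they require a
transcript length, which is not well defined for repetitive elements and
can itself change between conditions. The implementation is checked
against an independent library implementation of the same estimator in
the test suite.

Differential expression between two groups is computed on normalized
counts: fold-change from group means with a pseudocount of 1
(`log2((mean_b+1)/(mean_a+1))`), p-values from a two-sided Welch t-test
on `log2(normalized+1)`, and a feature is *significant* iff
`|fold| ≥ fold_threshold` (default 2) **and** `p < alpha` (default
0.05). The choice of test was open — the original downstream tooling for
this kind of analysis is a closed-source two-group comparison — and
Welch on log-transformed normalized counts was chosen as the standard
unequal-variance two-group test of that family; the transform choice
(log rather than linear) is recorded in the output. No multiple-testing
correction enters the call, matching the raw-p convention of the dual
threshold; a BH q-value column is emitted for information. Features
constant in both groups get p = 1. Z-scores standardize each feature to
mean 0, sample (ddof = 1) SD 1, after `log2(x+1)` by default; constant
rows map to all-zero by convention.

## Group enrichment

For a subset of loci (e.g. the induced set) against a background (all
expressed loci — chosen over "all annotated" because expression is the
universe the subset is drawn from; the background is an explicit
argument), each repeat group G gets the 2×2 table
(in G / not in G) × (subset / background−subset) and the Pearson χ²
statistic `N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`, df = 1, no continuity
correction. p-values are corrected across groups by Benjamini–Hochberg
(Bonferroni available), and a group is flagged *enriched* only if its
corrected p is below alpha **and** its subset frequency exceeds its
background frequency — over-representation one-sided by construction.
A zero margin leaves the statistic undefined (p = 1, warning); an
expected cell below 5 triggers a warning and, optionally, Fisher's exact
test. Grouping levels: `family` (token after `/` in the class string,
e.g. `ERV1`) and `subgroup` (the terminal-repeat model name from the
name chain, e.g. `MER41D`).

## Synthetic fixtures

The generators are pure functions of a spec and a NumPy `default_rng`
seed; the same seed yields byte-identical artifacts, and every artifact
is accompanied by an exact truth table so recovery tests never re-derive
ground truth.

- `gen_rm_out` plants full proviruses (three or more annotations with
  distinct linkage IDs, 50 bp inter-segment gaps by default, optionally
  a split internal body), solo LTRs, and interrupted LINEs sharing an
  ID. Planted elements must not overlap unless explicitly allowed.
- `gen_sam` places fixed numbers of reads uniformly within features,
  with configurable fractions of junction-spanning reads (anchored on
  the LTR/internal boundary coordinates), deliberately ambiguous reads
  (straddling two features that lie within a read length of each other),
  off-feature background, and multimapper secondary records. Exact
  per-read categories are returned.
- `gen_counts` draws NB(μ, α) counts (variance μ + αμ², dispersion
  α = 0.1 by default, lognormal base means), with per-sample depth
  factors and planted per-feature log2 fold-changes applied to group B.
  Defaults — 2,000 features, 3 vs 3 samples — are the scale at which the
  differential-recovery and normalization properties are demonstrated.

The canned **B-cell activation scenario** wires these together: three
proviruses (including the chromosome 5 element whose merged ID is the
canonical codec fixture), solo LTRs including a deliberately close
non-mergeable pair, interrupted LINEs, eight synthetic genes, and
3 resting vs 3 activated samples in which exactly one provirus is
induced ~20-fold (Poisson read counts around locus means, 15% junction
reads, 2% ambiguous, 5% background, 5% multimappers). It is a
demonstration that the pipeline singles out one strongly induced
provirus — the planted fold, not a numeric target.

What the fixtures deliberately omit: sequencing error, quality/adapter
artifacts, splicing, indels (all reads are single-block `M` CIGARs
except via paired-mate union), cross-mapping between homologous repeat
copies (multimappers are synthetic secondary records, not genuine
sequence ambiguity), and a realistic genome background. Passing tests
therefore validate the bookkeeping and the statistics exactly,
but say nothing about aligner behaviour on real repetitive sequence —
in real data, unique assignment inherits whatever the aligner calls a
primary mapping.

## Numerical and degenerate-input conventions

- Size factors: rows containing any zero are excluded from estimation;
  if no all-positive row exists the estimator raises rather than
  guessing.
- Welch test with zero variance in both groups: p = 1 when means are
  equal (NaN from the t statistic is mapped), p → 0 when they differ.
- Z-scores of constant rows: 0, so heat maps render them as "no signal"
  rather than NaN gaps.
- χ² with a zero margin: NaN statistic, p = 1, warning.
- Merging ties: groups are processed sorted by (reference, start, end);
  group order within a locus follows genomic position.
- The acceptance script derives all sub-seeds from `--seed` and keeps
  them below 2³¹.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
desk scale, chosen to make the statistical checks sharp but quick:
1,000 random fragment tables of up to 200 fragments for the merge
oracle, 1,000-read alignments for counting equivalence, 2,000-feature
NB matrices for normalization/differential properties, 100–200
replicates for null-calibration rates, and the 6-sample scenario for the
end-to-end run. Real studies (tens of millions of reads, millions of
loci genome-wide) exercise the same code paths; counting is streaming
and memory scales with the annotation, not the alignment.

## Known limitations

- The internal-suffix heuristic will miss internal models with
  unconventional names and will not pair an LTR with an internal segment
  more than `max_gap` away; both parameters are exposed but there is no
  curated model-pair table.
- Whether printed locus IDs in the literature span the merged extent or
  only the internal segment cannot be settled from naming alone; the
  merged span is used, and the three canonical provirus IDs reproduce
  exactly under it.
- Unique assignment discards genuinely expressed multi-locus signal;
  totals are underestimates by design, and no EM redistribution of
  multimappers is attempted.
- The χ² test is asymptotic; for small groups use the Fisher fallback.
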