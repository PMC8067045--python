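# Methods

This note documents the statistical procedures, their assumptions, the
numerical conventions, and the design choices behind `budmir`. It states
no empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Study design assumed by the pipeline

The pipeline contrasts two pooled small-RNA libraries — one from
paradormant buds under long days (LD) and one from endodormancy-induced
buds under short days (SD) — against an mRNA expression contrast of the
same two photoperiods (three biological replicates per condition for the
replicate-level analyses). Because each small-RNA condition is a single
pooled library, all small-RNA inference is pooled-count based; there is no
replicate-level count model (no DESeq-style shrinkage), which is a
deliberate scope decision, not an omission.

## Small-RNA annotation

**Alignment contract.** A read is matched to a mature miRNA by a
full-length, ungapped, substitution-only alignment: the shorter sequence
may sit anywhere inside the longer one provided the length difference is
at most 2 nt; terminal overhangs are uncounted. A read annotates when the
minimum mismatch count over such placements is ≤ 2 (configurable). T and U
are equivalent; sequences are uppercased at load. This deterministic
contract replaces a heuristic local aligner: mature-miRNA matching is
effectively global (reads and mature sequences are both ~21 nt), and a
closed-form contract is exactly testable against a brute-force Hamming
oracle.

**Classification.** A read with any focal-species match (default species
code `vvi`) is *known in the focal species*; with only other-species
matches it is *conserved*; otherwise *unannotated*. When a read matches
several references, its family assignment is the union of the families of
all matches at the minimum observed mismatch count (best tier) — family
tallies need a tie rule and this is the least arbitrary one.

**Abundance filter.** Sequences with ≥ 20 combined counts across the two
libraries are *highly abundant*; only annotated, highly abundant
sequences enter the family statistics.

## Differential abundance

* RPM = count / library total × 10⁶; per library, RPM sums to 10⁶
  (enforced as a test invariant).
* Per-sequence differential abundance is log₂(RPM_LD / RPM_SD). Zeros get
  no pseudocount: a sequence present in only one library is flagged
  library-specific (the *specifically abundant* path), and (0, 0) is
  flagged absent. A sequence (or family) is LD/SD-abundant when
  |log₂ fold| ≥ log₂ 2.
* The family fold reported in the family table is a different convention,
  implemented separately: the **signed linear ratio of mean member
  counts** — magnitude = larger mean / smaller mean, sign positive when
  the LD mean is at least the SD mean, rounded half-away-from-zero to one
  decimal. Family means are arithmetic means over member sequences passing
  the ≥ 20-count filter. Both conventions are exposed because the
  family-table values follow the ratio-of-means form (verified
  row-by-row in the acceptance tests), while the per-sequence definition
  is the log₂ form.
* Family significance is a two-sided Wilcoxon rank-sum test comparing the
  per-sequence member counts of a family between the two libraries: exact
  enumeration when the smaller sample has ≤ 8 observations and the pooled
  values are tie-free, otherwise the normal approximation with tie and
  continuity corrections (scipy's implementations behind a single
  dispatch). FDR across families is Benjamini–Hochberg; the original
  analysis names only "FDR", and BH is the field default.
* qPCR: ΔCt = Ct_control − Ct_gene per replicate, ΔΔCt = mean ΔCt_LD −
  mean ΔCt_SD (a log₂-scale fold), two-sided two-sample t-test on the ΔCt
  values; with one replicate per condition the fold is reported and the
  p-value is NaN.

## Target prediction

Sites are scored on the transcript sense strand; the miRNA binds
antiparallel, so miRNA position *i* (1-based from the 5′ end) pairs with
window position L−i+1. Pairing is strict Watson–Crick by default; a
configuration flag counts G:U wobble as a match (off by default, since a
pure-complementarity scan is the stricter and more common convention and
the original parameterisation is not stated).

**Positional rules** (per mismatch vector): ≤ 1 mismatch at positions
2–9, 0 at 10–11, ≤ 4 at 12..L (read as "at most"), and fewer than 3
consecutive mismatches anywhere. Position 1 carries no window constraint
but participates in the run rule. The rules are pure substitution
patterns; gaps/bulges are out of contract.

**Duplex energy.** The energy of a site is the sum of Watson–Crick
nearest-neighbour stacking free energies (37 °C, kcal/mol) over every
dyad of consecutive matched positions; a mismatch simply breaks the helix
(no loop penalty), and a site with no two consecutive matches scores 0.
The stack table is strand-symmetric and embedded in the package. This is
deliberately simpler than a full secondary-structure fold: the filter
actually applied is the **relative** MFE — site energy divided by the
energy of the perfectly complementary site, both computed on the site
window itself — and that ratio is robust to the simplification. A
perfectly complementary site always has relative MFE 1.0; the pass
threshold is ≥ 0.70 (boundary inclusive). Wobble positions, when enabled,
are treated as matches with the Watson–Crick stack value of the miRNA
dinucleotide — a coarse approximation that preserves the monotonicity
property (enabling wobble never removes a passing site).

The scanner evaluates every offset of every miRNA on every transcript; a
vectorised mismatch-count prefilter discards windows that exceed the
maximum mismatch load the windows can admit (1 + 1 + 0 + 4), and the
surviving windows get the full per-position evaluation. Equivalence with
a naive every-offset scanner is an acceptance-level test.

## Inverse-expression integration

DEG intake: *not expressed* if FPKM < 1 in both phases; *up/down in SD*
if adjusted p ≤ 0.05 and |log₂FC| ≥ 1 (the "2-fold" reading of the fold
threshold, configurable); otherwise *not DE*. An inverse pair requires a
differential miRNA, a passing site, and the target's DE direction
opposite in the condition of miRNA abundance: SD-abundant miRNA ↔ gene
down in SD, LD-abundant miRNA ↔ gene up in SD. The LD side mirrors the SD
rule symmetrically. Pairs are deduplicated on (miRNA, gene);
transcript→gene mapping is an optional two-column table, identity when
absent. Because all members of a miRNA family share near-identical
sequences, they typically co-target a gene; planted-truth comparisons in
the tests are therefore made at the (family, gene) level.

## Enrichment

* **Hypergeometric over-representation**: one-sided upper-tail p for the
  overlap of the query (e.g. downregulated genes) with each set, both
  restricted to the expressed-gene background; BH across sets. The
  original analysis used a tool-specific simulation-based multiple-testing
  threshold (set-counts correction); BH is used here as the reproducible
  standard replacement.
* **GSEA**: genes are ranked by signal-to-noise,
  (μ₁ − μ₂)/(σ₁ + σ₂), with each σ floored at max(0.2·|μ|, 0.2) — the
  floor guards near-constant genes on count data. The enrichment score is
  the signed extremum of the weighted Kolmogorov–Smirnov running sum
  (weight 1 by default; weight 0 gives the analytic unweighted case used
  in tests). With three replicates per condition a phenotype permutation
  has only 20 distinct relabelings, so the default null is **gene-set
  permutation** (random same-size sets, 1000 draws, add-one-corrected
  nominal p); phenotype permutation is available behind a flag. Sets with
  fewer than 7 members present are excluded. FDR is BH over nominal
  p-values. Significance convention: nominal p < 0.05 and q < 0.25;
  positive ES = concentrated among genes higher in the group passed as
  `positive_group` (SD in the dormancy analysis).

## Network assembly

PPI edges are kept at confidence strictly > 700 (0–1000 integer scale)
and deduplicated as undirected pairs. The network is the hub plus one
hop: its transcriptional targets (hub's gene set), its direct protein
interactors, protein–protein edges among included nodes, and
miRNA→target edges whose target is already included. Directed edge types:
`tf_target`, `mirna_target`; undirected: `tf_protein`,
`protein_protein`. Nodes carry log₂FC and DE status from the DEG table;
nodes without a record are kept and marked not differentially expressed.
Exports (GraphML, SIF, TSV) are canonical-sorted, so assembly is
independent of input row order, and GraphML round-trips exactly.

## Synthetic data: what it emulates and what it does not

The generator plants every structure the pipeline is supposed to find:

* miRNA families (numeric stems, members within one substitution of a
  family base; one family present in two species, one family present only
  in the non-focal species);
* two libraries with negative-binomial counts (variance μ + α μ²,
  dispersion α = 0.05 by default) around per-member means; planted
  differential families have a between-library mean ratio equal to
  `planted_fold` (default 4, chosen ≥ 2 so the ≥ 2-fold rule can recover
  them); the table also carries 1–2-mismatch variant reads, 3-mismatch
  near-misses, and random background;
* transcripts with planted sites: the reverse complement of a miRNA with
  substitutions at exactly the stated miRNA positions, chosen to mismatch
  under both strict and wobble pairing, covering pass and fail cases of
  every positional rule;
* a DEG table whose planted inverse-pair genes oppose their miRNA's
  planted direction, plus null genes, sub-FPKM genes, and extra DE genes;
* one pathway planted inside the downregulated genes, random pathways,
  PPI scores spanning the 700 threshold (both 700 and 701 occur), and a
  hub with targets and interactors.

Default sizes (12 families × 3 members, 4 differential, 30 transcripts of
500 nt, ~190 genes, 10⁵ reads per library) keep every test desk-scale
while leaving enough members per family for rank statistics to be
meaningful. What the generator does **not** emulate: sequencing error,
adapter artefacts, FASTQ-level structure, genome alignment ambiguity,
hairpin precursors, and the annotation-version drift of real references.
Passing tests therefore demonstrate correctness of the analysis rules and
recoverability of planted effects at realistic overdispersion — not
end-to-end fidelity to any particular sequenced dataset, whose headline
tallies depend on raw data and annotation versions.

## Numerical conventions and edge cases

* Reported folds: half-away-from-zero rounding to one decimal; full
  precision kept internally.
* No pseudocounts anywhere; zeros route to explicit flags.
* Wilcoxon: exact only when tie-free and min(n) ≤ 8; add-one correction
  keeps permutation p-values in [1/(B+1), 1].
* Scanner ties: output sorted by (miRNA, transcript, start); overlapping
  passing sites are all reported.
* RNG: `numpy.random.default_rng` seeded per artifact with independent
  substreams, so generators are order-independent and byte-reproducible.
* Degenerate inputs raise early with the offending value named (bad
  nucleotide, missing column, non-numeric PPI score with line number,
  hub absent from all inputs, site plan referencing unknown ids).

## Known limitations

* The duplex energy model has no loop penalties, dangling ends, or wobble
  thermodynamics; absolute energies are not comparable to a full folding
  program, only the relative-MFE filter is meaningful.
* The signal-to-noise floor means GSEA scores on raw counts are
  scale-sensitive for weakly expressed genes; counts are used as-is, as
  in the replicate-level enrichment the pipeline mirrors.
* Family-level Wilcoxon power is limited when families have few member
  sequences (exact p cannot fall below 2/C(n₁+n₂, n₁)); with the default
  synthetic family sizes the fold rule, not the test, drives recovery.
* The tool-specific set-counts multiple-testing procedure is replaced by
  BH throughout; adjusted significance calls can differ from analyses
  using that procedure.
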