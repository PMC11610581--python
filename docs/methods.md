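# Methods

This note documents the models behind `tandemdup`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where more than one reading was defensible.

## The problem

Tandemly expanded segmental duplications — gene families like *TBC1D3*
carried in variable-copy-number arrays — break most standard pipelines:
copy number differs between haplotypes, paralogs differ from each other by
little more than alleles do, and assemblies over such arrays are prone to
collapse.  The package provides the statistics such a locus needs: a
permutation test for the association between duplication units and
chromosomal rearrangement breakpoints, structural comparison of assembled
haplotypes, decomposition of gene copies into population-level paralog
groups, paralog-specific assignment of full-length transcript reads, and
read-depth copy-number estimation with collapse QC.

## Synthetic-data generator

The generator (`tandemdup.simulate`) produces every input downstream stages
consume, with full ground truth.  It emulates:

- **Clustered tandem expansions.** Each haplotype is flank + per-cluster
  tandem array + flank.  The default configuration mirrors the structure of
  the human locus the package targets: two clusters with per-haplotype
  copy-number ranges 1–14 and 2–14, a duplication unit of 11 kbp, and
  short spacers.
- **Allelic vs paralogous divergence.** Substitutions are independent and
  uniform (Jukes–Cantor-like; no indels within copies).  Divergence is
  realised on an explicit genealogy: a root unit sequence per cluster, one
  ancestor per truth group at branch rate (D − a)/2 per site, and each
  realised copy at branch rate a/2 from its group ancestor, where
  a = `allelic_rate` (default 15.3 SNVs/10 kbp, the published allelic SNV
  rate inside segmental duplications) and D = `paralog_divergence`
  (default 60/10 kbp).  Expected pairwise distance is therefore a within a
  group and ≈ D between groups, which makes binomial oracles for the tests
  exact (double-hit corrections at these rates are < 0.3 SNV/10 kbp and are
  ignored).
- **Structural classes.** Per cluster, a haplotype draws a layout template
  (copy count, orientations, truth-group order) from a finite pool with
  configured probabilities.  Haplotypes share a *structure class* iff they
  drew the same template everywhere, so the expected structural
  heterozygosity has the closed form 1 − Π_c Σ_i p_ci², which the tests
  check.  `truth_pair_alignments` emits exact block alignments between two
  haplotypes from the longest common prefix/suffix of their segment lists —
  the noise-free stand-in for an aligner.
- **Rearranged orthologs.** Inversions, translocations and fissions applied
  to a base chromosome, with breakpoints placed uniformly, at annotated
  element boundaries, or explicitly; the emitted truth alignments are the
  exact block alignments the rearrangement implies, and truth breakpoints
  are the segment boundaries (chromosome ends excluded).
- **Reads.** Transcript reads span a full gene copy (full-length cDNA is
  full-length by definition), with multinomial group sampling by expression
  weight, substitution errors at the configured rate, and a uniform quality
  string encoding the realised accuracy — so a read's mean error probability
  equals its true error fraction.  WGS reads have uniform starts at a
  configured mean depth per haplotype.

It does **not** emulate: mobile elements or other repeat content, realistic
platform error profiles (indels, homopolymer errors, quality-score
miscalibration), GC coverage bias, gene conversion between paralogs
(homogenisation), phasing errors, or indel/SV polymorphism inside copies.
Consequently, passing tests demonstrate the statistics are implemented
correctly and recover truth under the stated generative model — not that
any particular real locus satisfies that model.

## Breakpoint permutation test

Synteny blocks are maximal chains of colinear, orientation-consistent
alignment records: records with target span ≥ `min_subblock_size` (50 kbp)
are sorted by target start and chained while orientation matches, order is
preserved on both genomes (reversed on the query for inverted chains), and
gaps are ≤ `max_gap` (200 kbp) on both; chains spanning < `min_block_size`
(1 Mbp) on either genome are dropped, and remaining blocks are made
non-overlapping on the target (larger blocks win).  Only block edges count
as breakpoints; interior sub-block structure is deliberately not mined for
extra breaks.  Element-to-break distance is 0 when a break falls inside the
element, else the gap to the nearer edge; the observed statistic is the
median pooled across chromosomes.  The null redraws, per chromosome, as
many blocks as there are true elements, each of `block_len` (default: mean
true element length), uniformly over the chromosome or uniformly over
positions fully inside a segmental-duplication track; sampled blocks may
overlap anything — no rejection rule.  p = (1 + #{null ≤ observed})/(N+1):
the add-one estimator is never zero, and ties count against the observed
value.  Type-I error of this construction is calibrated by simulation in
the test suite (200 null datasets, N = 500, α = 0.05).

## Structural equivalence

Two haplotypes are equivalent when one colinear chain (same chaining rule,
`max_gap` default 1 kbp, matching the up-to-1-kbp-insertion tolerance used
with assembly-to-assembly alignment) covers ≥ 90% of **both** lengths;
coverage never double-counts overlapping records.  Requiring both sides
keeps the relation symmetric, which the all-vs-all procedure implicitly
assumes; the relation is deliberately not transitively closed.  The
distinct fraction counts haplotypes with no equivalent partner; structural
heterozygosity counts samples whose two haplotypes are not equivalent.
Copy-number tables report per-haplotype per-cluster counts, per-sample
diplotype totals, and the theoretical diplotype range
(2 × Σ cluster minima, 2 × Σ cluster maxima).

## Paralog grouping

Distances are mismatching non-gap columns per non-gap aligned column,
scaled to SNVs per 10 kbp.  The tree is neighbor joining (scikit-bio)
rooted on the outgroup's pendant edge — a deliberate substitution for
maximum-likelihood inference, since the grouping criterion uses only the
distance matrix and the clade structure, never branch-length likelihoods.
Groups are emitted root-down: a clade becomes a group as soon as its
intra-clade variation is ≤ `multiplier × allelic_rate`
(1.5 × 15.3 = 22.95 SNVs/10 kbp) — so emitted clades are maximal — and
clades below `min_members` (10) are reported as unassigned, never silently
dropped.

**Intra-clade variation is the MEAN pairwise distance by default.**  The
ceiling is stated against the allelic-variation rate, itself an average, so
mean-to-mean is the consistent comparison; it is also robust to single
hypermutated copies, which real arrays contain (gene conversion, assembly
error) and which the simulator reproduces as the upper tail of the
per-copy branch process.  Under a max-pairwise reading one such copy
shatters an otherwise tight clade, and exact group recovery becomes
impossible in a small but persistent fraction of simulations; the
max-pairwise reading remains available as `GroupingParams(statistic="max")`
for users who want the conservative ceiling.

Windowed diversity computes π per window as the mean over sequence pairs of
mismatching/comparable columns (pairs with zero comparable columns flag the
window); windows are non-overlapping by default and percentiles use the
fraction of strictly smaller windows plus half the ties.

## Transcript assignment

Reads shorter than 1000 bp or with mean per-base accuracy below 99.9% are
dropped; accuracy is the mean of per-base *error probabilities* converted
back from Phred (not the mean Phred), so a uniformly Q30 read sits exactly
on the boundary and is kept.  Alignment scores use a declared scheme —
match +1, mismatch −2, gap open −2, gap extend −1, computed by rescoring
an edlib alignment path — so the margin rule is exactly reproducible;
real-mode PAF inputs with AS tags use those scores instead.  Scores within
a group collapse to the group best; a read is assigned iff the top group
beats the best other group by ≥ 10 score units (≈ 4 distinguishing
substitutions), reads hitting a single group are assigned outright
(discarding uniquely mapping reads would be perverse), and anything else is
ambiguous and excluded from expression fractions.  Identity is
matches / alignment-block length, gaps counted against it.  Normalised
expression divides a group's read count by the population-wide median of
its per-haplotype copy number (a per-sample variant is a flag away);
groups with zero median are flagged rather than divided by zero.

The terminal-deletion characterisation takes a complete reference CDS
(ending in a stop) and an alternative sequence carrying one contiguous
deletion, locates the deletion (requiring ≥ 6 bp of reference 3' context to
re-match, so a truncation is not mistaken for a deletion; the deletion may
also be supplied explicitly), and reports: frameshift iff length mod 3 ≠ 0;
residues lost = reference codons from the first affected codon through the
last sense codon; and for frameshifts the extension length = codons
translated in the shifted frame up to the first downstream stop — the novel
C terminus.  A 43 bp deletion starting 51 bp before the stop with the first
shifted-frame stop 123 bp downstream yields 17 residues lost and a
41-residue extension; tests verify this and 100 random fixtures against an
independent translate-and-compare oracle.

## Depth, copy number, and QC

Copy number comes from exact canonical 32-mer depth: each reference
position's depth is the count of read k-mers identical to the canonical
k-mer starting there, the haploid-equivalent baseline is the median window
depth over declared single-copy control intervals divided by the control
ploidy, and a region's CN is its mean positional depth over the baseline
(a diploid-total estimate).  The read-length correction (a read of length
R contributes R − k + 1 k-mers) cancels between region and baseline.  Exact
matching replaces the mismatch tolerance of k-mer CN pipelines built for
real platform error; depth experiments therefore use error-free reads and
identical copies, which is the role that mismatch tolerance plays on real
data.  A GC-bias correction hook is intentionally absent — the generator
produces unbiased coverage.

Collapse detection works on origin-true pileups (no re-mapping in
simulation mode; real mode accepts a pileup TSV).  A position is a
candidate when its second most frequent base is seen ≥ 2 times and above
1% of depth; candidates within 500 bp of each other cluster, and clusters
of ≥ 5 candidates are flagged, annotated with whether mean depth exceeds
1.5× the genome median.  These numbers operationalise a qualitative
criterion ("a noticeable increase in secondary base frequency over
particular stretches, usually with a depth spike") and are declared
defaults, not published constants; the minimum-count-of-2 guard is what
keeps 0.1% random base error from producing candidate storms at 20–30×.
Gaps are maximal zero-coverage runs ≥ 100 bp.

## Numerical and interface choices

- Coordinates are 0-based half-open everywhere; strand is metadata on
  forward-strand coordinates (PAF semantics).  All parsers fail loudly with
  line numbers; round-trip write∘read is the identity on mandatory fields.
- Same seed + config ⇒ byte-identical generator output; every stochastic
  routine takes an explicit seed and all CLI commands share a `--seed`.
- PAF score/NM tags are honoured when present, else derived
  (score = matches − 2 × mismatches; mismatches = aln_len − matches).
- Rearrangement simulation returns a *list* of chromosomes so fissions have
  a faithful representation; all other rearrangements return one record.
- Group names default to the lexicographically smallest member id; an
  external name map translates them to reference paralog names, since the
  correspondence to reference annotations is input, not inference.

## Problem sizes used in tests and the acceptance script

Test and acceptance workloads are scaled to exercise each statistic at the
sample sizes its tolerance assumes: 200 permutation datasets × 500
permutations for type-I calibration; 500 randomized chaining cases vs the
exhaustive oracle; 200 simulated samples for the heterozygosity closed
form; 20 grouping replicates of 3 × 12 copies of 11 kbp units; 50
copy-number replicates per truth value at 30× with a 40 kbp control and a
6 kbp unit (chosen so sampling noise sits several standard deviations
inside the ±0.5 acceptance band); 20 collapse-QC seeds; and a 20 × 50 kbp
alignment for the π brute-force comparison.  The full suite runs in a few
minutes on one CPU.

## Known limitations

- The structural-equivalence chain search is sequential over
  target-sorted records; adversarial record sets interleaving many chains
  could hide a better chain, but aligner output and the generator's truth
  alignments do not produce such sets.
- NJ topology, not branch support, drives grouping; no bootstrap is
  computed.
- The deletion characteriser handles exactly one contiguous deletion and
  refuses multi-indel or start-codon-spanning cases rather than guessing.
- Read-depth CN assumes unbiased coverage and exact k-mer identity;
  divergent paralogs on real data need the mismatch-tolerant matching of
  dedicated CN pipelines.
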