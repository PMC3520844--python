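# Methods

## SSU rRNA read pipeline

The pipeline treats unassembled reads as anonymous fragments that may
contain partial SSU rRNA genes. Stages, in order:

1. **Quality filtering.** A read is kept iff length ≥ `min_length`
   (default 200 nt), ambiguous-base fraction ≤ `max_ambiguity_frac`
   (default 0.02) and homopolymer fraction ≤ `max_homopolymer_frac`
   (default 0.02). Boundary semantics are deliberate and asserted in
   tests: "shorter than 200" and "more than 2%" are strict, so a 200-nt
   read and a read with exactly 2% ambiguities both pass. The ambiguity
   fraction counts all non-ACGT IUPAC codes, not just N; the homopolymer
   fraction is the share of bases inside single-nucleotide runs of length
   ≥ `homopolymer_min_run` (default 6). Long homopolymers are the
   characteristic pyrosequencing error mode; the run-length definition is
   a package choice (the metric has no universal definition) and is
   configurable.

2. **Dereplication** (identity 1.00, word size 8). Following cd-hit-est
   semantics, a shorter read identical over its whole length to a longer
   one (exact containment) collapses into it. Implemented as exact
   substring matching behind a k-mer index; the longest read represents
   each group, ties broken lexicographically by read id.

3. **Greedy clustering** (identity 0.98, word size 8). Sequences are
   processed longest-first; each joins the first existing cluster whose
   reference shares ≥ 1 exact 8-mer and aligns at identity ≥ 0.98, where
   identity is matches of the best local alignment divided by the shorter
   sequence's length; otherwise it founds a cluster. References are
   therefore founders and longest by construction. For sequences ≥ 100 nt
   a word-counting prescreen skips alignments that cannot reach the
   threshold: a pair at identity ≥ t over shorter length L has at most
   ⌊(1−t)·L⌋ unmatched query bases, each destroying at most 8 distinct
   query 8-mers, so candidates sharing fewer distinct 8-mers than that
   bound are rejected without alignment (one extra word of slack absorbs
   boundary effects). Below 100 nt every word-sharing candidate is
   aligned, so the brute-force oracle-equivalence suite (≤ 60 nt)
   exercises the unmodified decision rule.

4. **Classification.** Each cluster reference is aligned (both strands;
   forward wins ties) against every reference taxon; the best hit
   maximises the composite score (mean of percent identity and percent
   query coverage), with ties broken by higher identity then smallest
   taxon id. The hit's six-rank path is assigned when the composite is
   ≥ 93.0 (inclusive). Coverage is query-relative (aligned query span /
   query length): the sensible choice when short reads are matched against
   full-length genes, and the one that makes a fully contained perfect
   read score 100. Identity is matches / alignment columns, internal gaps
   counted as columns.

   *Performance device:* with large reference sets, candidates are first
   ranked by banded edit distance (edlib, infix mode, both strands) and
   only those within a margin (max(4, ⌈0.05·read length⌉)) of the best are
   re-scored with the exact local aligner. This never changes which exact
   scores are compared, only how many candidates are exactly scored; with
   ≤ 4 references the prescreen is bypassed entirely.

5. **Propagation and profiling.** Members and dereplication replicates
   inherit their reference's path and status, conserving read counts.
   Profiles count assigned reads per label at a rank; percentages are
   rounded half-up to 2 decimals (1 decimal for GH families, 3 for
   ORF-prevalence figures), matching the precision such numbers are
   conventionally reported at. Unrounded percentages always sum to 100;
   rounded ones can drift by up to 0.005·(number of labels) per cent.

Alignment scoring is Smith–Waterman with affine gaps: match +1, mismatch
−2, gap open −5, gap extend −2 (megablast-like). The implementation uses
Biopython's `PairwiseAligner`; the test suite checks it against an
independent pure-Python Gotoh DP on small instances.

## Functional profiling

A KEGG or COG hit is valid iff E-value < 1e-5 (strict: exactly 1e-5
fails). CAZy hits additionally need homology ≥ 50% (inclusive), homology
being read as the percent identity of the hit. One best label is kept per
(ORF, database): lowest E-value, ties to the lexicographically smallest
label (deterministic; any rule would do). KO percentages are normalised to
total valid KO assignments; the KO universe size (default 20,590 entries)
is carried as metadata so newer hierarchies can be swapped in. GH-family
percentages are normalised to total CAZy-like proteins by default, with a
configurable denominator. Prevalence figures ("x% of all ORFs") use the
ORF-catalogue size. "Non-hypothetical" ORFs are those with database
matches of known function — i.e. the functional category alone, excluding
conserved hypotheticals.

## Comparative clustering

Profiles are aligned on the union of features (absent = 0) before
comparison. Distance is 1 − r with r the Pearson product-moment
coefficient, so anti-correlated profiles are maximally distant (d = 2);
this choice over 1 − |r| or (1−r)/2 is a package decision. Correlation
with a constant vector is undefined and raises — it is never silently 0 or
NaN. The distance matrix (validated symmetric, hollow) is clustered by
UPGMA by default (single/complete available); a node merging at distance d
sits at ultrametric height d/2, branch lengths are height differences, and
the tree is exported as newick. Heat-map export orders profile rows by
tree tip order and changes no values.

## Sequence statistics

N50 is the largest length L such that contigs ≥ L sum to at least half the
total assembly length (cumulative-sum-from-longest; always an element of
the input). GC content pools G+C over unambiguous bases across all
sequences; ambiguity codes are excluded from the denominator, and an
all-ambiguous sequence is skipped with a warning. "Longer than" cut-offs
are strict.

## Enzyme activity

Beer–Lambert converts absorbance to pNP concentration, c = A/(ε·l), with
ε = 15,200 M⁻¹·cm⁻¹ by default (the measured coefficient for pNP in
alkaline glycine buffer). The path length has no default asserted as a
measured value: microplate optical paths depend on fill volume, so it is
an explicit parameter (1 cm when unstated). The slope of the kinetics
series comes from ordinary least squares over the full series; an optional
initial-linear-window mode fits the largest prefix (≥ 3 points) with
r² ≥ 0.98, guarding against substrate depletion in incubations spanning
minutes to many hours. Specific activity is slope/(ε·l) · volume · 1e6 /
protein-mass, in µmol·min⁻¹·g⁻¹. A decreasing blank-corrected signal
yields activity 0 with a `clamped` flag rather than a negative rate. Fold
differences divide two activities; a zero denominator (below detection
limit) raises rather than returning infinity.

## Synthetic data: what it emulates, and what it does not

`generate_reference` grows a taxonomy tree (6 ranks, domain→genus; each
new taxon reuses an existing group with probability 0.6 per rank, genus
always new) and evolves sequences along it with per-rank substitution
doses (phylum 0.06, class 0.03, order 0.02, family 0.02, genus 0.04).
The doses were chosen so that (a) two distinct genera differ by ≥ ~8%,
keeping best-local-alignment identity below 0.95 — distinct taxa cannot be
conflated by the 0.98 clustering or win each other's reads — while (b) the
deepest split stays under ~25% divergence, so local alignments remain
gene-length. (With substantially larger doses the best local alignment
collapses onto short perfect repeats and "identity" stops being
informative — an instructive failure mode of identity-over-alignment
metrics.) Sequences are 1,200–1,600 nt, ACGT only.

`simulate_reads` draws taxa multinomially by weight, fragment lengths
normally (defaults: mean 367 nt, sd 60 nt, floor 30 nt), start positions
uniformly, then applies homopolymer indels (only inside runs ≥ 3 nt, one
expansion/contraction per affected run — the pyrosequencing error mode),
substitutions, and ambiguous-base replacement, each at per-base rates.
Default rates (substitution 0.005, ambiguity 0.002, homopolymer 0.005)
are plausible for filtered long-read pyrosequencing data but are free
parameters, not measured values. All randomness flows from one
`numpy.random.default_rng(seed)`, so outputs are byte-identical across
runs.

Not emulated: flowgram-level noise, quality scores, chimeras, conserved/
variable region structure within the gene, compositional bias, and
database incompleteness (every read's taxon is in the reference by
construction). Passing recovery tests therefore demonstrates correctness
of the pipeline's bookkeeping and decision rules under a clean error
model — not classification accuracy on real communities, where reference
gaps and chimeras dominate.

`simulate_annotations` assigns ORF categories multinomially, labels only
functional ORFs, and draws E-values from log-uniform mixtures on either
side of the 1e-5 cut-off (pass: 10^U(−30,−5.5); fail: 10^U(−5,−1)) and
homologies uniformly on either side of 50%, recording exactly which rows
survive — so filter recovery can be asserted as exact equality.
`simulate_kinetics` inverts the specific-activity formula to produce a
linear absorbance series plus Gaussian noise.

## Problem sizes and numerical choices

The recovery suites use 5,000 reads over 10 taxa (error-free and at 1%
substitutions), sizes at which per-phylum percentages are estimated to
well under one percentage point of sampling noise; oracle-equivalence
suites use 200 random clustering instances (≤ 20 sequences of 25–60 nt)
and 100 random ≤ 6-sample distance matrices, where brute-force
reimplementation is cheap and exact. Percentage rounding is half-up
(`decimal`-based) at the reported precision. Pearson r is clipped to
[−1, 1] before forming distances to absorb last-ulp float drift; distance
symmetry is enforced by construction and validated to 1e-12. Greedy-order
ties (equal length) break lexicographically by id everywhere, making every
clustering deterministic.

## Known limitations

- The greedy clustering is order-dependent by design (longest first, as in
  cd-hit); it is a replication of that heuristic, not an optimal
  clustering.
- The word-count prescreen bound assumes unmatched bases, not long
  internal insertions in the longer sequence; alignments with many gap
  opens could in principle be prescreened away. At the identity threshold
  (0.98) such alignments are essentially excluded by the gap penalties.
- The edlib classification prescreen ranks by unit-cost edit distance,
  which is not the affine-gap score; the margin makes candidate loss
  unlikely but not impossible for pathological reference sets.
- `AbundanceProfile` percentages are denominators-of-record, not
  compositional statistics; no rarefaction or variance estimates are
  provided.
- Specific activity assumes the initial rate is linear in time and that
  product absorbs independently of matrix effects; no Michaelis–Menten
  fitting is attempted.
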