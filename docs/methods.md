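# Methods

This note records the models and procedures behind `readtriage`, the
parameters that matter, the design choices made where the design was open,
and the limits of what the simulation-based tests establish.

## The triage model

The pipeline assumes paired-end short reads from a resequencing study of
closely related strains, mapped upstream against a *primary* reference; its
input is the set of pairs that failed to map (both mates unmapped) or
half-mapped (one mate anchored). Unmappedness is attributed, in order, to:

1. sequencing artifacts (adapter read-through, low base quality, short
   post-trimming length);
2. genomic variation — a structural breakpoint near the anchored mate
   explains the unmapped mate;
3. sequence present in an *alternative* assembly but not the primary
   reference, subdivided by a coverage annotation into regions the primary
   assembly is missing versus regions private to the second strain behind
   the alternative assembly;
4. Y-chromosomal sequence (the reference assemblies are female-derived);
5. contamination (non-animal genomes only, to avoid discarding host
   material that is merely homologous);
6. a remainder of candidate novel sequence, which feeds the similarity and
   assembly stages.

Categories are disjoint and exhaustive, so per-sample tallies conserve the
input count; this conservation is asserted throughout the test suite.

## Quality control

* **Adapter clipping** removes the longest read suffix that exactly matches
  an adapter prefix over at least `min_adapter_overlap` bases (default 10).
  The default is deliberately conservative: at 5 bases a random suffix
  matches ~1/1000 reads, which measurably corrupts downstream geometry (for
  a 100 bp read the false-clip probability at 10 bases is ~1e-6). A
  `mismatches_per_10bp` parameter can relax exactness; clipping repeats to a
  fixed point so the operation is idempotent.
* **Quality trimming** scans 5'→3' and cuts at the first position opening a
  window (default 25 nt, shrinking at the read end) whose mean phred score
  falls below the threshold (default 25). Because truncation shortens the
  terminal windows, the scan is re-applied until stable; this makes the
  whole QC stage idempotent, which the suite checks, and the result is
  verified base-exactly against a brute-force all-windows oracle.
* **Length rule**: both mates must stay *strictly* longer than half the
  expected read length; a mate at exactly 50% fails. Raising the quality
  threshold can only shrink reads, so the passing count is monotone
  non-increasing in the threshold (property-tested).
* **Breakpoint rescue**: the unmapped mate of a half-mapped pair is split
  into two halves; each half is searched on both strands within the anchor
  padded by `search_radius` (default 2× the fragment mean), allowing
  `rescue_max_mismatch_per_half` mismatches (default 2 — one mismatch per
  ~25 bp of half, sized to the error regime where a 1-mismatch budget
  already loses ~17% of genuine breakpoint mates at 1% sequencing error,
  while a chance placement of a 50 bp half at ≤2 mismatches is effectively
  impossible). Two placements classify as deletion (same strand, positive
  gap), insertion (same strand, overlapping placements), tandem duplication
  (downstream half placing upstream) or inversion (opposite strands); a
  contiguous placement means no breakpoint and the pair continues in the
  pipeline. This is a deliberately simplified anchored split search: it
  detects breakpoints centred in the unmapped mate, which is the planted
  geometry, and makes no claim of equivalence with a full split-read
  caller.

## The in-pair mapper

A complete canonical k-mer index (seed length 17) over each database
anchors candidate placements; ungapped extension counts mismatches. A pair
"maps in-pair" when both mates place on one sequence in FR orientation,
each within `max_mismatch` (default 5 per 100 bp mate), at an observed
insert within `insert_tolerance` (default 4× the library's fragment SD) of
the fragment mean. Ties break by total mismatches, then (sequence id,
leftmost coordinate), making tallies bit-reproducible. Seeds are taken at
stride k with a full-offset fallback when no placement is found, so a read
with scattered errors still anchors. The 5-mismatch budget is sized to the
data model: strain divergence of ~1 substitution/kb plus 1% sequencing
error leaves essentially no genuine placement above it (P[>5 events in
100 bp] ≈ 5e-4 at the noisiest setting), while a spurious 100 bp placement
at ≤5 mismatches in desk-scale random references does not occur. The mapper
is verified against exhaustive placement enumeration (every offset, both
strands) on 1000 mixed pairs.

Classification queries the alternative index, the Y index, and — only when
both miss — the contaminant index; host-derived databases take precedence
over contaminants because the converse would discard host material that
happens to share sequence with a contaminant. The coverage test uses the
placement midpoint of either mate (robust to reads straddling annotation
edges); `alt_missing_region` wins when at least one midpoint is covered.

## Similarity between samples

The unit is the read pair; blocks may come from either mate but never span
the mate boundary. Block length is ⌊0.4 × read length⌋ — 34 bp for the 85 bp
reads of the motivating study, 40 bp at the simulator's 100 bp default.
Membership is tested against the target sample's *pooled* canonical k-mer
set (the two blocks need not come from one target read), k-mers containing
N are skipped, and greedy left-to-right selection with a jump of k after
each acceptance decides existence — provably equivalent to exhaustive
search for fixed-length blocks, and oracle-tested. Samples are screened
before comparison: median read length below 2k, fewer than `min_pairs`
pairs (default 30 000, the screen used at the motivating study's scale;
desk-scale runs pass a value matched to their sample size), or a GC-content
shift above 2 percentage points between all reads and the retained set (a
known assembly-quality hazard) exclude a sample with a warning.

Clustering treats matrix rows as feature vectors (Euclidean distance,
average linkage, ties broken by sample-name order). Tree recovery is scored
as unrooted Robinson–Foulds distance, normalized by the total non-trivial
bipartition count of both trees.

## Contig classification

Substrains collapse into strain groups by the name before the slash and/or
a genetic distance strictly below 0.02, transitively closed. Contigs of at
least 500 bp (inclusive; a flag switches to strictly-greater) are compared
across groups with a local aligner (match +1, mismatch −2, linear gap −3):
pairs within the exact-DP budget get the true Smith–Waterman optimum (a
numba dynamic program, score-verified against an independent implementation
on hundreds of pairs), larger pairs are first windowed around the densest
shared-seed diagonal. A 12-mer shared-seed prefilter skips pairs that
cannot reach the match threshold (a >100-column alignment at >80% identity
contains an exact 12-mer with overwhelming probability). "Matching
sequence" counts aligned columns and "overall similarity" is identical over
aligned columns of the best local hit — both strict inequalities, both
switchable. Commonness is symmetric by construction and never conferred
within a strain group; raising either threshold can only move contigs
toward strain-specific (property-tested over a 3×3 grid).

Common contigs cluster greedily longest-first: a contig joins the first
cluster whose representative aligns at ≥ 0.90 identity (a conventional
clustering default) over ≥ 80% of the shorter sequence. Reciprocal-overlap
screening against an archive requires a single local hit covering ≥ 66% of
*both* sequences. N50 is the classical weighted median of contig sizes.

**Assembly distance.** The score of the motivating study's distance
clustering is not fully specified there, so the package defines a surrogate
and names it as such in output metadata: 1 − (bp of A covered by qualifying
hits onto B + bp of B covered onto A)/(total bp of A + B), i.e. the
size-weighted mean of the two aligned fractions. The weighting matters: an
unweighted mean lets a small assembly dominate the score (its own aligned
fraction is large against every relative), which misplaces size outliers in
the clustering. Identical assemblies score 0, disjoint ones 1, and the
measure is symmetric.

## The synthetic study generator

The generator defines the study conditions; all defaults are fixed here.

* **Genomes.** Ancestor/alternative assembly 500 kb of uniform random
  sequence. Reference-gap blocks (8% of the genome in ~10 blocks) and
  strain-divergent blocks (4% in ~8 blocks) are excised from the primary
  reference, separated by margins of 3 fragment means so no block geometry
  interacts; the coverage BED is the complement of the strain-divergent
  blocks. Three 10 kb Y contigs and six 25 kb contaminant genomes (with a
  small genus taxonomy) are independent random sequence; 20% of the first Y
  contig is a pseudoautosomal copy of covered shared sequence, planting the
  joint alternative+Y category.
* **Phylogeny.** Balanced random bipartition topology with exponential
  branch lengths (floor 0.05), leaves `strain_1..n`. The balance is a
  modelling choice with a statistical reason: under deep caterpillar
  topologies a leaf accumulates one clade-shared sequence component per
  ancestor edge, so per-sample totals diverge and any fraction-normalized
  similarity mis-orders partners at different clade depths regardless of
  rates. Balanced shapes equalize path depths — and are also the realistic
  regime for laboratory-strain panels, where substrains radiate from a few
  founder stocks.
* **Evolution.** Substitutions at 3e-4 per base per unit branch length
  (root-to-leaf divergence ≈ 1 substitution/kb, the magnitude seen between
  inbred strains and their reference). Novel inserted segments
  (600–2500 bp, uniform) arise as Poisson events: mean 8 per internal
  branch and 3 per terminal branch, so every clade carries unambiguous
  novel signal (an empty internal edge would make its split unrecoverable
  in principle) while private material stays small relative to clade-shared
  material, the regime the motivating study reports (up to ~90% cross-sample
  similarity among related strains). Inserts are novel random sequence —
  classification truth stays unambiguous — with a flag to copy mutated
  reference segments instead for homology stress tests; an insert is never
  placed inside another, so every copy is contiguous and registry
  coordinates are exact.
* **Reads.** Each strain emits 20 000 *unmapped* pairs: fragments are
  sampled uniformly over the strain genome and resampled while wholly
  inside primary-shared sequence (those would have mapped upstream).
  Fragment length ~ Normal(500, 60) truncated to ±4 SD — exactly the
  mapper's insert tolerance, so sampling never violates the in-pair test.
  Spike-ins per pair: 40% quality artifacts (every base phred 2–20, below
  the QC threshold by construction; good bases are phred 30–40, so the
  threshold of 25 is discriminative), 5% adapter read-through (fragment
  0.7–0.95× read length, TruSeq fill), 3% contaminant pairs, 5% planted
  deletion-breakpoint half-mapped pairs (deletion 250–450 bp, breakpoint at
  the unmapped mate's midpoint, anchored mate clean), and 8% Y pairs for
  male strains (`strain_1` and `strain_4` by default). Sequencing errors are
  substitutions at `error_rate` with correspondingly low quality symbols.
  Mates that would partially straddle an insert or PAR boundary are
  resampled, which keeps every pair's origin geometrically unambiguous; the
  truth table's `expected_category` is derived from the same geometry at
  generation time, never from the classifier.
* **Determinism.** All randomness flows from `SimulationConfig.seed`
  through named child seed sequences, so identical configurations give
  byte-identical FASTQ/SAM/TSV/BED/FASTA/Newick outputs.

## What the simulations show — and what they do not

Under these conditions the suite demonstrates: exact planted-origin
recovery at zero sequencing error (every tally category equals its truth
count across 8×20 000 pairs); ≥ 90% per-category agreement at 1% error;
count conservation; oracle equivalence for trimming, mapping, block finding
and local alignment; planted phylogeny recovery (Robinson–Foulds 0) from
both the read-similarity and assembly-distance routes in ≥ 9 of 10
replicate studies; and perfect strain-specific/common contig labels at zero
assembly noise.

The generator does not emulate base-caller error profiles (no indel
errors, no cycle- or context-dependent quality), repetitive or
low-complexity sequence, homology between contaminants and host,
copy-number variation, real assembly fragmentation, or mate-pair
(large-insert) libraries. Exact recovery is therefore a statement about the
pipeline's logic under a clean generative model, not a claim about error
rates on real data, where repeats and homology are the dominant confounders
and the categories necessarily blur. The stage-isolated tree-recovery
replicates run the similarity stage on the generator's labeled remaining
reads; the full chain (QC → classification → similarity) is exercised
end-to-end at full size separately. Problem sizes throughout (0.5 Mb
genomes, 20 000 pairs, 8 strains) are the package's desk-scale defaults,
chosen so the whole suite runs in minutes while every rate that matters
(block footprints, insert burdens, spike-in fractions) stays in a regime
comparable to the motivating study.

## Numerical and edge-case conventions

Coordinates are 0-based half-open everywhere; SAM positions convert on
read. Interval midpoints are `(start+end)//2`. N bases are allowed in reads
(k-mers containing them are skipped) and rejected in reference FASTA unless
explicitly permitted. Canonical k-mers are the lexicographic minimum of the
2-bit-encoded k-mer and its reverse complement. Empty inputs raise errors
naming the offender (empty similarity samples, empty assemblies, empty
contig sets for N50). The contaminant genus report errors on a hit sequence
without a taxonomy row rather than silently dropping it.
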