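# Methods

## Overview

`msacorrect` corrects substitution errors in Illumina-style short reads.
Every read in turn serves as the *anchor*: similar reads are retrieved by
minhash fingerprints, aligned to the anchor without gaps, stacked into an
anchor-centered multiple sequence alignment (MSA), pruned of rows that
belong to other genomic copies, and finally the anchor (and, where the MSA
is trustworthy, its supporting candidates) is rewritten towards the weighted
column consensus.  Two correction policies share this machinery: a
rule-based policy, and a policy that delegates the ambiguous decisions to a
pair of random-forest classifiers.

The method assumes (i) errors are substitutions — indels are neither modeled
nor corrected; (ii) coverage is high enough (roughly 15x and up) that most
anchor positions are seen by several independent reads; (iii) the user can
supply an estimate of the dataset's fold-coverage, which calibrates the MSA
refinement threshold.

## Candidate retrieval

Each read is fingerprinted by `h` independent hash functions (default 48):
function `l` is applied to every canonical k-mer (default k = 20; the
canonical form is the lexicographic minimum of a k-mer and its reverse
complement on the 2-bit code, so fingerprints are strand-invariant) and the
minimum hash value is kept as signature slot `l`.  The read id is stored in
hash table `l` under that key.  Querying a read unions the `h` buckets its
own signature addresses.  Two reads collide in a table exactly when they
share the k-mer minimizing that hash function — likely for reads overlapping
in the genome, unlikely otherwise.  The hash family is a splitmix64
avalanche finalizer applied to the k-mer code XOR a per-function seed, so
the whole index is reproducible from one integer seed.  k-mer windows
containing N are skipped.  Queries whose union exceeds `max_candidates`
(default 1000, a repeat-region guard) drop the most populous buckets first.

## Alignment and filtering

Candidates are aligned to the anchor by shifted Hamming distance: every
shift of the candidate against the anchor, in both orientations, is scored
by mismatches within the overlap, and the placement with the smallest
mismatch/overlap ratio wins (ties: smaller |shift|, then forward).  Only
shifts whose overlap reaches `min_overlap_ratio` (default 0.3) of the anchor
length are considered.  N positions are excluded from both overlap and
mismatch counts.  This is an exact computation; the test suite holds it
equal to a brute-force all-shifts oracle.

Single-end filtering removes candidates whose ratio exceeds
`max_mismatch_ratio` (default 0.2).  In paired mode the two anchors of a
pair are processed together: a candidate whose mate is a candidate of the
other anchor passes unconditionally (both fragments almost surely stem from
the same locus); all others must have ratio strictly below `t_paired`
(default 0.06).

## MSA construction, weights, refinement

Members are stacked gaplessly at their alignment shifts (star-approximation
style).  Per column and nucleotide the MSA keeps a raw count and a weight
sum.  A row's per-base weight is

    max(1 - 3 * mismatch_ratio, 0.25) * (1 - 10^(-Q/10))

— an alignment factor that discounts noisy rows (floored at 0.25 so no
surviving row is voiceless) times the Phred-derived probability that the
base call is correct; the anchor row uses mismatch ratio 0, and N bases
contribute nothing.  The column *consensus* is the nucleotide with the
largest weight (ties prefer the anchor's base, then the lexicographically
smallest — conservative toward no-op corrections); *support* is the
consensus' share of the column weight; *coverage* is the number of non-N
bases in the column.

Refinement targets candidates from other copies of inexact repeats: a
round scans anchor-covered columns for a non-consensus nucleotide `X` whose
count reaches `0.3 x estimated_coverage`.  Only the column with the largest
such count is acted on per round (removals invalidate the other columns'
consensus).  If `X` equals the anchor's base there, candidate rows covering
the column *without* `X` are removed — the anchor's own pattern is a minority
being rescued; otherwise rows carrying `X` are removed.  Rows that do not
span the triggering column carry no evidence and are kept.  At most five
rounds, stopping early when nothing is removed; the anchor row is immune.
Removal updates the column profiles by subtraction and is held equal to a
from-scratch rebuild by the tests.

## Correction policies

MSA quality is judged on the anchor-covered columns: minimum support,
average support, minimum coverage, thresholded at 0.75 / 0.90 / 5 by
default.  These defaults are this package's declared operating point (they
separate clean piles from ambiguous ones under the simulator's statistics)
and are exposed in the configuration.

*Rule-based (classic).*  High-quality MSA: the anchor becomes the consensus
outright.  Low-quality: a position changes only when its column support
exceeds 0.90 and at most two reads still carry the anchor's base.
Candidates are corrected only from high-quality MSAs and only when fully
contained in `[b - x, e + x)` around the anchor's column range (x = 15);
their corrected sequence is the column consensus, mapped back to the read's
original orientation.

*Forest.*  High-quality MSAs are handled exactly as in classic mode.  For
low-quality MSAs, each anchor position disagreeing with the consensus is
described by 16 features — local column statistics (count and weight
fractions of the original and consensus base, Phred-derived qualities,
support, coverage, relative position) and global MSA aggregates
(min/avg/max coverage scaled by the coverage estimate, min/avg support,
mean support over the read's span) — and changed only when the ensemble's
mean positive probability strictly surpasses the confidence threshold.  A
second forest with four additional alignment features (overlap fraction,
mismatch count and ratio, |shift|) vets each changed position of a
candidate correction.  Positions already agreeing with the consensus are
never scored.

The default confidence threshold is 0.7 for both forests.  With 128
bootstrapped trees, per-position confidence is the fraction of trees voting
for the correction; genuinely correct consensus corrections routinely draw
dissent from a minority of trees trained on other bootstrap slices, so a
threshold near 0.9 demands near-unanimity and suppresses corrections the
evidence supports, while 0.7 requires a clear majority and still rejects
contested positions.  The threshold is deliberately user-facing: raising it
trades sensitivity for precision, and both true and false positives are
non-increasing in it (a tested invariant).

## Training

Forests (scikit-learn `RandomForestClassifier`, 128 trees, library-default
hyperparameters, fixed seed) are trained on simulated reads with an
error-free twin.  The pipeline runs in feature-harvest mode so training
MSAs are identical to inference MSAs.  Anchor examples come from
low-quality MSAs (the only place the anchor forest is consulted), candidate
examples from high-quality MSAs (the only place candidate corrections
occur), in both cases at consensus-discordant positions; the label is
positive exactly when the consensus equals the error-free base, i.e. when
applying the correction would be right.  Training follows a
leave-one-genome-out protocol: datasets are tagged by genome and named tags
are excluded.  Example counts are capped (50 000 per role, seeded
subsample) to bound tree size.  Models serialize to a JSON container of
flattened tree arrays plus the named feature schema; the bundled traversal
reproduces scikit-learn's `predict_proba` (verified bit-for-bit in tests),
so no pickled code is shipped or loaded.

## Merge

A read may receive one anchor correction and any number of candidate
corrections from other anchors' MSAs.  With fewer than three candidate
corrections, the anchor correction wins; with three or more it is used only
if string-equal to all of them; otherwise the read is left unchanged.  A
read with candidate corrections but no anchor correction (not covered by
the base rule set) takes three or more mutually identical candidate
corrections, else stays unchanged — the same agreement principle applied
symmetrically, flagged in the audit log.  Reconciliation is order
independent (tested by permutation).

## Evaluation machinery

Per-base three-way comparison against the error-free twin: with `u`, `e`,
`c` the uncorrected/error-free/corrected base, TP is `u != e and e == c`,
FP is `u == e and e != c`, FN `u != e and c == u`, TN `u == e and c == u`;
the residual case (`u != e`, `c` neither `u` nor `e`) is reported as a
separate miscorrection column and excluded from the FP-rate formula
`10^6 * FP / (FP + TP)`, keeping the printed formulas exact without hiding
the event.  The k-mer check counts canonical 21-mers present in the
uncorrected reads and the reference but absent after correction, binned by
multiplicity 1–10 in the uncorrected reads.

## The simulator

The simulator emulates what the corrector exploits in Illumina data:
uniform fragment sampling at a chosen fold-coverage, 100 bp paired reads
from opposite fragment ends (insert ~ N(300, 30)), Phred qualities from a
linearly degrading profile (mean 28 at the 5' end to 18 at the 3' end,
sd 3), and substitution probabilities proportional to `10^(-Q/10)`,
rescaled so the dataset-mean error rate equals the configured `error_rate`
(default 1%) exactly in expectation — the raw profile fixes the *shape* of
the error distribution along the read, the rescale fixes its level, and
both stated properties (errors tied to quality; mean equal to the target)
hold at once.  Optionally it plants inexact repeat families
(copies/unit-length/divergence) to exercise MSA refinement and to produce
the ambiguous MSAs the anchor forest trains on.  An error-free twin and a
per-substitution log provide ground truth.

What it does **not** emulate: indels, GC-coverage bias, adapter read-through,
PCR duplicates, machine-specific quality artifacts, or realistic genome
composition (uniform-random background plus planted repeats only).  Passing
tests therefore demonstrate the algorithms' correctness and their behavior
under idealized Illumina-like statistics, not performance on real libraries.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run a 10 kb genome at 30x
(3 000 reads) for end-to-end evaluation, an 8 kb repeat-rich genome for
training, and a 5 kb dataset for the threshold sweep — sizes at which every
phase (indexing, alignment, refinement, training, two full correction
passes) completes comfortably on one CPU while leaving hundreds of planted
errors to measure.  Column weights are float64; consensus ties are broken
deterministically (anchor base, then lexicographic); all randomness
(genomes, reads, hash seeds, forest training, subsampling) flows from
integer seeds, and a fixed seed reproduces byte-identical output.

## Known limitations

- Substitutions only; an indel shifts every downstream base and will defeat
  the gapless alignment.
- The coverage estimate is taken on trust; a badly wrong estimate skews the
  refinement threshold (too low: repeats survive refinement; too high:
  legitimate minority patterns are purged).
- Low-coverage datasets (< ~10x) leave most MSAs below the quality floor,
  where only the conservative low-quality rules apply.
- The candidate cap discards retrieval information in extreme repeat piles.
- Forest mode's quality depends on the training genomes containing the
  ambiguity classes (repeats, coverage dips) present at inference time.
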