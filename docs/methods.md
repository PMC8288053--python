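# Methods

This note records the model, the defaults and the design choices behind
`glycurate`, in the order data flows through the pipeline.

## Text processing

Cleaning applies three removals, in order: (i) spans enclosed in
parentheses, square brackets or braces, innermost-first until no bracketed
span remains (so nesting and stray partner-less brackets are handled);
(ii) every character outside alphanumerics, space and period, deleted in
place so that neighbours merge — `O-GlcNAc` becomes `OGlcNAc`, which is why
the shipped patterns match hyphen-free, case-folded variants; (iii)
stop-word phrases at word boundaries, iterated to a fixed point because
deleting a phrase can merge its neighbours into a new occurrence. The
result uses only `[A-Za-z0-9 .]` and the function is idempotent, which the
test suite checks by property.

Section selection runs **before** cleaning (cleaning deletes newlines and
would destroy header lines): headers matched by the configurable section
patterns partition the text, and only results/discussion spans are kept.
When no such header is found the whole document is kept — text extracted
from layout-based formats frequently loses its headers, and triaging the
whole document is strictly better than triaging nothing.

Tagging matches four word lists (biology, glycobiology, cells, methods),
nine regex categories (conclusion, description, peptides, nucleic acids,
pronominial, ser/thr, amino acids, phosphorylation, O-GlcNAc) and the
protein/organism dictionaries, case-insensitively. Overlapping candidate
matches are resolved longest-leftmost; exact ties fall back to a fixed
priority (regex categories > protein names > organism names > word lists).
A literal term claimed by two word-list categories is a configuration
error, refused at load. Only period-delimited segments retaining more than
one tag survive. The shipped lexicons are deliberately small, editable
seed lists — a production deployment should substitute dictionaries built
from UniProtKB and a curated stop-word corpus; every list loads from plain
text/YAML files for exactly that reason.

## Features

An expression is one whole tag sentence rendered as a space-joined chain;
occurrences are counted at corpus level over the concatenated training
documents, and the vocabulary keeps expressions with count ≥ `min_count`
(default 4). The cutoff suppresses one-off artifacts of text conversion
while keeping patterns that recur across documents. Descriptors are
strictly binary presence vectors — no counts, no weighting — ordered
lexicographically so that model files and vectors stay aligned across
runs; a short content hash of the vocabulary is embedded in model files
and checked at prediction time.

## Splits

Shuffle-and-slice at fractions (1/2, 1/4, 1/4); test and validation sizes
round down and training absorbs the remainder, so a 1340-document pool
yields (670, 335, 335). A candidate split is accepted only when every set
satisfies |n⁺ − n⁻|/n < 1% (strict), otherwise the pool is reshuffled.
The strict 1% rule needs sets of a few hundred documents: a 335-document
set passes with an imbalance of 1 or 3, whereas a 25-document set can
never pass, so desk-scale tests relax the tolerance explicitly rather than
silently. Splitting takes an explicit seed for reproducibility; seedless
mode reproduces unbiased shuffling. Bagging subsets are independent
half-size slices of the training set (without replacement within a
subset), not classical with-replacement bootstraps.

## Network and training

One hidden ReLU layer (default 96 units) into two *independent* sigmoid
outputs — not a softmax; the two outputs are trained against the label
pairs (1,0)/(0,1) with mean binary cross-entropy, the canonical loss for a
logistic classifier with sigmoid units. Predictions are clipped to
[1e−12, 1−1e−12] before the logarithm. The optimizer is plain full-batch
gradient descent; weights initialise from a scaled-uniform distribution
with He limits (√(6/fan-in)), biases at zero.

The learning rate follows
`lr(e) = ilr · d^⌊e/c⌋ · exp(−k·(e mod c))` with ilr = 0.25, k = 0.05,
c = 100 epochs and d = 0.95: exponential decay within a cycle, each cycle
restarting from a peak reduced by d. With k > 0 the rate strictly
decreases within a cycle and with d < 1 the peaks strictly decrease across
cycles; both are property-tested.

The dropout parameter (0.7) is interpreted as the hidden-unit **retention**
probability, implemented as inverted dropout (survivors scaled by 1/keep
at train time, so eval mode needs no rescaling); the interpretation is a
constructor flag because either convention is defensible, and
`dropout = 0` always means "no dropout". A fresh mask is drawn every epoch
for every sample. The Monte-Carlo expectation-preservation of inverted
dropout is verified over 10⁴ masks.

Training always runs the full `n_cycles × c` epochs; early stopping is
*selection*, not halting — the returned parameters are the snapshot with
the highest test-set accuracy. Ties on test accuracy are broken by
training accuracy, then by earliest epoch. The secondary criterion
matters on easy corpora: when the test set saturates at 1.0 within a few
epochs, the earliest saturating snapshot is barely trained and
generalises measurably worse than a snapshot that also explains its
training subset; preferring the latter fixed exactly that failure mode on
held-out data. Non-finite losses or parameters abort with a divergence
diagnostic rather than continuing silently.

## Ensemble, intervals, decisions

Members vote 0/1 (positive output ≥ negative output); votes are averaged
and wrapped in the normal-approximation binomial interval
p̂ ± z·√(p̂(1−p̂)/n) with z = 1.96 (configurable). Stored bounds truncate
to [0,1], but the *width* the ambiguity rule compares against its
threshold is the untruncated 2z·√(p̂(1−p̂)/n). A call is ambiguous when
that width strictly exceeds 0.5; otherwise p̂ rounds to the call, with
exactly 0.5 rounding to negative (conservative for triage: a false
negative costs a missed paper, a false positive costs curator time
believing a wrong claim). With five members and z = 1.96 every
non-unanimous vote is ambiguous — an intended property of the triage
overlay, but it means plain majority-vote accuracy must be scored with
the ambiguity threshold disabled (`threshold = 1.0`), which is what the
bagging-benefit tests and the acceptance script do when comparing the
aggregate against single members and the Bayes ceiling.

`evaluate` partitions samples three ways: accuracy counts decisive correct
calls; `accuracy_with_ambiguous` additionally credits ambiguous samples
(they reach a curator, so they are never silently wrong); precision and
recall are computed on the positive class over decisive calls, with
precision reported as absent (not zero) when no positive call was made.

## Synthetic corpora

The generator emulates a labeled curation corpus at the tag-sentence
level: each of `n_signal_patterns` (default 3) planted tag chains appears
in a positive document with probability `p_signal_pos` and in a negative
one with `p_signal_neg`; `n_background_patterns` (default 10) chains
appear with a label-independent 0.3; random filler sentences pad each
document to 8–15 sentences. Filler chains are resampled if they collide
with a planted pattern — otherwise filler could inject signal bits into
negative documents and invalidate the exact Bayes computation. Defaults
(200 documents, half positive) are a desk-scale analogue of a balanced
curation corpus of ~1300 papers.

`bayes_accuracy` enumerates the 2^k presence configurations of the signal
patterns and sums `max(π⁺P(v|+), π⁻P(v|−))`; enumeration is refused above
12 patterns. Trained ensembles must not beat this ceiling by more than
binomial noise — a guard against information leaking through the pipeline.

Surface-realization mode wraps every tag in a literal term the shipped
lexicons recognise, interleaved with untagged filler words, and draws its
filler words from a stream derived from (seed + 999983) so the tag-level
structure of a corpus is identical across modes for the same seed. What
the generator does **not** emulate: real scientific English, section
structure, conversion noise, correlated pattern co-occurrence, or class
imbalance drift — so passing tests demonstrate the pipeline's mechanics
and calibration, not field performance on real literature, whose headline
accuracies depend on corpus-specific dictionaries and cannot be reproduced
without the copyrighted full texts.

## Sequence utilities

Coordinates are 1-based, closed intervals (UniProt convention). Site QC
checks, in order: position within the sequence, claimed residue equals the
sequence letter, residue ∈ {S, T}. Sequences containing ambiguity codes
(B, Z, X, U, O) are refused at load rather than coerced. Digestion uses
the standard tryptic rule (cleave after K/R, blocked before P) or a custom
(cleave-after, blocked-next) pair; full mode yields the maximal cleavage
partition (peptides provably tile the sequence), partial mode every run of
up to `max_missed + 1` consecutive fragments, verified against brute-force
enumeration. Consensus matrices tally residues at offsets −w..+w around
sites that pass QC (failures are excluded with a logged warning — a
self-maintaining pipeline keeps going); out-of-range offsets contribute
nothing to their column, per-column frequencies sum to 1 wherever counts
are positive, and information content is log₂20 minus the column's Shannon
entropy, without small-sample correction. The logo renderer is a minimal
matplotlib letter-stack; the CSV matrix is the primary output.

## Problem sizes in tests and the acceptance script

End-to-end tests use 120–200-document corpora, ensembles of 3–5 members
with 8–32 hidden units and 1–3 cycles; the acceptance script uses
200-document corpora, 5 members, and the full default network for the
separable-recovery check. These sizes were chosen so the full suite
completes in seconds while every statistical assertion retains power
(binomial standard errors are computed at the actual n used, never
assumed).

## Known limitations

- The shipped lexicons are seed reconstructions, not curated dictionaries;
  tagging quality on real papers depends entirely on replacing them.
- The binomial interval uses the normal approximation, which is crude at
  n = 5 members; it is calibrated (and tested) in the n ≈ 100 regime.
- Site QC flags errors but never auto-corrects positions (no isoform or
  variant coordinate mapping).
- The classifier is deliberately minimal: no mini-batching, momentum,
  softmax, or deeper architectures.
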