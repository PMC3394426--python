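# Methods

This note documents the models and procedures implemented in
`abbrclust`, the conventions adopted where more than one reading was
defensible, what the synthetic benchmark does and does not emulate, and
the numerical choices that affect results.

## Task

Given records ("A-pairs") of an abbreviation, its full form, a gold
concept identifier, and a chemical/non-chemical flag, all A-pairs sharing
an abbreviation are candidates for denoting the same concept.  Matching
is cast as a binary decision per candidate pair: predict same-concept
when the string score of the two full forms clears a cutoff.  Strict
inequalities are used throughout — score `< t` for distances, `> t` for
similarities — so that every threshold equal to an observed score value
has a well-defined prediction set.  Full forms are lowercased before
scoring; no other normalization is applied.

## Measures

**Length-normalized edit distance.**  `d = ed(s₁,s₂)/max(n₁,n₂)` with
unit-cost Levenshtein `ed`, computed by O(n₁n₂) dynamic programming
(numba-compiled).  `d(ε,ε)` is defined as 0 (the raw formula is 0/0, but
the inputs are identical).

**Weighted edit distance.**  Identical, except inserting or deleting a
letter c ∈ a..z costs `w[c]` ∈ [0,1].  Substitution stays at cost 1 and
characters outside a..z (space, hyphen, digits) cost 1, because the
weight vector is defined only over the 26 letters.  With all weights at
1.0 the measure equals the unweighted distance bit-for-bit (the DP sums
the same floats).  Lowering any single weight can only lower the
distance, which makes the coordinate search below well behaved.

**Monge-Elkan score.**  Best *local* alignment (Smith-Waterman style)
under a character score matrix: +5 for equal characters, +3 for two
characters in one of the equivalence classes {d,t}, {g,j}, {l,r}, {m,n},
{b,p,v}, {a,e,i,o,u}, −3 otherwise, with affine gap penalty
`g(k) = α + βk`, α = 5, β = 1.  The {5,3,−3} matrix is the default; the
historical {5,2,−5} variant is available through `MongeElkanParams`.
Two conventions are deliberate:

* the score is *maximized* (higher = more similar), which is the only
  direction consistent with using `> t` similarity cutoffs and with
  self-similarity 1;
* the exact constant used historically to scale the raw alignment score
  into [0,1] is not fixed by any source we follow, so the package
  divides by `match_score · min(n₁,n₂)` — the largest score any
  alignment of the two strings can attain — and clips negatives to 0.
  Identical strings then score exactly 1.  Empty strings are rejected
  (the scale is undefined).

**Jaro / Jaro-Winkler.**  Characters match when equal and at most
`⌊min(n₁,n₂)/2⌋` positions apart — note this window uses the *shorter*
length, which we keep as specified even though the classical definition
uses `⌊max/2⌋−1`.  With m matches and T = (number of matched positions
whose characters appear in different order)/2, the Jaro score is
`(m/n₁ + m/n₂ + (m−T)/m)/3`, 0 when m = 0.  The Winkler boost is
`j + (min(p,4)/10)(1−j)` for common-prefix length p; capping p at 4 is
forced by the score ≤ 1 invariant (an uncapped prefix factor can exceed
the unit interval).

**SoftTFIDF.**  Token weights `V(w,s)` are L2-normalized
`log(TF(w,s)+1)·log(IDF_S(w))` with natural logarithms, where `IDF_S(w)`
is corpus size over the number of corpus strings containing w.  Each
token w of s₁ whose best Jaro-Winkler match w* in s₂ reaches the cutoff
a (default 0.9, ties broken to the lexicographically first token)
contributes `V(w,s₁)·V(w*,s₂)·jw(w,w*)`.  Using the argmax token w* on
the s₂ side makes the second factor well defined when w itself does not
occur in s₂.  Tokens unseen in the corpus statistics get document
frequency 1 (maximally informative); tokens occurring in every corpus
string get zero weight.  The measure is *not* exactly symmetric (the sum
runs over s₁'s tokens); self-similarity is exactly 1 whenever all tokens
carry positive weight.  Corpus statistics default to the union of all
full forms in the pair set; per-abbreviation-group statistics are a
config option.

**Bigram Dice.**  `s_n = 2·c_n/(n₁+n₂)` where `c_n` is the *capped*
multiset intersection of length-n substrings (a repeated bigram cannot
match more often than it occurs in the other string) and the denominator
is the plain character lengths.  That denominator leaves self-similarity
at `(n−1)/n` rather than 1; it is kept as the default because it is the
form the analysis is defined with, and the conventional n-gram-count
denominator `(n₁−n+1)+(n₂−n+1)` is available via
`ngram_dice(..., denominator="ngram")` and the `--dice-denominator`
flag.  n = 2 by default.

## Evaluation layer

Precision is defined as 0 when nothing is predicted, recall as 0 when
there are no gold positives, F as 0 unless both are positive.  Threshold
grids: coarse (0.00–1.00 step 0.05), fine (0.900–0.995 step 0.005, for
SoftTFIDF whose F peak sits near 1), and *observed* — every distinct
score value plus a sentinel (+∞ for distances, −∞ for similarities) that
realizes the all-predicted set.  Best-F selection uses the observed grid,
because F-maximizing cutoffs generically fall on observed score values,
not on a fixed lattice; F ties break toward the stricter threshold.

PR curves and fixed-recall operating points rank pairs best-score-first
and scan prefixes; ties in score are grouped so every curve point is
realizable by a strict threshold.  `threshold_at_recall` returns the
prefix whose recall is *closest* to the target (ties toward the smaller
prefix) and reports the score of the last included pair as the
threshold; when the empty prefix is closest it reports the best observed
score (which, with a strict cutoff, predicts nothing).

The split-vs-mixed comparison at target recall r selects per-subset
prefixes for the chemical and non-chemical pair sets, reports their
precisions and thresholds, evaluates the union of the two prediction
sets against the pooled gold ("all" row: pooled TP over pooled
predictions; its recall is reported alongside), and compares with the
single prefix chosen on the concatenated set ("mixed" row).  The union
construction is one of two defensible readings of a pooled row (the
other is recall-weighted averaging); it is used because it corresponds
to an operational system that actually applies the two thresholds.  The
mixed row is computed by the same fixed-recall scan on the concatenated
set, so the two settings are bit-for-bit comparable.

## Weight learning

Coordinate descent starts from the all-ones vector and visits each
letter a..z exactly once, in alphabetical order — a single pass, no
convergence iteration.  For each letter the candidate costs are the 0.1
grid over [0.0, 1.0] plus the incumbent value; each candidate is scored
by rescoring every pair with the weighted edit distance and taking the
best F over the observed-score sweep.  Maximizing over thresholds is the
only reading that makes candidate costs comparable without fixing an
arbitrary cutoff.  Because the incumbent is always a candidate, the best
F is non-decreasing along the trace.  Ties prefer the value closest to
1.0 (then the larger), so letters with no effect on the objective keep
their initial cost instead of drifting.  The search range [0,1] and the
0.1 step are configurable.  Weights are learned and evaluated on the
same pair set, reproducing the original protocol; no cross-validation is
attempted, and the resulting F values should be read accordingly.

## Synthetic benchmark

The generator emulates the statistical structure the analysis needs, at
desk scale (defaults: 300 chemical + 300 non-chemical concepts, mean 3
variants per concept, collision groups of mean size 3, producing on the
order of 10³–10⁴ candidate pairs per subset):

* **Chemical names** are 2–5 tokens concatenated from a morpheme grammar
  (multipliers mono/di/tri/tetra/penta; stems meth/eth/prop/but/pent;
  suffixes yl/ol/ane/ene/oxy; connectors glycol/ether/acid/amine/
  benzene), with at least one morpheme compound and one connector.
* **Near-miss neighbors**: with probability 0.3 a chemical concept gets a
  distinct-concept neighbor produced by swapping one morpheme for a
  close one (meth↔eth, di↔tri, yl↔ol, ol↔oxy, ane↔ene), guaranteed
  within edit distance 2 and sharing the source's abbreviation.  These
  are the hard negatives that force strict chemical thresholds.
* **Variants** of a concept are hyphen/space swaps, an optional plural
  's', and benign character insertions at 0.05 per character drawn from
  a small planted set (e, h, p for chemical names; x, z, u for
  non-chemical).  For chemical names the insertions are confined to
  connector words so the discriminative stem characters stay intact.
  The planted sets are what the weight learner should discover.
* **Abbreviations** are token initials with random truncation; concepts
  are packed into collision groups of the configured mean size and each
  group shares one (uniquified) abbreviation.  Near-miss pairs always
  land in the same group.
* A config option (`match_letter_frequencies`) replaces the non-chemical
  word list with pseudowords sampled letter-by-letter from the empirical
  letter distribution of the generated chemical names, making aggregate
  letter frequencies close while sequence structure still differs.

Everything is reproducible from the config seed (numpy `default_rng`).

What the generator does *not* emulate: real IUPAC syntax or its
ambiguity, UMLS concept granularity, OCR/typographic noise, token
reordering variants, digits and Greek letters (names are restricted to
a–z, space and hyphen so the 26-dimensional weight vector covers every
weighted character), and the real 10:1 scale and class imbalance of
dictionary-derived pair sets.  In particular the synthetic non-chemical
subset is *easier* than real data — its false pairs are unrelated word
phrases — so non-chemical F-measures near 1.0 say nothing about absolute
real-world performance.  Passing tests establish the *ordinal* findings
(chemical thresholds are stricter; splitting beats pooling at fixed
recall; benign-edit letters get discounted), not the original study's
absolute precision/recall numbers, which were computed on a proprietary
dictionary-derived corpus that is not redistributable.

## Problem sizes and determinism

The acceptance script and the heaviest tests run the default generator
at 10 seeds (~10⁴ candidate pairs per seed) for the threshold and
split comparisons and 3–10 seeds for weight learning; these sizes give
stable medians while keeping the full suite in the tens of seconds.
Edit-distance kernels are numba-compiled; all remaining computation is
numpy or plain Python.  All randomness flows from explicit seeds; two
runs with the same configuration produce identical outputs, including
TSV files.

## Known limitations

* SoftTFIDF's asymmetry is inherited from its definition; callers who
  need symmetry should average the two directions.
* The Monge-Elkan [0,1] scaling is a convention (see above); scores from
  differently scaled implementations are not directly comparable.
* The weighted edit distance only reweights insertions and deletions;
  substitution costs are fixed at 1 by design.
* Weight learning is a greedy single pass; it is deterministic but not
  guaranteed to find the global optimum of the (piecewise-constant)
  objective.
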