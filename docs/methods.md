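# Methods

## The problem

Seed-and-extend read mappers locate a read `R` in a reference `T` by looking
up exact occurrences of read substrings (*seeds*) and aligning `R` around
each occurrence.  A reference interval `[l1, l2]` is a *valid mapping* when
the edit distance `D(R, T[l1, l2])` is strictly below an error tolerance
`t`.  The classical pigeonhole argument forces `t` non-overlapping seeds per
read: with fewer seeds an alignment with `t - 1` errors could hit every seed
once.  As `t` grows, seeds get shorter and more frequent, and the mapper
drowns in candidate alignments.

This package implements *context-aware seeds*: each reference substring `s`
(up to a maximum seed length `P`) carries a **confidence radius** `c_s >= 1`,
and any non-overlapping seed set whose radii sum to at least `t` suffices to
find every valid mapping (the *weighted pigeonhole principle*).  Radii above
1 mean fewer, longer, less frequent seeds at equal sensitivity.

## Vicinity, trivial neighbors, and the radius

All coordinates are 0-based half-open internally; inclusive interval
notation appears only in mapping output (1-based there, documented in the
CLI).

An occurrence interval `[l1, l2]` is **in the vicinity** of a seed `s`
under `c` when `s` occurs at some `[ls1, ls2]` with `l1 - c <= ls1` and
`ls2 <= l2 + c` — the seed occurrence sits inside the query interval
extended by `c` letters on each side.  We use inclusive bounds throughout:
they are the only convention under which a seed's own occurrence is in its
vicinity at `c = 0` (self-trivialness) and under which all distance-1
neighbors of a seed sit inside its 1-letter extended window, both of which
the theory requires.  The candidate windows of the mapper widen seed
occurrences by `t` on each side, matching this convention at `c = t`.

A neighbor `s'` (a reference substring with `D(s, s') < theta`) is
**trivial** when *every* occurrence of `s'` is in the vicinity of `s` under
`D(s, s')`: such a neighbor can never reveal a mapping location that `s`
does not already point at.  The **confidence radius** is the minimum edit
distance from `s` to a *nontrivial* neighbor, capped at the threshold
`theta` (a search-space bound: radii are lower bounds and never need to be
tight, so seeds whose true radius exceeds `theta` simply receive `theta`).

Sensitivity argument: if a valid mapping escaped the vicinity of every
selected seed, each seed's aligned counterpart inside that mapping would be
a nontrivial neighbor, costing at least `c_s` edits per seed, hence at
least `sum c_s >= t` edits in total — contradicting validity.  The suite
verifies this guarantee empirically with zero tolerated misses.

## Database construction

1. **Suffix trie** of `T` to depth `P + theta` (string length), one node
   per distinct substring, BFS ranks (depth-major, parent-rank, then fixed
   alphabet order A<C<G<T).  Naive `O(|T| * depth)` insertion; the
   linear-time claims concern the traversal below, not trie construction.
2. **Neighbor database**: for every node `v`, the rank-sorted array `X_v`
   of nodes within edit distance `< theta`, with distances `Y_v` and
   immediateness flags `Z_v`.  Nodes are processed in rank order; a child
   pair's distance derives in O(1) from the parent pair and the two
   parent-child cross pairs (the edit-distance recurrence restricted to
   trie edges), with forward-only pointers into the sorted arrays.  Absent
   cross pairs (distance >= theta) enter as the sentinel `theta + 1`, which
   can never produce a stored value.  Storage is strictly `D < theta`: a
   distance-theta pair cannot change any capped radius.  The root is
   initialized with all nodes of depth <= theta (distance = depth - 1) and
   symmetrically seeds itself, as the lowest rank, into each neighbor's
   array.
3. **Immediateness flags**: eight conditions per stored pair — prefix,
   suffix, containment (proper/internal), and two overlap conditions ("a
   prefix of one is a suffix of the other", minimum overlap length
   `min_overlap`, default 1).  The flags propagate along trie edges in
   O(1); the recurrences were re-derived from the string definitions
   because the obvious parent/child index pairings are easy to get wrong,
   and they are validated exhaustively against a declarative
   string-comparison oracle in the tests.  Two absences matter: conditions
   1-6 are provably false when their cross pair is unstored (a containment
   relation forces the cross distance below the child distance), while the
   overlap conditions 7/8 are not — when their cross pair sits exactly on
   the threshold, the builder evaluates the overlap on the spelled strings
   directly.  The empty-string root is flagged truthfully as a prefix and a
   suffix of every neighbor; with that, no root special case is needed.
4. **Radii.** Classifying a neighbor as immediate (substring, superstring
   or overlapping string) is cheap, and minimizing over *non-immediate*
   neighbors only is a tempting shortcut — superstrings are always trivial,
   and trivial neighbors of seeds longer than the distance always have a
   string relationship with the seed.  The shortcut is **not sound in the
   other direction**: around repeats, the closest nontrivial neighbor is
   frequently itself a substring or overlapping string of the seed, and
   every same-length replacement string one could substitute for it
   overlaps the seed too.  Minimizing over non-immediate neighbors then
   *overestimates* the radius, which would break the sensitivity guarantee
   (an overconfident seed skips locations it must visit).  We measured this
   on exhaustive binary-alphabet references and on random DNA: the
   overestimate affects a large fraction of short seeds at every
   `min_overlap` setting.  The pipeline therefore computes the
   **definitional radius exactly**: neighbors are scanned in ascending
   distance; a non-immediate neighbor of a seed longer than the distance is
   accepted immediately (provably nontrivial, see above); immediate
   candidates get an explicit occurrence-geometry trivialness check against
   the trie's occurrence lists (total size `|T| * depth`, so the checks are
   cheap at this package's scale).  The immediateness-only minimum remains
   available (`confidence_radius(..., method="non_immediate_min")`) for
   profiling, with its failure mode pinned by a unit test.
5. **Table**: radii of all seeds `T[x, x+y)` for sampled lengths
   `y ∈ {I, 2I, ...}` capped at `P` (lengths that are multiples of the
   sampling interval `I`; `P` itself is included only when `I` divides
   `P`).  Stored as one byte per entry (radii <= theta <= 255) next to a
   text header carrying the parameters and an MD5 checksum of the
   reference, which the CLI verifies on every use.  Equal strings at
   different positions share one radius through their shared trie node.
   Strand: forward only; map reverse-complement reads by building a second
   database over the reverse complement.

## Seeding and mapping

Seeds are maximal exact matches (MEMs) scanned left to right: the longest
prefix of the unscanned read suffix that occurs in `T` (suffix-array
lookup, one binary search per extension letter).  After each MEM the scan
skips 2 bp — a heuristic jump over the error that ended the match; the skip
is suppressed when it would waste a still-usable tail.  Matches shorter
than a minimum seed length (default 5 bp, never below `I`) are scanned
past without becoming seeds: 1-2 bp fragments occur hundreds of times in
even a kilobase reference, carry no locating power, and the greedy rule
below would otherwise select one as a cheap radius top-up with enormous
frequency cost.  Dropping them is sensitivity-safe — selection reverts to
the pigeonhole split whenever the surviving radii cannot reach `t`.

Radius assignment: a seed of sampled length resolves by direct lookup.
Otherwise all substrings of the next-smaller sampled length are enumerated;
among those whose occurrence frequency equals the seed's, the maximum
radius is taken (an equal-frequency substring occurs exactly where the seed
does, so its radius lower-bounds the seed's — the substring-monotonicity
property checked by the suite).  With no frequency match, the seed is
withdrawn and replaced by the sampled substring with minimum frequency
(ties: maximum radius, then leftmost).

Greedy selection sorts seeds by frequency ascending (ties: longer, then
leftmost) and takes the shortest prefix with `sum c_s >= t`; at most `t`
seeds are ever taken since every radius is >= 1.  If the whole list cannot
reach `t`, the read is re-split into `t` contiguous pigeonhole seeds
(longer pieces first).  At `theta = 1` the scheme collapses exactly to
pigeonhole seeding.

Mapping: every occurrence of every selected seed projects a read placement;
starts within `t` of the projection are verified by batched semi-global
dynamic programming (free end gaps on the reference side), and **all**
intervals with `D < t` are reported, deduplicated.  An optional
best-per-locus collapse keeps the minimum-distance interval per overlapping
cluster (leftmost on ties).  The suite asserts that the output equals
brute-force enumeration of all valid intervals on every synthetic trial.

## Synthetic data

The generator emulates short-read mapping at desk scale: uniform ACGT
background; optional repeat families (template length, copy count, per-copy
substitution rate) planted at mutually non-overlapping positions, so at
mutation rate 0 a family's string occurs at least its copy count times;
fixed-length reads from uniform starts with up to `max_edits` planted edits
(uniform mix of substitutions/insertions/deletions; the true distance to
the origin can be smaller when edits cancel).  All randomness flows from a
single integer seed through one numpy generator; equal seeds give
byte-identical FASTA/FASTQ.  Not modeled: sequencing error profiles, base
qualities (constant 'I'), coverage biases, reverse-strand reads, N bases.
Passing tests therefore demonstrate the combinatorial guarantees of the
seeding scheme, not robustness to platform-specific artifacts.

## Benchmark conditions used by the suite

- Neighbor-database and radius exactness: all 2046 binary-alphabet
  references of length <= 10 (`theta=2, P=4`) plus 50 random ACGT
  references of length 60-200 (`theta` alternating 2/3, `P=12`), compared
  bit-for-bit against brute-force enumeration.
- Sensitivity: 20 references of 0.5-5 kb, two planted repeat families each
  (length `|T|/10`, 3 copies, 2% divergence), `theta=2, P=12`, tolerances
  `t = 2..5`, 50 reads per (reference, t) with planted edits `< t`;
  sampling intervals 1, 2 and 4.  Zero misses tolerated.
- Efficiency comparison: one 2.5 kb genome with two 200 bp repeat families
  (4 copies, 3% divergence), `theta=5, P=20` so that the radius cap is not
  the binding constraint (mirroring the benchmark regime where `theta`
  matches the largest tolerance), 500 reads, against naive consecutive
  12-bp pigeonhole seeding.
- Construction-cost linearity: uniform references of 250-2000 bp at
  `theta=3`; candidate evaluations per stored pair must stay within a
  factor of 3.

These sizes keep the full suite within a coffee break on one CPU while
exercising every code path (direct lookup, inference, substitution,
pigeonhole fallback, repeat-induced multi-mappings).

## Known limitations

- The neighbor arrays of all nodes are held in memory; `M` (total neighbor
  pairs) grows steeply with `theta` and genome size, which is exactly the
  scaling wall the offline builder is known to hit on real genomes.  The
  arrays of a processed node could be released once its children are
  processed; the implementation keeps them because every desk-scale target
  fits comfortably.
- One contig per database; multi-record FASTA is refused rather than
  concatenated (occurrence semantics stay unambiguous).
- The suffix array is built by plain sorting (`O(n^2 log n)` worst case) —
  adequate below ~100 kb, not for real genomes.
- `min_overlap` only affects the reported immediateness profile and the
  `non_immediate_min` diagnostic, not the radii used for seeding.
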