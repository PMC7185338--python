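# Methods

## Objects and conventions

All indexes are defined over the *extended text* `S' = S · $^w`: exactly
`w` copies of the sentinel `$` appended to the input, where `w` is the
trigger window size. The alphabet order is the plain byte order
`'#' < '$' < 'A' < 'C' < 'G' < 'N' < 'T'`; `#` (dictionary separator) and
`$` are reserved and rejected in input and queries, and any byte above `$`
is accepted in generic/test mode. Coordinates are 0-based everywhere,
intervals half-open `[s, e)`. The BWT is circular,
`BWT[i] = S'[(SA[i] − 1) mod n']`, so position 0 is preceded by the final
sentinel and no suffix needs special-casing.

Appending `w` sentinels guarantees that every suffix except the `w`
sentinel-only ones is prefixed by a phrase suffix longer than `w`. The
sentinel-only suffixes are emitted by a closed form: they open the suffix
array as `n'−1, n'−2, …, n'−w` (shorter all-`$` suffix first) and
contribute `w−1` sentinels followed by the input's final character to the
BWT. This convention is validated purely by agreement with the brute-force
oracle over the same `S'`.

## Prefix-free parsing

A window `W` of width `w` triggers when its Karp–Rabin fingerprint
`f(W) = Σ W[j]·B^{w−1−j} mod M` satisfies `f(W) ≡ 0 (mod p)`, with
`B = 256` and `M = 2^61 − 1` fixed build-time constants recorded in the
index container header. The first and last windows of `S'` are forced
triggers. Phrases span consecutive triggers plus the closing window, so
adjacent phrases overlap by exactly `w` characters; the distinct phrases,
lexicographically sorted, form the dictionary, and the parse stores
0-based ranks (shifted to 1-based with terminator 0 only inside the
parse-BWT step). An explicit-set trigger policy exists solely to make the
worked examples deterministic and readable.

Parameters that matter:

* `w` (window, default 10 in the CLI): smaller `w` means shorter phrases
  and a larger parse; must satisfy `w ≥ 1`. Inputs shorter than `w` are
  legal — the forced first/last windows produce a single phrase.
* `p` (modulus, default 101): expected phrase length is about `w + p`.
  `p = 1` (every window triggers) is the degenerate stress case.
* The parse is an intermediate: the BWT/SA are functions of the text only,
  and the suite checks bit-identical output across `(w, p)` choices.

## BWT, SA and run samples from the parse

The builder sorts only (i) the suffixes of the dictionary string
`t₁#t₂#…t_d#` and (ii) the suffixes of the parse-rank sequence, both with
an in-package numpy prefix-doubling suffix array (`O(n log² n)` work,
entirely adequate at the sizes used; any correct algorithm could be
substituted behind the same contract). Scanning the dictionary suffix
array yields every distinct phrase suffix `α` with `|α| > w` in
lexicographic order; consecutive equal suffixes (several phrases sharing a
suffix) merge into one group. For each group the per-phrase inverted lists
of parse-BWT positions are merged by position (ties impossible — positions
are distinct), giving the text-suffix order within the block; the BWT
character is the dictionary byte preceding `α` for proper-suffix sources
and the stored text predecessor `PR` for whole-phrase sources; the SA
entry is `EP − |α| + 1` with 0-based `EP` and SA (the 1-based formula
carries over unchanged). In `bwt+samples` mode blocks are consumed
streaming: only run heads, run starts and the SA values at run boundaries
are retained, and the full SA is never materialized.

### The whole-phrase-as-suffix case

The classical argument assumes a phrase that equals some `α` cannot also
be a *suffix* of another phrase. Under the append-only sentinel scheme
used here that assumption can fail for the first phrase of the text: its
leading window is a forced trigger, so if the first phrase's string occurs
again ending at a trigger it becomes a proper suffix of a longer phrase
(`"ACGTACG"` with `w = 2` and trigger `"CG"`: phrase `ACG` is a suffix of
`CGTACG`). Rather than forbidding the case, the merge handles it
uniformly: the whole-phrase source contributes its `PR` characters (for
the first phrase, the circular predecessor `$`), proper-suffix sources
their dictionary bytes, and the inverted-list order remains the true
suffix order. The ordering argument only needs the dictionary to be
*prefix*-free (no phrase a prefix of another), which does hold under this
scheme — every phrase ends with a content trigger or the unique final
`$^w` window — and is asserted during every build and property-tested.
The degenerate case has a dedicated regression test against the oracle.

## r-index

* **Run-length BWT.** Runs are maximal unary substrings; `rank(c, i)` is a
  binary search over a per-character run directory, `O(log r)` per query.
  No succinct bit-vector machinery — contract-level complexity is enough
  at desk scale.
* **Backward search with toehold.** The state carries `[s, e)` and
  `SA[e−1]`. Stepping with character `c`: if `BWT[e−1] = c` the toehold
  decrements (mod `n`); otherwise it is repaired from the end-sample of
  the last `c`-run below `e` (that run's end is necessarily the last `c`
  in the interval). The initial toehold is the last run's end sample.
* **φ / φ⁻¹.** φ keys are the SA values at run *starts* with the SA entry
  one row above as satellite (the previous run's end sample); φ⁻¹ keys are
  the SA values at run *ends* with the next run's start sample as
  satellite. A predecessor query (largest key ≤ argument, circular
  fallback to the largest key with arithmetic mod `n`) plus an offset
  evaluates either function. The assignment of satellites to run ends for
  φ⁻¹ is the reading that validates against the oracle on worked examples
  (the boundary-set phrasing in the literature is ambiguous on this
  point); both boundary samples are stored, so both directions are
  available. Enumeration proceeds from the toehold upward via φ.
* **locate** returns a sorted list restricted to the input region
  `[0, n − w)`; legal patterns (no `$`/`#`) cannot match in the sentinel
  tail, so the restriction is belt-and-braces. `stats` reports
  `(n, r, n/r)` on the extended text.

## Synthetic collections

`testkit.synth_collection` emulates an intra-species haplotype panel: one
uniform-random base sequence over `{A,C,G,T}`, replicated with independent
per-base substitutions (always to a different base, so the Hamming
distance is exactly Binomial(`n`, rate)), and rare indels (initiation
probability per base; geometric length; insertion or deletion with equal
probability; inserted bases uniform). Defaults — 50 kb base, 10 copies,
substitution rate 10⁻³, indel rate 10⁻⁴, mean indel length 3 — give a
panel whose concatenation builds in seconds while showing the
characteristic behaviour: `n` grows linearly in the number of copies while
`r` stays nearly flat, so `n/r` climbs from ≈1.3 (one copy of random
sequence) to ≈12 at ten copies. The generator does **not** model
transition/transversion bias, mutation hotspots, structural variants or
shared population phylogeny; passing tests demonstrate correctness of the
construction and the qualitative run-compression effect, not realistic
population-genetic structure.

Brute-force oracles (direct suffix sort, cross-checked by an independent
rank-doubling implementation; sliding-window occurrence scan; linear run
decomposition) are deliberately unoptimized and used only at small sizes.

## Problem sizes and numerics

The test suite exercises ~200 random texts of lengths 1–5000 (DNA with
and without `N`) under four trigger policies `(w, p) ∈
{(2,5), (4,11), (10,101), (2,1)}` for oracle equivalence, 500+
text/pattern query cases, and synthetic panels up to 10 × 50 kb; these
sizes keep the whole suite under a minute while covering every code path,
including single-character texts, inputs shorter than `w`, unary texts and
absent patterns. All integer arrays are int64; the container stores them
fixed-width little-endian with a magic/version header and rejects
truncation, foreign magic, version or hash-constant mismatches.

## Known limitations

* In-memory construction only; the one-pass/external-memory engineering
  needed for collections larger than RAM is out of scope, though the
  streaming block emission keeps the `bwt+samples` path away from the full
  SA.
* No generalized suffix array over record boundaries: records are
  concatenated directly, and cross-record phantom matches are filtered at
  locate time instead (a hit whose span crosses an offset boundary is
  dropped).
* Queries are exact-match only over `{A,C,G,T,N}` (reverse-complement hits
  come from indexing both strands at build time, not from query-time
  rc-awareness).
* The index container does not store the sequence, so a reloaded index
  answers count/locate/stats and maps coordinates but cannot re-emit
  record sequences.
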