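# pfbwt

Burrows–Wheeler transform and r-index construction from a **prefix-free
parse**, with exact `count` and `locate` queries — a desk-scale, fully
tested reference implementation aimed at people studying or engineering
compressed full-text indexes for repetitive sequence collections
(pan-genomes, haplotype panels, bacterial isolate databases).

## The problem

The FM-index answers "how often / where does pattern `Q` occur in text
`S`?" from the BWT of `S`, but first you must *build* that BWT, and for a
collection of hundreds of near-identical genomes a direct suffix sort is
the bottleneck. Prefix-free parsing exploits the redundancy: a rolling
hash slides a window of width `w` over `S` and cuts it at *trigger*
windows (Karp–Rabin fingerprint ≡ 0 mod `p`) into overlapping phrases. The
distinct phrases form a dictionary `D`, the phrase-rank sequence a parse
`P`, and on repetitive input `|D| + |P| ≪ |S|`. The BWT — and, crucially,
the suffix-array values sampled at BWT run boundaries — can then be
computed from `D` and `P` alone:

* every suffix of `S` is prefixed by exactly one phrase suffix `α` with
  `|α| > w` (its *representative prefix*), so scanning the suffix array of
  the dictionary string `t₁#t₂#…t_d#` enumerates the blocks of `SA(S)` in
  order;
* within a block, merging per-phrase inverted lists `IL` of positions in
  `BWT(P)` gives the suffix order, the preceding character gives the BWT,
  and the phrase-end positions `EP` give each SA entry as `EP − |α| + 1`.

The run-boundary samples feed an **r-index**: a run-length BWT (`r` runs),
backward search for counting in `O(m)` rank steps, a *toehold* SA value
maintained at the bottom of the search interval, and the predecessor-based
functions

```
φ(SA[j])   = SA[j−1] = satellite(pred(SA[j])) + SA[j] − pred(SA[j])
φ⁻¹(SA[j]) = SA[j+1]   (mirror image over run-end samples)
```

which enumerate all occurrences from the single toehold. Index size scales
with `r`, not `n`; the ratio `n/r` measures how much repetition the BWT
exposes.

## Worked example

```python
from pfbwt import (ExplicitSetPolicy, parse, build, index_from_build)

p = parse("ACGACG", ExplicitSetPolicy(2, {"AC"}))   # w=2, trigger "AC"
print(p.phrases)                    # [b'ACG$$', b'ACGAC']

full = build(p, mode="bwt+sa")
print(full.bwt)                     # b'$GG$AACC'
print(list(full.sa))                # [7, 6, 3, 0, 4, 1, 5, 2]

res = build(p, mode="bwt+samples")  # never materializes the full SA
print(res.samples.r)                # 5
print(res.samples.start_pairs)      # [(0, 7), (1, 6), (3, 0), (4, 4), (6, 5)]

idx = index_from_build(res)
print(idx.count("AC"))              # 2
print(idx.locate("AC"))             # [0, 3]
print(idx.stats())                  # (8, 5, 1.6)   = (n, r, n/r)
```

The text is extended with `w` sentinels (`ACGACG$$`); the two phrases
overlap by `w = 2` characters; the BWT has `r = 5` runs whose boundary SA
values are exactly the sample the r-index needs. `locate` reports the two
occurrences of `AC` at positions 0 and 3.

The same machinery is exposed as a CLI:

```
pfbwt synth -o panel.fa --base-length 50000 --copies 10 --sub-rate 0.001
pfbwt build panel.fa -o panel.pfri -w 10 -p 101 --revcomp
pfbwt stats panel.pfri
pfbwt locate panel.pfri ACGTTAGGCA        # TSV: pattern, record, offset, strand
```

## Layout

| module | contents |
| --- | --- |
| `pfbwt.pfp` | trigger policies, prefix-free parsing, reconstruction |
| `pfbwt.builder` | dictionary/parse suffix arrays, BWT + SA + run-sample construction |
| `pfbwt.rindex` | run-length BWT, backward search with toehold, φ/φ⁻¹ locate |
| `pfbwt.testkit` | brute-force oracles, synthetic haplotype collections |
| `pfbwt.io`, `pfbwt.cli` | FASTA ingestion, index container, coordinate mapping, CLI |

Design notes and the full account of conventions live in
[`docs/methods.md`](docs/methods.md).
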