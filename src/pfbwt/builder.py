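"""BWT / suffix-array / SA-sample construction from a prefix-free parse.

The builder never sorts the suffixes of the text itself.  It sorts (i) the
suffixes of the dictionary string ``t_1#t_2#...t_d#`` and (ii) the suffixes
of the parse (a short sequence of phrase ranks), then merges:

* Every text suffix other than the ``w`` sentinel-only ones is prefixed by
  exactly one phrase suffix ``alpha`` of length ``> w`` (its *representative
  prefix*).  Scanning the dictionary suffix array therefore enumerates the
  blocks of the text suffix array in order.
* Within a block, the relative order of the suffixes sharing ``alpha`` is
  the order of what follows each occurrence, which is exactly the order of
  the corresponding positions in the BWT of the parse.  Per-phrase inverted
  lists ``IL`` of those positions, merged by position, give the block.
* The emitted BWT character is the byte preceding ``alpha``: inside the
  dictionary when ``alpha`` is a proper phrase suffix, or the stored
  text predecessor ``PR`` when ``alpha`` is a whole phrase.  The suffix
  array value is ``EP - |alpha| + 1`` where ``EP`` is the 0-based text end
  position of the phrase occurrence.
* Runs of the BWT are detected on the fly, so the ``bwt+samples`` mode
  emits the r-index sample (SA at every run boundary) without ever
  materializing the full suffix array.

One degenerate case needs care: a phrase that is also a proper suffix of
another phrase.  Under the append-only sentinel convention this can happen
for the first phrase of the text (its leading window is a forced, not a
content, trigger, so other occurrences of the same string do not split).
The merge above handles it uniformly — the whole-phrase source contributes
its ``PR`` characters, the proper-suffix sources their dictionary bytes —
and the inverted-list order remains the true suffix order, because the
dictionary is still prefix-free (no phrase is a *prefix* of another, which
is what the ordering argument needs and what :func:`build` asserts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .pfp import SENTINEL, SEPARATOR, PrefixFreeParse, _as_bytes


def plain_suffix_array(text) -> np.ndarray:
    """Suffix array (plain, non-cyclic lexicographic order) of a byte
    string or integer sequence, by prefix doubling with numpy radix sorts.

    O(n log n) sorts of O(log n) rounds; entirely adequate at desk scale
    and independent of any alphabet assumptions (out-of-range padding
    sorts before every real symbol, giving plain suffix order).
    """
    if isinstance(text, (bytes, bytearray, str)):
        arr = np.frombuffer(_as_bytes(text), dtype=np.uint8).astype(np.int64)
    else:
        arr = np.asarray(text, dtype=np.int64)
    n = len(arr)
    if n == 0:
        raise ValueError("empty text has no suffix array")
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    _, rank = np.unique(arr, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        bumps = np.empty(n, dtype=np.int64)
        bumps[0] = 0
        np.cumsum((r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1]), out=bumps[1:])
        if bumps[-1] == n - 1:
            return order.astype(np.int64)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = bumps
        k *= 2


@dataclass
class DictIndex:
    """The dictionary string and its suffix array."""

    dict_str: bytes
    sa_d: np.ndarray
    phrase_starts: np.ndarray  # start offset of each phrase in dict_str

    @classmethod
    def from_pfp(cls, pfp: PrefixFreeParse) -> "DictIndex":
        sep = bytes([SEPARATOR])
        dict_str = b"".join(t + sep for t in pfp.phrases)
        lens = np.array([len(t) + 1 for t in pfp.phrases], dtype=np.int64)
        starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
        return cls(dict_str=dict_str, sa_d=plain_suffix_array(dict_str),
                   phrase_starts=starts)


@dataclass
class ParseArtifacts:
    """BWT of the parse plus the per-phrase occurrence tables.

    ``il[i]``, ``pr[i]`` and ``ep[i]`` all have length ``occ[i]`` and are
    aligned: the j-th occurrence of phrase ``i`` (in parse-BWT position
    order) sits at parse-BWT position ``il[i][j]``, is preceded in the text
    by byte ``pr[i][j]`` (circularly: the first phrase is preceded by the
    final sentinel), and ends at text position ``ep[i][j]``.
    """

    bwt_p: np.ndarray
    il: list
    pr: list
    ep: list


def parse_bwt(pfp: PrefixFreeParse) -> np.ndarray:
    """BWT of the parse: ranks shifted to 1..d, terminator 0 appended,
    then ``BWT[i] = R[(SA[i]-1) mod len(R)]``."""
    ranks = np.concatenate((pfp.parse + 1, [0])).astype(np.int64)
    sa_p = plain_suffix_array(ranks)
    return ranks[(sa_p - 1) % len(ranks)]


def parse_occurrence_tables(pfp: PrefixFreeParse) -> ParseArtifacts:
    """Inverted lists IL, preceding-character arrays PR and phrase-end
    arrays EP, replacing the parse BWT (which is returned alongside)."""
    ranks = np.concatenate((pfp.parse + 1, [0])).astype(np.int64)
    big_l = len(ranks)
    sa_p = plain_suffix_array(ranks)
    occ_pos = (sa_p - 1) % big_l         # parse position of each BWT_P slot
    bwt_p = ranks[occ_pos]

    ends = pfp.phrase_ends()
    # byte preceding each parse occurrence: phrase q is preceded by the byte
    # just before its start, i.e. the (-w-1)-th byte of phrase q-1; the
    # first phrase is circularly preceded by the final '$'.
    last_char = np.array(
        [t[-pfp.w - 1] for t in pfp.phrases], dtype=np.uint8
    )
    prec = np.empty(len(pfp.parse), dtype=np.uint8)
    prec[0] = SENTINEL
    if len(pfp.parse) > 1:
        prec[1:] = last_char[pfp.parse[:-1]]

    keep = bwt_p > 0                      # drop the terminator slot
    ys = np.flatnonzero(keep)
    phrase_of = bwt_p[ys] - 1
    qs = occ_pos[ys]
    grouped = np.argsort(phrase_of, kind="stable")  # by (phrase, y)
    cuts = np.cumsum(pfp.occ)[:-1]
    il = np.split(ys[grouped], cuts)
    pr = np.split(prec[qs[grouped]], cuts)
    ep = np.split(ends[qs[grouped]], cuts)
    for i in range(pfp.d):
        assert len(il[i]) == pfp.occ[i], "inverted-list length != Occ"
    return ParseArtifacts(bwt_p=bwt_p, il=il, pr=pr, ep=ep)


@dataclass
class RepPrefixGroup:
    """A representative prefix ``alpha`` with its source phrases.

    ``sources`` pairs each phrase id ending with ``alpha`` with a flag
    telling whether ``alpha`` *is* that phrase (whole-phrase occurrence).
    """

    alpha: bytes
    sources: list  # [(phrase_id, is_full_phrase_source), ...]

    @property
    def phrase_ids(self) -> list:
        return [pid for pid, _ in self.sources]

    @property
    def is_full_phrase(self) -> bool:
        return any(full for _, full in self.sources)


def representative_prefixes(dict_index: DictIndex, w: int) -> Iterator[RepPrefixGroup]:
    """Scan the dictionary suffix array and yield, in lexicographic order,
    every distinct phrase suffix longer than ``w`` together with the
    phrases it terminates."""
    ds = dict_index.dict_str
    sa_d = dict_index.sa_d
    starts = dict_index.phrase_starts
    ell = len(ds)
    pos = np.arange(ell, dtype=np.int64)
    pid_of = np.searchsorted(starts, pos, side="right") - 1
    next_starts = np.concatenate((starts[1:], [ell]))
    beta_len = next_starts[pid_of] - 1 - pos  # distance to the phrase's '#'

    cur_alpha = None
    cur_sources: list = []
    for q in sa_d:
        bl = beta_len[q]
        if bl <= w:
            continue
        alpha = ds[q : q + bl]
        pid = int(pid_of[q])
        if alpha == cur_alpha:
            cur_sources.append((pid, q == starts[pid]))
        else:
            if cur_alpha is not None:
                yield RepPrefixGroup(alpha=cur_alpha, sources=cur_sources)
            cur_alpha = alpha
            cur_sources = [(pid, q == starts[pid])]
    if cur_alpha is not None:
        yield RepPrefixGroup(alpha=cur_alpha, sources=cur_sources)


def sentinel_block(last_input_char: int, w: int, n_prime: int):
    """Closed form for the ``w`` sentinel-only suffixes, which open the
    suffix array: the shorter all-'$' suffix sorts first, so the SA prefix
    is ``n'-1, n'-2, ..., n'-w`` and the BWT prefix is ``w-1`` sentinels
    followed by the input's final byte."""
    if w < 1:
        raise ValueError("w must be >= 1")
    sa = np.arange(n_prime - 1, n_prime - w - 1, -1, dtype=np.int64)
    bwt = np.full(w, SENTINEL, dtype=np.uint8)
    bwt[-1] = last_input_char
    return bwt, sa


@dataclass
class RunSamples:
    """SA values at every BWT run boundary: r start-run and r end-run pairs
    of (BWT position, SA value)."""

    start_pos: np.ndarray
    start_sa: np.ndarray
    end_pos: np.ndarray
    end_sa: np.ndarray

    @property
    def r(self) -> int:
        return len(self.start_pos)

    @property
    def start_pairs(self) -> list:
        return list(zip(self.start_pos.tolist(), self.start_sa.tolist()))

    @property
    def end_pairs(self) -> list:
        return list(zip(self.end_pos.tolist(), self.end_sa.tolist()))


@dataclass
class BuildResult:
    """Outputs of :func:`build`; fields absent from the chosen mode are None."""

    n_prime: int
    w: int
    bwt: bytes | None = None
    sa: np.ndarray | None = None
    samples: RunSamples | None = None
    run_heads: np.ndarray | None = None   # head byte of each run
    run_starts: np.ndarray | None = None  # BWT position where each run begins


def _emit_blocks(pfp: PrefixFreeParse) -> Iterator[tuple]:
    """Yield (BWT bytes, SA values) blocks in suffix order: the sentinel
    block first, then one block per representative-prefix group."""
    arts = parse_occurrence_tables(pfp)
    di = DictIndex.from_pfp(pfp)

    # the ordering argument needs a prefix-free dictionary
    for a, b in zip(pfp.phrases, pfp.phrases[1:]):
        assert not b.startswith(a), "dictionary phrase is a prefix of another"

    yield sentinel_block(pfp.last_input_char, pfp.w, pfp.n_prime)

    phrases = pfp.phrases
    for group in representative_prefixes(di, pfp.w):
        la = len(group.alpha)
        if len(group.sources) == 1:
            pid, full = group.sources[0]
            chars = arts.pr[pid] if full else np.full(
                len(arts.il[pid]), phrases[pid][len(phrases[pid]) - la - 1],
                dtype=np.uint8,
            )
            yield chars, arts.ep[pid] - la + 1
        else:
            pos_parts, char_parts, sa_parts = [], [], []
            for pid, full in group.sources:
                pos_parts.append(arts.il[pid])
                sa_parts.append(arts.ep[pid] - la + 1)
                if full:
                    char_parts.append(arts.pr[pid])
                else:
                    c = phrases[pid][len(phrases[pid]) - la - 1]
                    char_parts.append(
                        np.full(len(arts.il[pid]), c, dtype=np.uint8)
                    )
            posv = np.concatenate(pos_parts)
            order = np.argsort(posv)  # positions are distinct: ties impossible
            yield (np.concatenate(char_parts)[order],
                   np.concatenate(sa_parts)[order])


def build(pfp: PrefixFreeParse, mode: str = "bwt+samples") -> BuildResult:
    """Construct outputs of the chosen ``mode`` from the parse.

    mode = "bwt"          : full BWT of the extended text.
    mode = "bwt+sa"       : full BWT and full suffix array.
    mode = "bwt+samples"  : full BWT run structure plus the run-boundary
                            SA sample; the full SA is never materialized.
    """
    if mode not in ("bwt", "bwt+sa", "bwt+samples"):
        raise ValueError(f"unknown mode {mode!r}")
    n_prime = pfp.n_prime

    if mode in ("bwt", "bwt+sa"):
        char_blocks, sa_blocks = [], []
        for chars, sas in _emit_blocks(pfp):
            char_blocks.append(chars)
            sa_blocks.append(sas)
        bwt = np.concatenate(char_blocks)
        assert len(bwt) == n_prime, "emitted blocks do not partition the text"
        result = BuildResult(n_prime=n_prime, w=pfp.w, bwt=bwt.tobytes())
        if mode == "bwt+sa":
            result.sa = np.concatenate(sa_blocks)
        return result

    # streaming run decomposition: keep only run heads and boundary samples
    heads: list = []
    s_pos: list = []
    s_sa: list = []
    e_pos: list = []
    e_sa: list = []
    pos = 0
    prev_char = -1
    prev_sa = -1
    for chars, sas in _emit_blocks(pfp):
        if len(chars) == 0:
            continue
        if pos == 0 or chars[0] != prev_char:
            if pos > 0:
                e_pos.append(pos - 1)
                e_sa.append(prev_sa)
            heads.append(int(chars[0]))
            s_pos.append(pos)
            s_sa.append(int(sas[0]))
        inner = np.flatnonzero(chars[1:] != chars[:-1])
        for i in inner:
            e_pos.append(pos + int(i))
            e_sa.append(int(sas[i]))
            heads.append(int(chars[i + 1]))
            s_pos.append(pos + int(i) + 1)
            s_sa.append(int(sas[i + 1]))
        prev_char = int(chars[-1])
        prev_sa = int(sas[-1])
        pos += len(chars)
    assert pos == n_prime, "emitted blocks do not partition the text"
    e_pos.append(n_prime - 1)
    e_sa.append(prev_sa)

    samples = RunSamples(
        start_pos=np.array(s_pos, dtype=np.int64),
        start_sa=np.array(s_sa, dtype=np.int64),
        end_pos=np.array(e_pos, dtype=np.int64),
        end_sa=np.array(e_sa, dtype=np.int64),
    )
    return BuildResult(
        n_prime=n_prime,
        w=pfp.w,
        samples=samples,
        run_heads=np.array(heads, dtype=np.uint8),
        run_starts=samples.start_pos.copy(),
    )
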