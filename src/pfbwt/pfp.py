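"""Prefix-free parsing of a text into a dictionary and a parse.

A window of fixed width ``w`` slides over the input; positions where the
window is a *trigger* (its Karp-Rabin fingerprint is 0 modulo a small
modulus ``p``, or a forced first/last window) delimit overlapping phrases.
The distinct phrases, in lexicographic order, form the dictionary ``D``;
the sequence of phrase ranks in text order forms the parse ``P``.  On
repetitive inputs (e.g. pan-genome collections) the same phrases recur, so
``|D| + |P|`` is far smaller than the text, and the BWT and suffix-array
sample of the text can be built from ``D`` and ``P`` alone (see
:mod:`pfbwt.builder`).

Conventions
-----------
* The alphabet is ordered ``'#' < '$' < 'A' < 'C' < 'G' < 'N' < 'T'``
  (plain byte order); ``'#'`` and ``'$'`` are reserved and rejected in
  input.  Arbitrary bytes above ``'$'`` are accepted for generic tests.
* Exactly ``w`` copies of the sentinel ``'$'`` are appended to the input;
  every downstream object (suffix array, BWT, r-index) is defined over the
  extended text ``S' = S + '$'*w`` of length ``n' = n + w``.
* All coordinates are 0-based; intervals are half-open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

SEPARATOR = 0x23  # '#', below every other legal byte
SENTINEL = 0x24   # '$', below all data bytes, above '#'

#: Karp-Rabin fingerprint parameters (build-time constants, recorded in the
#: index header): polynomial base and large Mersenne prime modulus.
KR_BASE = 256
KR_PRIME = (1 << 61) - 1


class AlphabetError(ValueError):
    """Input contains a reserved or out-of-order byte ('#', '$' or below)."""


class CorruptParseError(ValueError):
    """A parse references a phrase rank outside the dictionary."""


def _as_bytes(text) -> bytes:
    if isinstance(text, str):
        return text.encode("ascii")
    return bytes(text)


class TriggerPolicy:
    """Decides which length-``w`` windows delimit phrases.

    Deciding a window is a pure function of its ``w`` bytes; the first and
    last windows of the extended text are forced triggers regardless of the
    policy.
    """

    w: int

    def is_trigger(self, window: bytes) -> bool:
        raise NotImplementedError

    def trigger_positions(self, s_ext: bytes) -> list[int]:
        """Sorted trigger positions in ``s_ext``, including the forced
        first (0) and last (``len(s_ext) - w``) windows."""
        w = self.w
        last = len(s_ext) - w
        positions = {0, last}
        is_trigger = self.is_trigger
        for s in range(1, last):
            if is_trigger(s_ext[s : s + w]):
                positions.add(s)
        return sorted(positions)


@dataclass(frozen=True)
class ExplicitSetPolicy(TriggerPolicy):
    """Trigger iff the window is in a fixed set (test/teaching mode only)."""

    w: int
    windows: frozenset = frozenset()

    def __init__(self, w: int, windows) -> None:
        if w < 1:
            raise ValueError("window size w must be >= 1")
        ws = frozenset(_as_bytes(x) for x in windows)
        for win in ws:
            if len(win) != w:
                raise ValueError(f"trigger window {win!r} does not have length {w}")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "windows", ws)

    def is_trigger(self, window: bytes) -> bool:
        window = _as_bytes(window)
        if len(window) != self.w:
            raise ValueError(f"window has length {len(window)}, expected {self.w}")
        return window in self.windows


@dataclass(frozen=True)
class RollingHashPolicy(TriggerPolicy):
    """Trigger iff the Karp-Rabin fingerprint of the window is 0 mod ``p``.

    The fingerprint of a window ``c_0 .. c_{w-1}`` is
    ``sum(c_j * KR_BASE**(w-1-j)) mod KR_PRIME``; the window triggers when
    that value is divisible by ``p``.  ``p = 1`` makes every window a
    trigger (a useful stress case: phrases degenerate to length ``w+1``).
    """

    w: int
    p: int

    def __init__(self, w: int, p: int) -> None:
        if w < 1:
            raise ValueError("window size w must be >= 1")
        if p < 1:
            raise ValueError("modulus p must be >= 1")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "p", p)

    def fingerprint(self, window: bytes) -> int:
        window = _as_bytes(window)
        if len(window) != self.w:
            raise ValueError(f"window has length {len(window)}, expected {self.w}")
        h = 0
        for c in window:
            h = (h * KR_BASE + c) % KR_PRIME
        return h

    def is_trigger(self, window: bytes) -> bool:
        return self.fingerprint(window) % self.p == 0

    def trigger_positions(self, s_ext: bytes) -> list[int]:
        # incremental add-one-drop-one update of the fingerprint
        w, p = self.w, self.p
        last = len(s_ext) - w
        positions = {0, last}
        h = self.fingerprint(s_ext[:w])
        drop = pow(KR_BASE, w - 1, KR_PRIME)
        for s in range(1, last):
            h = ((h - s_ext[s - 1] * drop) * KR_BASE + s_ext[s + w - 1]) % KR_PRIME
            if h % p == 0:
                positions.add(s)
        return sorted(positions)


def is_trigger(window, policy: TriggerPolicy) -> bool:
    """Whether ``window`` (length ``policy.w``) delimits phrases."""
    return policy.is_trigger(_as_bytes(window))


@dataclass
class PrefixFreeParse:
    """Dictionary + parse of the sentinel-extended text.

    Attributes
    ----------
    phrases : list[bytes]
        Distinct phrases in strict lexicographic order.
    parse : np.ndarray
        0-based phrase ranks covering ``S' = input + '$'*w`` in text order.
    occ : np.ndarray
        Occurrence count of each phrase in the parse.
    w : int
        Window size; consecutive phrases overlap by exactly ``w`` bytes.
    n_prime : int
        Length of the extended text.
    last_input_char : int
        Final byte of the raw input (needed for the sentinel block of the
        BWT, where the shortest all-'$' suffixes sort first).
    """

    phrases: list
    parse: np.ndarray
    occ: np.ndarray
    w: int
    n_prime: int
    last_input_char: int
    policy: TriggerPolicy | None = field(default=None, repr=False)

    @property
    def d(self) -> int:
        return len(self.phrases)

    def validate(self) -> None:
        w = self.w
        assert all(len(t) > w for t in self.phrases), "phrase no longer than w"
        assert self.phrases == sorted(set(self.phrases)), "phrases not sorted/distinct"
        total = len(self.phrases[self.parse[0]]) + sum(
            len(self.phrases[r]) - w for r in self.parse[1:]
        )
        assert total == self.n_prime, "phrase-length law violated"
        counts = Counter(int(r) for r in self.parse)
        assert all(counts[j] == self.occ[j] for j in range(self.d))
        assert int(self.occ.sum()) == len(self.parse)

    def phrase_ends(self) -> np.ndarray:
        """0-based end position in S' of each parse occurrence (EP source)."""
        lens = np.array([len(self.phrases[r]) for r in self.parse], dtype=np.int64)
        lens[1:] -= self.w
        return np.cumsum(lens) - 1


def parse(text, policy: TriggerPolicy) -> PrefixFreeParse:
    """One-pass prefix-free parse of ``text`` under ``policy``.

    Appends ``w`` sentinels, finds trigger positions
    ``s_1 < ... < s_k`` (forced first/last included), and cuts the phrases
    ``S'[s_i : s_{i+1} + w]``, which overlap pairwise by ``w`` bytes.
    """
    data = _as_bytes(text)
    if len(data) == 0:
        raise ValueError("cannot parse an empty text")
    if min(data) <= SENTINEL:
        raise AlphabetError(
            "input must not contain '#', '$' or any byte below them"
        )
    w = policy.w
    s_ext = data + bytes([SENTINEL]) * w
    n_prime = len(s_ext)

    triggers = policy.trigger_positions(s_ext)
    raw_phrases = [
        s_ext[triggers[i] : triggers[i + 1] + w] for i in range(len(triggers) - 1)
    ]
    if not raw_phrases:  # single forced window pair collapsed (cannot happen: n >= 1)
        raw_phrases = [s_ext]

    phrases = sorted(set(raw_phrases))
    rank = {t: j for j, t in enumerate(phrases)}
    parse_arr = np.fromiter((rank[t] for t in raw_phrases), dtype=np.int64)
    occ = np.bincount(parse_arr, minlength=len(phrases)).astype(np.int64)

    pfp = PrefixFreeParse(
        phrases=phrases,
        parse=parse_arr,
        occ=occ,
        w=w,
        n_prime=n_prime,
        last_input_char=data[-1],
        policy=policy,
    )
    return pfp


def reconstruct(pfp: PrefixFreeParse) -> bytes:
    """Inverse of :func:`parse`: re-expand the phrases (dropping the
    ``w``-byte overlap after the first) and strip the trailing sentinels."""
    out = bytearray()
    for i, r in enumerate(pfp.parse):
        if r < 0 or r >= pfp.d:
            raise CorruptParseError(f"phrase rank {r} out of range 0..{pfp.d - 1}")
        t = pfp.phrases[int(r)]
        out.extend(t if i == 0 else t[pfp.w :])
    if len(out) != pfp.n_prime:
        raise CorruptParseError("expansion length does not match n_prime")
    return bytes(out[: -pfp.w])


def dict_string(pfp: PrefixFreeParse) -> bytes:
    """The dictionary string ``t_1 # t_2 # ... t_d #`` (phrases in
    lexicographic order, each terminated by the separator)."""
    sep = bytes([SEPARATOR])
    return b"".join(t + sep for t in pfp.phrases)
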