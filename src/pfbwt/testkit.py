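"""Brute-force oracles and a synthetic pan-genome generator.

Everything here is deliberately simple and independent of the construction
path in :mod:`pfbwt.builder` / :mod:`pfbwt.rindex`: direct suffix sorting,
sliding-window pattern scans, and run decomposition by linear scan.  The
oracles are quadratic-ish and meant for small inputs only.

The synthetic generator emulates a haplotype collection: one random base
sequence replicated ``m`` times with independent low-rate substitutions
and short indels, the regime in which the BWT run count ``r`` grows far
slower than the text length ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pfp import _as_bytes

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


def naive_sa(text) -> list:
    """Suffix array by direct comparison sort of all suffixes."""
    t = _as_bytes(text)
    if len(t) == 0:
        raise ValueError("empty text")
    return sorted(range(len(t)), key=lambda i: t[i:])


def naive_sa_doubling(text) -> list:
    """Second, independent suffix-array method (pure-python rank doubling)
    used only to cross-validate :func:`naive_sa`."""
    t = _as_bytes(text)
    n = len(t)
    rank = list(t)
    k = 1
    sa = list(range(n))
    while True:
        key = lambda i: (rank[i], rank[i + k] if i + k < n else -1)
        sa.sort(key=key)
        new = [0] * n
        for j in range(1, n):
            new[sa[j]] = new[sa[j - 1]] + (key(sa[j]) != key(sa[j - 1]))
        rank = new
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


def naive_bwt(text) -> bytes:
    """BWT by the definition BWT[i] = S[(SA[i] - 1) mod n]."""
    t = _as_bytes(text)
    sa = naive_sa(t)
    n = len(t)
    return bytes(t[(i - 1) % n] for i in sa)


def naive_occurrences(text, pattern) -> list:
    """All start positions of ``pattern`` in ``text`` by sliding window."""
    t, p = _as_bytes(text), _as_bytes(pattern)
    if len(p) == 0:
        raise ValueError("empty pattern")
    out = []
    i = t.find(p)
    while i != -1:
        out.append(i)
        i = t.find(p, i + 1)
    return out


def run_decomposition(bwt):
    """Maximal equal-character runs of a string.

    Returns ``(runs, starts, ends)`` where ``runs`` is a list of
    ``(char, start, end)`` with inclusive ends.
    """
    b = _as_bytes(bwt)
    if len(b) == 0:
        raise ValueError("empty string")
    runs = []
    start = 0
    for i in range(1, len(b)):
        if b[i] != b[i - 1]:
            runs.append((b[start], start, i - 1))
            start = i
    runs.append((b[start], start, len(b) - 1))
    starts = [s for _, s, _ in runs]
    ends = [e for _, _, e in runs]
    return runs, starts, ends


@dataclass
class SynthConfig:
    """Parameters of the synthetic haplotype collection.

    Defaults mirror a small intra-species panel: 50 kb haplotypes at one
    substitution per kilobase and rare short indels — enough sequence for
    the run-length statistics to behave, small enough to build in seconds.
    """

    base_length: int = 50_000
    copies: int = 10
    sub_rate: float = 0.001
    indel_rate: float = 0.0001
    indel_mean_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.base_length < 1 or self.copies < 1:
            raise ValueError("base_length and copies must be >= 1")


def _mutate(base: np.ndarray, cfg: SynthConfig, rng) -> bytes:
    seq = base.copy()
    # substitutions: always to one of the three *other* bases
    hit = np.flatnonzero(rng.random(len(seq)) < cfg.sub_rate)
    if len(hit) > 0:
        base_idx = np.searchsorted(_DNA, seq[hit])
        shift = rng.integers(1, 4, size=len(hit))
        seq[hit] = _DNA[(base_idx + shift) % 4]
    # indels: initiation sites with geometric lengths, deletion or
    # insertion with equal probability
    sites = np.flatnonzero(rng.random(len(seq)) < cfg.indel_rate)
    if len(sites) == 0:
        return seq.tobytes()
    pieces = []
    prev = 0
    p_geo = min(1.0, 1.0 / max(cfg.indel_mean_len, 1.0))
    for s in sites:
        if s < prev:
            continue
        length = int(rng.geometric(p_geo))
        pieces.append(seq[prev:s])
        if rng.random() < 0.5:  # deletion
            prev = min(len(seq), s + length)
        else:  # insertion
            pieces.append(_DNA[rng.integers(0, 4, size=length)])
            prev = s
    pieces.append(seq[prev:])
    return np.concatenate(pieces).tobytes()


def synth_collection(config: SynthConfig) -> list:
    """Generate ``(name, sequence)`` records: one base haplotype plus
    ``copies - 1`` mutated derivatives.  Deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    base = _DNA[rng.integers(0, 4, size=config.base_length)]
    records = [("hap0", base.tobytes())]
    for i in range(1, config.copies):
        records.append((f"hap{i}", _mutate(base, config, rng)))
    return records
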