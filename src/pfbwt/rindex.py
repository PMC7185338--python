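"""The r-index: run-length BWT + run-boundary SA samples.

Counting is plain FM-index backward search over the run-length-compressed
BWT (rank by binary search on run boundaries, O(log r) per step).  Locating
uses the *toehold* technique: backward search additionally maintains the
suffix-array value of the last row of the current interval, repaired from
the per-run end samples whenever the interval's bottom character changes.
Once a pattern's interval [s, e) and SA[e-1] are known, the remaining
occurrences are enumerated with the phi function

    phi(SA[j]) = SA[j-1] = satellite(pred(SA[j])) + SA[j] - pred(SA[j])

where pred is a predecessor query over the SA values sampled at run
*starts* and the satellite of such a key is the SA entry just above it
(i.e. the previous run's end sample); phi_inv is the mirror image over run
*end* samples.  Both are circular: a query below the smallest key wraps to
the largest, with arithmetic modulo n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import BuildResult, RunSamples
from .pfp import SENTINEL, _as_bytes


class QueryError(ValueError):
    """Pattern contains a reserved byte or is empty."""


class BuildError(ValueError):
    """Samples inconsistent with the BWT run structure."""


@dataclass
class RunLengthBWT:
    """BWT stored as maximal runs of equal characters.

    ``run_heads[i]`` is the character of run ``i``, which occupies BWT
    positions ``[run_starts[i], run_starts[i] + run_lens[i])``; ``c_table``
    maps each byte to the number of strictly smaller BWT characters.
    """

    run_heads: np.ndarray
    run_starts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        heads = np.asarray(self.run_heads, dtype=np.uint8)
        starts = np.asarray(self.run_starts, dtype=np.int64)
        if len(heads) != len(starts) or len(heads) == 0:
            raise BuildError("run arrays empty or of unequal length")
        if starts[0] != 0 or np.any(np.diff(starts) <= 0):
            raise BuildError("run starts must be strictly increasing from 0")
        if np.any(heads[1:] == heads[:-1]):
            raise BuildError("adjacent runs with equal head are not maximal")
        self.run_heads = heads
        self.run_starts = starts
        self.run_lens = np.diff(np.concatenate((starts, [self.n])))
        if self.run_lens[-1] <= 0:
            raise BuildError("n smaller than the last run start")
        counts = np.bincount(heads, weights=self.run_lens, minlength=256)
        self.c_table = np.concatenate(([0], np.cumsum(counts)[:-1])).astype(
            np.int64
        )
        # per-character run directory for O(log r) rank
        self._char_runs: dict = {}
        for c in np.unique(heads):
            idx = np.flatnonzero(heads == c)
            lens = self.run_lens[idx]
            self._char_runs[int(c)] = (
                idx,
                self.run_starts[idx],
                np.concatenate(([0], np.cumsum(lens))),
            )

    @classmethod
    def from_bwt(cls, bwt) -> "RunLengthBWT":
        data = np.frombuffer(_as_bytes(bwt), dtype=np.uint8)
        if len(data) == 0:
            raise BuildError("empty BWT")
        starts = np.concatenate(
            ([0], np.flatnonzero(data[1:] != data[:-1]) + 1)
        ).astype(np.int64)
        return cls(run_heads=data[starts], run_starts=starts, n=len(data))

    @property
    def r(self) -> int:
        return len(self.run_heads)

    def run_of(self, i: int) -> int:
        """Index of the run covering BWT position ``i``."""
        return int(np.searchsorted(self.run_starts, i, side="right") - 1)

    def char_at(self, i: int) -> int:
        return int(self.run_heads[self.run_of(i)])

    def rank(self, c: int, i: int) -> int:
        """Number of occurrences of byte ``c`` in ``BWT[0:i)``."""
        if not 0 <= i <= self.n:
            raise IndexError(f"rank position {i} outside [0, {self.n}]")
        entry = self._char_runs.get(int(c))
        if entry is None:
            return 0
        idx, starts, cum = entry
        j = int(np.searchsorted(starts, i, side="left"))  # runs starting < i
        if j == 0:
            return 0
        k = idx[j - 1]
        partial = min(int(self.run_lens[k]), i - int(self.run_starts[k]))
        return int(cum[j - 1]) + partial

    def last_run_of_before(self, c: int, e: int) -> int | None:
        """Index of the last run of ``c`` starting strictly before ``e-1``,
        or None.  When BWT[e-1] != c, this run's end is the last
        occurrence of ``c`` below ``e``."""
        entry = self._char_runs.get(int(c))
        if entry is None:
            return None
        idx, starts, _ = entry
        j = int(np.searchsorted(starts, e - 1, side="left"))
        return None if j == 0 else int(idx[j - 1])


@dataclass
class SearchState:
    """Backward-search interval [s, e) plus the toehold SA[e-1]."""

    s: int
    e: int
    toehold: int | None

    @property
    def empty(self) -> bool:
        return self.s >= self.e

    @property
    def width(self) -> int:
        return max(0, self.e - self.s)


class RIndex:
    """Queryable r-index over the sentinel-extended text of length ``n``.

    ``n_text`` is the length of the raw input region; locate results are
    restricted to it (legal patterns cannot reach the sentinel tail).
    """

    def __init__(self, rlbwt: RunLengthBWT, samples: RunSamples,
                 w: int = 0, n_text: int | None = None) -> None:
        if samples.r != rlbwt.r:
            raise BuildError(
                f"sample run count {samples.r} != BWT run count {rlbwt.r}"
            )
        run_ends = rlbwt.run_starts + rlbwt.run_lens - 1
        if (np.any(samples.start_pos != rlbwt.run_starts)
                or np.any(samples.end_pos != run_ends)):
            raise BuildError("sample positions do not match run boundaries")
        self.rlbwt = rlbwt
        self.samples = samples
        self.n = rlbwt.n
        self.w = w
        self.n_text = self.n - w if n_text is None else n_text
        self.run_end_sa = samples.end_sa

        # phi: keys = SA at run starts, satellite = SA one row above
        #      (= the previous run's end sample, circular at the top row)
        sat_above = np.roll(samples.end_sa, 1)
        order = np.argsort(samples.start_sa)
        self._phi_keys = samples.start_sa[order]
        self._phi_sat = sat_above[order]
        # phi_inv: keys = SA at run ends, satellite = SA one row below
        #      (= the next run's start sample, circular at the bottom row)
        sat_below = np.roll(samples.start_sa, -1)
        order = np.argsort(samples.end_sa)
        self._phi_inv_keys = samples.end_sa[order]
        self._phi_inv_sat = sat_below[order]

    # -- phi machinery ----------------------------------------------------
    def _pred_apply(self, keys: np.ndarray, sats: np.ndarray, pos: int) -> int:
        i = int(np.searchsorted(keys, pos, side="right")) - 1
        if i < 0:  # below the smallest key: wrap to the largest, mod n
            i = len(keys) - 1
        off = (pos - int(keys[i])) % self.n
        return (int(sats[i]) + off) % self.n

    def phi(self, pos: int) -> int:
        """SA value one row above the row holding SA value ``pos``."""
        return self._pred_apply(self._phi_keys, self._phi_sat, pos)

    def phi_inv(self, pos: int) -> int:
        """SA value one row below the row holding SA value ``pos``."""
        return self._pred_apply(self._phi_inv_keys, self._phi_inv_sat, pos)

    # -- backward search --------------------------------------------------
    def initial_state(self) -> SearchState:
        return SearchState(0, self.n, int(self.run_end_sa[-1]))

    def backward_step(self, state: SearchState, c: int) -> SearchState:
        """Extend the matched pattern by ``c`` on the left."""
        if state.empty:
            return SearchState(0, 0, None)
        rl = self.rlbwt
        c = ord(c) if isinstance(c, str) else int(c)
        s2 = int(rl.c_table[c]) + rl.rank(c, state.s)
        e2 = int(rl.c_table[c]) + rl.rank(c, state.e)
        if s2 >= e2:
            return SearchState(0, 0, None)
        if rl.char_at(state.e - 1) == c:
            toe = (state.toehold - 1) % self.n
        else:
            k = rl.last_run_of_before(c, state.e)
            toe = (int(self.run_end_sa[k]) - 1) % self.n
        return SearchState(s2, e2, toe)

    def _search(self, pattern) -> SearchState:
        pat = _as_bytes(pattern)
        if len(pat) == 0:
            raise QueryError("empty pattern")
        if min(pat) <= SENTINEL:
            raise QueryError("pattern contains a reserved byte ('#'/'$')")
        state = self.initial_state()
        for c in reversed(pat):
            state = self.backward_step(state, c)
            if state.empty:
                break
        return state

    def count(self, pattern) -> int:
        """Number of occurrences of ``pattern`` in the indexed text."""
        return self._search(pattern).width

    def locate(self, pattern) -> list:
        """Sorted start positions of all occurrences of ``pattern``."""
        state = self._search(pattern)
        if state.empty:
            return []
        vals = [state.toehold]
        cur = state.toehold
        for _ in range(state.width - 1):
            cur = self.phi(cur)
            vals.append(cur)
        return sorted(v for v in vals if v < self.n_text)

    def stats(self) -> tuple:
        """(n, r, n/r): text length, BWT run count, compression ratio."""
        return self.n, self.rlbwt.r, self.n / self.rlbwt.r


def build_rindex(bwt, samples: RunSamples, w: int = 0,
                 n_text: int | None = None) -> RIndex:
    """Assemble an :class:`RIndex` from a BWT (bytes, or precomputed run
    arrays as ``(heads, starts, n)``) and its run-boundary samples."""
    if isinstance(bwt, RunLengthBWT):
        rl = bwt
    elif isinstance(bwt, tuple):
        heads, starts, n = bwt
        rl = RunLengthBWT(run_heads=heads, run_starts=starts, n=n)
    else:
        rl = RunLengthBWT.from_bwt(bwt)
    return RIndex(rl, samples, w=w, n_text=n_text)


def index_from_build(result: BuildResult, n_text: int | None = None) -> RIndex:
    """Shortcut from a builder ``bwt+samples`` result to a queryable index."""
    if result.samples is None or result.run_heads is None:
        raise BuildError("build result lacks samples; use mode='bwt+samples'")
    return build_rindex(
        (result.run_heads, result.run_starts, result.n_prime),
        result.samples, w=result.w, n_text=n_text,
    )
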