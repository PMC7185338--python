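"""FASTA ingestion, genome-coordinate mapping, and the index container.

Preprocessing follows the usual pan-genome indexing conventions: sequences
are uppercased, every character outside {A, C, G, T, N} is removed, and
records are concatenated directly in file order (no separator — phantom
matches spanning a record boundary are filtered at locate time).
Optionally the reverse complement of every record is appended as an
additional record so that both strands are findable at query time.

The index container is a small versioned binary format holding the
run-length BWT, the run-boundary SA samples and the record table; it does
NOT store the sequence itself (the index is the compressed representation).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .builder import RunSamples
from .pfp import KR_BASE, KR_PRIME
from .rindex import RIndex, build_rindex

_KEEP = b"ACGTN"
_DELETE = bytes(c for c in range(256) if c not in _KEEP)
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

MAGIC = b"PFRX"
FORMAT_VERSION = 1


class InputError(ValueError):
    """Empty or malformed input file."""


class FormatError(ValueError):
    """Bad magic, unsupported version, or truncated index container."""


@dataclass
class Collection:
    """A concatenated, filtered sequence collection.

    ``names``/``lengths`` have one entry per stored record; when
    ``revcomp_included``, the second half of the records are the reverse
    complements of the first half (same names, minus strand).  ``concat``
    is None for collections reloaded from an index container.
    """

    names: list
    lengths: np.ndarray
    revcomp_included: bool
    concat: bytes | None = None
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.offsets = np.concatenate(
            ([0], np.cumsum(self.lengths)[:-1])
        ).astype(np.int64)

    @property
    def n_fwd(self) -> int:
        return len(self.names) // 2 if self.revcomp_included else len(self.names)

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1] + self.lengths[-1])


def filter_sequence(seq) -> bytes:
    """Uppercase and drop every byte outside {A, C, G, T, N}."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return bytes(seq).upper().translate(None, _DELETE)


def reverse_complement(seq: bytes) -> bytes:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path, include_revcomp: bool = False) -> Collection:
    """Read a FASTA file into a :class:`Collection`.

    Records are filtered, concatenated in file order and, when requested,
    followed by their reverse complements in the same order.
    """
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(filter_sequence(str(rec.seq)))
    if not names:
        raise InputError(f"no FASTA records in {path}")
    if include_revcomp:
        names = names + names
        seqs = seqs + [reverse_complement(s) for s in seqs]
    if sum(len(s) for s in seqs) == 0:
        raise InputError(f"records in {path} contain no A/C/G/T/N characters")
    return Collection(
        names=names,
        lengths=np.array([len(s) for s in seqs], dtype=np.int64),
        revcomp_included=include_revcomp,
        concat=b"".join(seqs),
    )


def collection_from_records(records, include_revcomp: bool = False) -> Collection:
    """Build a :class:`Collection` from in-memory ``(name, bytes)`` records
    (e.g. from :func:`pfbwt.testkit.synth_collection`)."""
    names = [n for n, _ in records]
    seqs = [filter_sequence(s) for _, s in records]
    if include_revcomp:
        names = names + names
        seqs = seqs + [reverse_complement(s) for s in seqs]
    return Collection(
        names=names,
        lengths=np.array([len(s) for s in seqs], dtype=np.int64),
        revcomp_included=include_revcomp,
        concat=b"".join(seqs),
    )


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            if isinstance(seq, bytes):
                seq = seq.decode("ascii")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def map_position(collection: Collection, text_pos: int):
    """Map a concatenated-text position to ``(record name, offset, strand)``.

    Positions in the sentinel tail (at or beyond the concatenated length)
    are out of range.
    """
    if not 0 <= text_pos < collection.total_length:
        raise IndexError(
            f"position {text_pos} outside the input region "
            f"[0, {collection.total_length})"
        )
    rec = int(np.searchsorted(collection.offsets, text_pos, side="right") - 1)
    strand = "-" if rec >= collection.n_fwd else "+"
    return collection.names[rec], int(text_pos - collection.offsets[rec]), strand


def locate_in_collection(index: RIndex, collection: Collection, pattern):
    """Locate a pattern and report genome coordinates.

    Returns sorted ``(name, offset, strand)`` tuples; hits whose span
    crosses a record boundary (artifacts of direct concatenation) are
    dropped.
    """
    m = len(pattern)
    hits = []
    for pos in index.locate(pattern):
        rec = int(np.searchsorted(collection.offsets, pos, side="right") - 1)
        if pos + m > collection.offsets[rec] + collection.lengths[rec]:
            continue  # phantom match across a record boundary
        strand = "-" if rec >= collection.n_fwd else "+"
        hits.append(
            (collection.names[rec], int(pos - collection.offsets[rec]), strand)
        )
    return hits


# ---------------------------------------------------------------------------
# index container

_HEADER = struct.Struct("<4sHHQQQQQQ")  # magic, version, w, base, prime, p, n, n_text, r


def save_index(index: RIndex, collection: Collection | None, path,
               hash_modulus: int = 0) -> None:
    """Serialize the r-index (+ record table) to a versioned container.

    Integer arrays are fixed-width little-endian; the header records the
    window size and the rolling-hash parameters used at build time.
    """
    rl = index.rlbwt
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, FORMAT_VERSION, index.w, KR_BASE,
                              KR_PRIME, hash_modulus, index.n, index.n_text,
                              rl.r))
        fh.write(rl.run_heads.astype("<u1").tobytes())
        fh.write(rl.run_starts.astype("<u8").tobytes())
        fh.write(index.samples.start_sa.astype("<u8").tobytes())
        fh.write(index.samples.end_sa.astype("<u8").tobytes())
        if collection is None:
            fh.write(struct.pack("<B", 0))
        else:
            fh.write(struct.pack("<BBQ", 1, int(collection.revcomp_included),
                                 len(collection.names)))
            for name, length in zip(collection.names, collection.lengths):
                raw = name.encode("utf-8")
                fh.write(struct.pack("<H", len(raw)))
                fh.write(raw)
                fh.write(struct.pack("<Q", int(length)))


def _read_exact(fh, size: int) -> bytes:
    data = fh.read(size)
    if len(data) != size:
        raise FormatError("truncated index container")
    return data


def load_index(path):
    """Load a container; returns ``(RIndex, Collection | None)``."""
    with open(path, "rb") as fh:
        header = _read_exact(fh, _HEADER.size)
        magic, version, w, base, prime, _p, n, n_text, r = _HEADER.unpack(header)
        if magic != MAGIC:
            raise FormatError(f"bad magic {magic!r}")
        if version != FORMAT_VERSION:
            raise FormatError(f"unsupported container version {version}")
        if base != KR_BASE or prime != KR_PRIME:
            raise FormatError("index built with different hash constants")
        heads = np.frombuffer(_read_exact(fh, r), dtype="<u1")
        starts = np.frombuffer(_read_exact(fh, 8 * r), dtype="<u8").astype(np.int64)
        start_sa = np.frombuffer(_read_exact(fh, 8 * r), dtype="<u8").astype(np.int64)
        end_sa = np.frombuffer(_read_exact(fh, 8 * r), dtype="<u8").astype(np.int64)
        run_lens = np.diff(np.concatenate((starts, [n])))
        samples = RunSamples(
            start_pos=starts.copy(),
            start_sa=start_sa,
            end_pos=(starts + run_lens - 1),
            end_sa=end_sa,
        )
        index = build_rindex((heads, starts, int(n)), samples, w=int(w),
                             n_text=int(n_text))
        (has_coll,) = struct.unpack("<B", _read_exact(fh, 1))
        collection = None
        if has_coll:
            rc_flag, nrec = struct.unpack("<BQ", _read_exact(fh, 9))
            names, lengths = [], []
            for _ in range(nrec):
                (nlen,) = struct.unpack("<H", _read_exact(fh, 2))
                names.append(_read_exact(fh, nlen).decode("utf-8"))
                (length,) = struct.unpack("<Q", _read_exact(fh, 8))
                lengths.append(length)
            collection = Collection(
                names=names,
                lengths=np.array(lengths, dtype=np.int64),
                revcomp_included=bool(rc_flag),
                concat=None,
            )
    return index, collection
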