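"""FM-index over a concatenated genome database.

The database sequences are concatenated with ``#`` separators and a single
terminal ``$`` sentinel.  The Burrows-Wheeler transform is computed from a
suffix array built by prefix doubling (numpy ``lexsort`` rounds), the
occurrence table is checkpointed every :data:`OCC_BLOCK` symbols, and locate
queries walk the LF mapping to the nearest stride-sampled suffix-array entry.

Separator characters compare smaller than any base and never match a query,
so exact matches cannot span sequence boundaries.  Query patterns are DNA
over ``{A, C, G, T}``; an ``N`` in either the pattern or the database never
matches anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import GenomeRecord

ALPHABET = "$#ACGNT"  # code order == sort order
SIGMA = len(ALPHABET)
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_BASE_CODES = frozenset(_CODE[c] for c in "ACGT")

_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _ENCODE_TABLE[ord(_c)] = _i

OCC_BLOCK = 128  # occurrence-table checkpoint spacing
DEFAULT_SA_STRIDE = 16

FORMAT_VERSION = 1


@dataclass(frozen=True)
class SaRange:
    """Half-open suffix-array interval for a matched pattern."""

    low: int
    high: int
    pattern_length: int = 0

    @property
    def size(self) -> int:
        return self.high - self.low

    @property
    def empty(self) -> bool:
        return self.high <= self.low


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling; O(n log^2 n) with numpy sorts."""
    n = codes.size
    rank = codes.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    if n == 1:
        return order
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_ord = rank[order]
        k2_ord = key2[order]
        diff = np.empty(n, dtype=bool)
        diff[0] = True
        diff[1:] = (r_ord[1:] != r_ord[:-1]) | (k2_ord[1:] != k2_ord[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(diff) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


def encode(seq: str) -> np.ndarray:
    codes = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 255):
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"sequence contains non-indexable character {bad!r}")
    return codes


class FmIndex:
    """BWT + occurrence table + sampled suffix array over a genome database."""

    def __init__(
        self,
        bwt: np.ndarray,
        counts: np.ndarray,
        occ_checkpoints: np.ndarray,
        sa_samples: np.ndarray,
        sa_stride: int,
        seq_ids: Sequence[str],
        seq_starts: np.ndarray,
        seq_lengths: np.ndarray,
    ):
        self.bwt = bwt
        self.counts = counts  # counts[c] = number of symbols < c in the text
        self._occ = occ_checkpoints
        self._samples = sa_samples  # -1 where unsampled, else SA value
        self.sa_stride = int(sa_stride)
        self.seq_ids = list(seq_ids)
        self._starts = seq_starts
        self._lengths = seq_lengths
        self.n = int(bwt.size)

    # -- construction ------------------------------------------------------
    @classmethod
    def build(
        cls, records: Sequence[GenomeRecord], sa_stride: int = DEFAULT_SA_STRIDE
    ) -> "FmIndex":
        """Index a nonempty list of genome records."""
        if not records:
            raise ValueError("cannot build an index over an empty database")
        if sa_stride < 1:
            raise ValueError("sa_stride must be >= 1")
        parts = []
        starts = np.empty(len(records), dtype=np.int64)
        lengths = np.empty(len(records), dtype=np.int64)
        off = 0
        for i, rec in enumerate(records):
            if not rec.sequence:
                raise ValueError(f"record {rec.seq_id!r} is empty")
            starts[i] = off
            lengths[i] = rec.length
            parts.append(rec.sequence)
            off += rec.length + 1
        text = "#".join(parts) + "$"
        codes = encode(text)
        n = codes.size
        sa = _suffix_array(codes)
        bwt = codes[(sa - 1) % n]

        counts_hist = np.bincount(codes, minlength=SIGMA).astype(np.int64)
        counts = np.zeros(SIGMA + 1, dtype=np.int64)
        counts[1:] = np.cumsum(counts_hist)

        n_blocks = n // OCC_BLOCK + 1
        block_idx = np.arange(n) // OCC_BLOCK
        per_block = np.zeros((n_blocks, SIGMA), dtype=np.int64)
        np.add.at(per_block, (block_idx, bwt), 1)
        ckpt = np.zeros((n_blocks, SIGMA), dtype=np.int64)
        if n_blocks > 1:
            ckpt[1:] = np.cumsum(per_block[:-1], axis=0)

        samples = np.full(n, -1, dtype=np.int64)
        mask = sa % sa_stride == 0
        samples[mask] = sa[mask]

        return cls(bwt, counts, ckpt, samples, sa_stride, [r.seq_id for r in records], starts, lengths)

    # -- primitives --------------------------------------------------------
    def occ(self, code: int, i: int) -> int:
        """Occurrences of symbol ``code`` in ``bwt[:i]``."""
        b = i // OCC_BLOCK
        lo = b * OCC_BLOCK
        extra = int(np.count_nonzero(self.bwt[lo:i] == code)) if i > lo else 0
        return int(self._occ[b, code]) + extra

    def lf(self, i: int) -> int:
        c = int(self.bwt[i])
        return int(self.counts[c]) + self.occ(c, i)

    def full_range(self) -> SaRange:
        return SaRange(0, self.n, 0)

    def backward_step(self, rng: SaRange, code: int) -> SaRange:
        base = int(self.counts[code])
        low = base + self.occ(code, rng.low)
        high = base + self.occ(code, rng.high)
        return SaRange(low, high, rng.pattern_length + 1)

    # -- queries -----------------------------------------------------------
    def backward_search(self, pattern: str) -> SaRange:
        """Suffix-array range of all exact occurrences of ``pattern``.

        The empty pattern returns the full range; a pattern containing ``N``
        (or any non-DNA character) matches nothing.
        """
        rng = self.full_range()
        for ch in reversed(pattern):
            code = _CODE.get(ch, -1)
            if code not in _BASE_CODES:
                return SaRange(0, 0, len(pattern))
            rng = self.backward_step(rng, code)
            if rng.empty:
                return SaRange(0, 0, len(pattern))
        return rng

    def count(self, pattern: str) -> int:
        return self.backward_search(pattern).size

    def extend_left(self, read: str, end: int) -> tuple[int, SaRange]:
        """Longest suffix of ``read[:end]`` occurring in the database.

        Returns ``(length, range)`` where ``range`` is the suffix-array
        interval of the longest matching suffix (the state just before the
        range would have emptied).  Length 0 with an empty range if even the
        final character is absent or not a DNA base.
        """
        if not 0 <= end <= len(read):
            raise ValueError("end out of bounds")
        cur = self.full_range()
        length = 0
        for j in range(end - 1, -1, -1):
            code = _CODE.get(read[j], -1)
            if code not in _BASE_CODES:
                break
            nxt = self.backward_step(cur, code)
            if nxt.empty:
                break
            cur = nxt
            length += 1
        if length == 0:
            return 0, SaRange(0, 0, 0)
        return length, cur

    def locate(self, row: int) -> int:
        """Text position of the suffix at a suffix-array row (LF-walk)."""
        steps = 0
        r = row
        while self._samples[r] < 0:
            r = self.lf(r)
            steps += 1
        return int(self._samples[r]) + steps

    def resolve(self, rng: SaRange, max_positions: int = 200) -> list[tuple[str, int]]:
        """Up to ``max_positions`` distinct (seq_id, offset) pairs for a range."""
        out: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for row in range(rng.low, rng.high):
            pos = self.locate(row)
            idx = int(np.searchsorted(self._starts, pos, side="right")) - 1
            offset = pos - int(self._starts[idx])
            if offset >= int(self._lengths[idx]):
                continue  # separator position; cannot happen for DNA patterns
            pair = (self.seq_ids[idx], offset)
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
                if len(out) >= max_positions:
                    break
        return out

    # -- reconstruction and metadata ----------------------------------------
    @property
    def total_length(self) -> int:
        """Total genome bases indexed (separators excluded)."""
        return int(self._lengths.sum())

    @property
    def n_sequences(self) -> int:
        return len(self.seq_ids)

    def boundaries(self) -> list[tuple[str, int, int]]:
        """(seq_id, global_start, global_end) for each indexed sequence."""
        return [
            (sid, int(s), int(s + l))
            for sid, s, l in zip(self.seq_ids, self._starts, self._lengths)
        ]

    def inverse_bwt(self) -> str:
        """Reconstruct the concatenated text (round-trip check)."""
        chars = np.empty(self.n, dtype=np.uint8)
        i = 0
        for k in range(self.n - 1):
            c = int(self.bwt[i])
            chars[self.n - 2 - k] = c
            i = self.lf(i)
        chars[self.n - 1] = _CODE["$"]
        return "".join(ALPHABET[c] for c in chars)

    # -- serialization -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = json.dumps(
            {"version": FORMAT_VERSION, "sa_stride": self.sa_stride, "seq_ids": self.seq_ids}
        )
        with open(path, "wb") as fh:
            np.savez(
                fh,
                meta=np.array(meta),
                bwt=self.bwt,
                counts=self.counts,
                occ=self._occ,
                samples=self._samples,
                starts=self._starts,
                lengths=self._lengths,
            )

    @classmethod
    def load(cls, path: str | Path) -> "FmIndex":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("version") != FORMAT_VERSION:
                raise ValueError(f"unsupported index version {meta.get('version')}")
            return cls(
                data["bwt"],
                data["counts"],
                data["occ"],
                data["samples"],
                meta["sa_stride"],
                meta["seq_ids"],
                data["starts"],
                data["lengths"],
            )


def build_index(records: Sequence[GenomeRecord], sa_stride: int = DEFAULT_SA_STRIDE) -> FmIndex:
    """Functional alias for :meth:`FmIndex.build`."""
    return FmIndex.build(records, sa_stride=sa_stride)
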