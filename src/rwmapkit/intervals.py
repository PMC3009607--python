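"""Exact genomic interval algebra on a single chromosome.

All coordinates are stored 0-based half-open ``[start, end)``; positions
printed by genome browsers and marker tables are 1-based inclusive and are
converted at the I/O boundary (1-based inclusive ``[s, e]`` maps to
``[s - 1, e)``).  An :class:`IntervalSet` is always kept in canonical form:
sorted, pairwise disjoint, with touching intervals merged, so set equality
is exact tuple equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

__all__ = [
    "ChromosomeMismatchError",
    "GenomicInterval",
    "IntervalSet",
    "width_kb",
    "read_bed",
    "write_bed",
]


class ChromosomeMismatchError(ValueError):
    """Raised when an operation mixes intervals from different chromosomes."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome label, carried for format fidelity (all loci handled
        here live on mouse Chr 5).
    start, end : int
        0-based half-open bounds; ``start < end`` and ``start >= 0``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @classmethod
    def from_1based(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from a 1-based inclusive span ``[start, end]``."""
        return cls(chrom, start - 1, end)

    def to_1based(self) -> tuple[int, int]:
        """Return the 1-based inclusive ``(start, end)`` of this span."""
        return self.start + 1, self.end

    def contains(self, pos: int) -> bool:
        """Point membership for a 0-based position."""
        return self.start <= pos < self.end

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenomicInterval({self.chrom!r}, {self.start}, {self.end})"


IntervalLike = Union[GenomicInterval, tuple]


class IntervalSet:
    """A canonical, immutable set of disjoint intervals on one chromosome.

    Touching intervals (``a.end == b.start``) are merged on construction,
    so two sets covering the same base pairs always compare equal.  The
    empty set carries no chromosome and is compatible with any.
    """

    __slots__ = ("_chrom", "_ivs")

    def __init__(self, intervals: Iterable[IntervalLike] = ()) -> None:
        ivs: list[GenomicInterval] = []
        for iv in intervals:
            if not isinstance(iv, GenomicInterval):
                iv = GenomicInterval(*iv)
            ivs.append(iv)
        chroms = {iv.chrom for iv in ivs}
        if len(chroms) > 1:
            raise ChromosomeMismatchError(
                f"intervals span multiple chromosomes: {sorted(chroms)}"
            )
        self._chrom: Optional[str] = chroms.pop() if chroms else None
        ivs.sort(key=lambda iv: iv.start)
        merged: list[tuple[int, int]] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], iv.end))
            else:
                merged.append((iv.start, iv.end))
        self._ivs: tuple[tuple[int, int], ...] = tuple(merged)

    # -- construction helpers -------------------------------------------

    @classmethod
    def from_spans(cls, chrom: str, spans: Iterable[tuple]) -> "IntervalSet":
        return cls(GenomicInterval(chrom, s, e) for s, e in spans)

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls()

    # -- basic queries ---------------------------------------------------

    @property
    def chrom(self) -> Optional[str]:
        return self._chrom

    @property
    def is_empty(self) -> bool:
        return not self._ivs

    @property
    def spans(self) -> tuple[tuple[int, int], ...]:
        return self._ivs

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self._ivs)

    def __len__(self) -> int:
        return len(self._ivs)

    def __iter__(self) -> Iterator[GenomicInterval]:
        chrom = self._chrom or ""
        return (GenomicInterval(chrom, s, e) for s, e in self._ivs)

    def __bool__(self) -> bool:
        return bool(self._ivs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.is_empty and other.is_empty:
            return True
        return self._chrom == other._chrom and self._ivs == other._ivs

    def __hash__(self) -> int:
        return hash((self._chrom if self._ivs else None, self._ivs))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"[{s}, {e})" for s, e in self._ivs)
        return f"IntervalSet({self._chrom!r}: {{{body}}})"

    def contains(self, pos: int) -> bool:
        """Membership of a 0-based point position."""
        import bisect

        i = bisect.bisect_right([s for s, _ in self._ivs], pos) - 1
        return i >= 0 and pos < self._ivs[i][1]

    def contains_1based(self, pos: int) -> bool:
        return self.contains(pos - 1)

    def envelope(self) -> Optional[GenomicInterval]:
        """Smallest single interval covering the whole set, or None."""
        if not self._ivs:
            return None
        return GenomicInterval(self._chrom or "", self._ivs[0][0], self._ivs[-1][1])

    # -- algebra ---------------------------------------------------------

    def _common_chrom(self, other: "IntervalSet") -> Optional[str]:
        if self._chrom is None:
            return other._chrom
        if other._chrom is None:
            return self._chrom
        if self._chrom != other._chrom:
            raise ChromosomeMismatchError(
                f"chromosome mismatch: {self._chrom!r} vs {other._chrom!r}"
            )
        return self._chrom

    def union(self, other: "IntervalSet") -> "IntervalSet":
        """Point-wise set union; adjacent intervals merge."""
        chrom = self._common_chrom(other)
        if chrom is None:
            return IntervalSet()
        return IntervalSet.from_spans(chrom, list(self._ivs) + list(other._ivs))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Point-wise set intersection."""
        chrom = self._common_chrom(other)
        out: list[tuple[int, int]] = []
        i = j = 0
        a, b = self._ivs, other._ivs
        while i < len(a) and j < len(b):
            s = max(a[i][0], b[j][0])
            e = min(a[i][1], b[j][1])
            if s < e:
                out.append((s, e))
            if a[i][1] < b[j][1]:
                i += 1
            else:
                j += 1
        if not out:
            return IntervalSet()
        return IntervalSet.from_spans(chrom or "", out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Point-wise set difference ``self − other``."""
        chrom = self._common_chrom(other)
        if self.is_empty:
            return IntervalSet()
        out: list[tuple[int, int]] = []
        j = 0
        b = other._ivs
        for s, e in self._ivs:
            cur = s
            while j < len(b) and b[j][1] <= cur:
                j += 1
            k = j
            while k < len(b) and b[k][0] < e:
                bs, be = b[k]
                if bs > cur:
                    out.append((cur, bs))
                cur = max(cur, be)
                if be >= e:
                    break
                k += 1
            if cur < e:
                out.append((cur, e))
        if not out:
            return IntervalSet()
        return IntervalSet.from_spans(chrom or "", out)

    # operator sugar
    __or__ = union
    __and__ = intersect
    __sub__ = subtract

    def width_kb(self) -> int:
        return width_kb(self)

    def positions_1based(self) -> list[tuple[int, int]]:
        """Spans as 1-based inclusive pairs, for display and logging."""
        return [(s + 1, e) for s, e in self._ivs]


def width_kb(s: IntervalSet) -> int:
    """Total length in kb, rounded half away from zero.

    A 288,969 bp span reports as 289 kb; rounding is fixed (not banker's)
    for determinism.
    """
    return math.floor(s.total_length / 1000 + 0.5)


# -- BED3 I/O ------------------------------------------------------------


def read_bed(path: Union[str, Path]) -> IntervalSet:
    """Read a BED3 file (0-based half-open, tab-separated) as an IntervalSet."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            ivs.append(GenomicInterval(chrom, int(start), int(end)))
    return IntervalSet(ivs)


def write_bed(s: IntervalSet, path: Union[str, Path]) -> None:
    """Write an IntervalSet as BED3."""
    with open(path, "w") as fh:
        for iv in s:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
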