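"""Genomic intervals, BED I/O, overlap arithmetic and Jaccard similarity.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
Chromosome names are compared as opaque strings ("chr1" != "1").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


class BedParseError(ValueError):
    """A BED record could not be parsed or violates interval invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """One half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A labelled collection of genomic intervals grouped by chromosome.

    An IntervalSet is *normalized* when, per chromosome, intervals are sorted
    by start and pairwise non-overlapping. Overlap queries and Jaccard
    computations require normalized sets; :meth:`normalize` merges
    overlapping *and bookended* intervals (``[0,10)+[10,20) -> [0,20)``).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        label: str = "",
        _normalized: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.label = label
        self._normalized = _normalized
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- construction / IO ------------------------------------------------

    @classmethod
    def from_bed(cls, path, label: str = "") -> "IntervalSet":
        """Read a BED3+ file (tab-separated, 0-based half-open).

        The optional 4th column is kept as the interval name. Malformed
        records raise :class:`BedParseError` naming the line number; an empty
        file yields an empty set with a warning.
        """
        intervals: list[GenomicInterval] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise BedParseError(
                        f"{path}:{lineno}: expected >=3 tab-separated fields"
                    )
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
                if start < 0 or start >= end:
                    raise BedParseError(
                        f"{path}:{lineno}: invalid interval [{start}, {end})"
                    )
                name = fields[3] if len(fields) > 3 else None
                intervals.append(GenomicInterval(fields[0], start, end, name))
        if not intervals:
            warnings.warn(f"{path}: empty BED file", stacklevel=2)
        return cls(intervals, label=label)

    def to_bed(self, path) -> None:
        """Write as BED (3 columns, plus name when present)."""
        with open(path, "w") as fh:
            for iv in self.intervals:
                cols = [iv.chrom, str(iv.start), str(iv.end)]
                if iv.name is not None:
                    cols.append(iv.name)
                fh.write("\t".join(cols) + "\n")

    # -- basic properties -------------------------------------------------

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    @property
    def is_normalized(self) -> bool:
        return self._normalized

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    # -- normalization ----------------------------------------------------

    def normalize(self) -> "IntervalSet":
        """Sort and merge overlapping-or-bookended intervals per chromosome.

        Idempotent; merged intervals lose their names. total_bases of the
        result never exceeds that of the input.
        """
        if self._normalized:
            return self
        out: list[GenomicInterval] = []
        for chrom in self.chroms():
            s = np.array(
                [iv.start for iv in self.intervals if iv.chrom == chrom]
            )
            e = np.array([iv.end for iv in self.intervals if iv.chrom == chrom])
            order = np.argsort(s, kind="stable")
            s, e = s[order], e[order]
            cummax = np.maximum.accumulate(e)
            is_new = np.ones(len(s), dtype=bool)
            is_new[1:] = s[1:] > cummax[:-1]  # strict: bookended merge
            starts = s[is_new]
            ends = np.maximum.reduceat(cummax, np.flatnonzero(is_new))
            out.extend(
                GenomicInterval(chrom, int(a), int(b))
                for a, b in zip(starts, ends)
            )
        return IntervalSet(out, label=self.label, _normalized=True)

    def _chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if not self._normalized:
            raise ValueError("operation requires a normalized IntervalSet")
        if self._arrays is None:
            self._arrays = {}
            for c in self.chroms():
                s = np.array(
                    [iv.start for iv in self.intervals if iv.chrom == c],
                    dtype=np.int64,
                )
                e = np.array(
                    [iv.end for iv in self.intervals if iv.chrom == c],
                    dtype=np.int64,
                )
                self._arrays[c] = (s, e)
        empty = np.empty(0, dtype=np.int64)
        return self._arrays.get(chrom, (empty, empty))

    # -- queries ----------------------------------------------------------

    def contains_positions(self, chrom: str, positions) -> np.ndarray:
        """Boolean array: is each base position inside some interval?"""
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        starts, ends = self._chrom_arrays(chrom)
        if len(starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[ok] = pos[ok] < ends[idx[ok]]
        return hit

    def overlapping(self, chrom: str, start: int, end: int):
        """Starts/ends of normalized intervals intersecting ``[start, end)``."""
        starts, ends = self._chrom_arrays(chrom)
        if len(starts) == 0:
            return starts, ends
        i0 = np.searchsorted(ends, start, side="right")
        i1 = np.searchsorted(starts, end, side="left")
        return starts[i0:i1], ends[i0:i1]

    @property
    def max_interval_length(self) -> int:
        return max((len(iv) for iv in self.intervals), default=0)


# -- set arithmetic and Jaccard -------------------------------------------


def _union_bases(a: IntervalSet, b: IntervalSet) -> int:
    merged = IntervalSet(
        list(a.intervals) + list(b.intervals), label="union"
    ).normalize()
    return merged.total_bases


def intersection_bases(a: IntervalSet, b: IntervalSet) -> int:
    """Number of bases covered by both normalized sets."""
    if not (a.is_normalized and b.is_normalized):
        raise ValueError("both sets must be normalized")
    return a.total_bases + b.total_bases - _union_bases(a, b)


def jaccard_similarity(a: IntervalSet, b: IntervalSet) -> float:
    """Jaccard statistic |A∩B| / |A∪B| over covered bases.

    0 means no overlap, 1 full overlap. Two empty sets give 0 by convention
    (keeps pairwise matrices total).
    """
    union = _union_bases(a, b)
    if union == 0:
        return 0.0
    inter = a.total_bases + b.total_bases - union
    return inter / union


def pairwise_jaccard(sets: Sequence[IntervalSet]) -> pd.DataFrame:
    """Symmetric labelled matrix of pairwise Jaccard similarities."""
    if len(sets) == 0:
        raise ValueError("need at least one IntervalSet")
    labels = [s.label or f"set{i}" for i, s in enumerate(sets)]
    n = len(sets)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v = jaccard_similarity(sets[i], sets[j])
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=labels, columns=labels)


def write_jaccard_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")
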