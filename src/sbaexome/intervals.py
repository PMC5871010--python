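"""Genomic interval collections.

In-memory coordinates are 1-based inclusive throughout the package; BED I/O
converts from 0-based half-open at the boundary. Chromosome-name dialects
("chr1" vs "1") are normalized at ingest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree


def strip_chr(chrom: str) -> str:
    """Normalize a chromosome name to the bare dialect ("chr1" -> "1")."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class GenomicIntervals:
    """A per-chromosome collection of 1-based inclusive intervals.

    Backed by one :class:`intervaltree.IntervalTree` per chromosome
    (half-open internally; the +1 conversion happens at the edges).
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        """Add [start, end] (1-based inclusive) on ``chrom``."""
        if end < start:
            raise ValueError(f"interval end {end} < start {start}")
        tree = self._trees.setdefault(strip_chr(chrom), IntervalTree())
        tree.addi(start, end + 1)

    def merge(self) -> "GenomicIntervals":
        """Merge overlapping and book-ended intervals in place; returns self."""
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)
        return self

    def overlaps(self, chrom: str, start: int, end: int | None = None) -> bool:
        tree = self._trees.get(strip_chr(chrom))
        if tree is None:
            return False
        end = start if end is None else end
        return tree.overlaps(start, end + 1)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.overlaps(chrom, pos)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end - 1

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def total_bp(self) -> int:
        """Total covered bases; only meaningful after :meth:`merge`."""
        return sum(iv.end - iv.begin for t in self._trees.values() for iv in t)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicIntervals":
        """Read 0-based half-open BED into 1-based inclusive intervals."""
        out = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                out.add(fields[0], int(fields[1]) + 1, int(fields[2]))
        return out

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self:
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")
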