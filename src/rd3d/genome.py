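"""Shared genomic data model: genomes, intervals, bins.

All coordinates are 0-based, half-open (BED convention). 1-based inputs
(GTF) are converted at parse time by :mod:`rd3d.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np


class Genome:
    """An ordered set of chromosomes with lengths.

    Parameters
    ----------
    chromsizes
        Mapping of chromosome name to length in base pairs. Names must be
        unique (guaranteed by the dict) and lengths positive.
    """

    def __init__(self, chromsizes: dict[str, int]):
        if not chromsizes:
            raise ValueError("genome needs at least one chromosome")
        for name, length in chromsizes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chromsizes: dict[str, int] = {str(k): int(v) for k, v in chromsizes.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromsizes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromsizes)

    def __len__(self) -> int:
        return len(self.chromsizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.chromsizes == other.chromsizes

    def __repr__(self) -> str:
        return f"Genome({self.chromsizes!r})"

    def length(self, chrom: str) -> int:
        return self.chromsizes[chrom]

    def n_bins(self, chrom: str, bin_size: int) -> int:
        """Number of bins tiling *chrom* at *bin_size* (last bin may be short)."""
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        return math.ceil(self.chromsizes[chrom] / bin_size)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the overlap with *other* in bp (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Bin:
    """One Hi-C bin: chromosome plus index at a given bin size."""

    chrom: str
    index: int

    def interval(self, bin_size: int, genome: Genome | None = None) -> GenomicInterval:
        start = self.index * bin_size
        end = start + bin_size
        if genome is not None:
            end = min(end, genome.length(self.chrom))
        return GenomicInterval(self.chrom, start, end)


def make_bins(genome: Genome, bin_size: int) -> dict[str, list[Bin]]:
    """Tile every chromosome with bins of *bin_size*; the final bin may be short.

    Returns an ordered mapping chromosome -> list of :class:`Bin`.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    return {
        chrom: [Bin(chrom, i) for i in range(genome.n_bins(chrom, bin_size))]
        for chrom in genome
    }


def position_to_bin(pos, bin_size: int):
    """Bin index of base-pair position(s) at *bin_size* (vectorised)."""
    return np.asarray(pos, dtype=np.int64) // int(bin_size)


def bin_midpoint(index, bin_size: int):
    """Midpoint base-pair coordinate of bin *index* (vectorised)."""
    return np.asarray(index, dtype=np.int64) * int(bin_size) + int(bin_size) // 2


class IntervalIndex:
    """Per-chromosome overlap lookup over a set of (possibly labelled) intervals.

    Built once from arrays, queried with vectorised half-open interval or
    point probes via searchsorted. Intervals need not be disjoint.
    """

    def __init__(self, chroms, starts, ends, labels=None):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        labels = (
            np.asarray(labels, dtype=object)
            if labels is not None
            else np.full(len(starts), None, dtype=object)
        )
        for chrom in np.unique(chroms):
            m = chroms == chrom
            order = np.argsort(starts[m], kind="stable")
            self.by_chrom[str(chrom)] = (starts[m][order], ends[m][order], labels[m][order])

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        """Labels of all intervals sharing >= 1 bp with [start, end)."""
        if chrom not in self.by_chrom:
            return []
        s, e, lab = self.by_chrom[chrom]
        hits = (s < end) & (e > start)
        return list(lab[hits])

    def label_at(self, chrom: str, pos: int):
        """Label of the first interval covering point *pos*, or None."""
        if chrom not in self.by_chrom:
            return None
        s, e, lab = self.by_chrom[chrom]
        hits = np.nonzero((s <= pos) & (e > pos))[0]
        return lab[hits[0]] if hits.size else None

    def labels_at(self, chrom: str, positions) -> np.ndarray:
        """Vectorised :meth:`label_at` for sorted-agnostic position arrays.

        Assumes intervals on *chrom* are non-overlapping (compartment /
        TAD-style tracks); returns an object array with None for gaps.
        """
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, None, dtype=object)
        if chrom not in self.by_chrom:
            return out
        s, e, lab = self.by_chrom[chrom]
        idx = np.searchsorted(s, positions, side="right") - 1
        valid = idx >= 0
        idx_c = np.clip(idx, 0, len(s) - 1)
        covered = valid & (positions < e[idx_c])
        out[covered] = lab[idx_c[covered]]
        return out
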