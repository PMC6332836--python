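"""Standardized k-mer alignability maps and mean probe alignability.

An alignability map gives, for each position p, how often the k-mer
starting at p occurs in the whole genome. The on-disk representation is a
bedGraph of standardized scores in [0, 1]: a score s corresponds to a
genome-wide occurrence count of round(1/s), so 0.25 means the k-mer occurs
4 times and 1.0 means it is unique. Positions not covered by any bedGraph
interval are unmappable: their count is treated as +infinity, and any
probe overlapping such a position is rejected.

The mean k-mer alignability (MKA) of a probe of length l starting at p is
the arithmetic mean of the counts of its l-k+1 constituent k-mers; it is
+infinity as soon as a single constituent k-mer is unmappable.
"""

from __future__ import annotations

import gzip
import math
from typing import Iterable

import numpy as np

__all__ = ["AlignabilityMap", "load_alignability"]


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


class AlignabilityMap:
    """Per-chromosome step function position -> genome-wide k-mer count.

    Intervals are stored as sorted, non-overlapping numpy arrays and
    queried by binary search.
    """

    def __init__(
        self,
        intervals: dict[str, Iterable[tuple[int, int, float]]],
        k: int = 50,
    ):
        self.k = int(k)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._scores: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
            ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
            scores = np.array([iv[2] for iv in ivs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping alignability intervals on {chrom}")
            if np.any(scores < 0) or np.any(scores > 1):
                raise ValueError(f"standardized scores must lie in [0,1] on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._scores[chrom] = scores

    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)

    @classmethod
    def from_bedgraph(cls, path: str, k: int = 50) -> "AlignabilityMap":
        """Load a 4-column bedGraph (track lines tolerated and skipped)."""
        intervals: dict[str, list[tuple[int, int, float]]] = {}
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
                    )
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                    score = float(fields[3])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from None
                if not 0.0 <= score <= 1.0:
                    raise ValueError(
                        f"{path}:{lineno}: standardized score {score} outside [0,1]"
                    )
                if start >= end:
                    raise ValueError(f"{path}:{lineno}: empty interval [{start},{end})")
                intervals.setdefault(chrom, []).append((start, end, score))
        return cls(intervals, k=k)

    def to_bedgraph(self, path: str) -> None:
        with open(path, "wt") as fh:
            for chrom in self._starts:
                for s, e, sc in zip(
                    self._starts[chrom], self._ends[chrom], self._scores[chrom]
                ):
                    fh.write(f"{chrom}\t{s}\t{e}\t{sc:g}\n")

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self._starts:
            raise KeyError(f"no alignability data for chromosome {chrom!r}")

    def score_at(self, chrom: str, p: int) -> float:
        """Standardized score at position p; 0 when uncovered."""
        self._check_chrom(chrom)
        starts = self._starts[chrom]
        i = int(np.searchsorted(starts, p, side="right")) - 1
        if i < 0 or p >= self._ends[chrom][i]:
            return 0.0
        return float(self._scores[chrom][i])

    def count_at(self, chrom: str, p: int) -> float:
        """Genome-wide occurrence count of the k-mer at p.

        round(1/score) for covered positions; +infinity when the position
        is uncovered (unmappable).
        """
        s = self.score_at(chrom, p)
        if s <= 0.0:
            return math.inf
        return float(round(1.0 / s))

    def counts_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Vector of occurrence counts for k-mer start positions [start, end)."""
        self._check_chrom(chrom)
        if start >= end:
            return np.empty(0)
        positions = np.arange(start, end, dtype=np.int64)
        starts = self._starts[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        counts = np.full(positions.shape, math.inf)
        valid = idx >= 0
        iv = idx[valid]
        covered = positions[valid] < self._ends[chrom][iv]
        scores = self._scores[chrom][iv]
        ok = covered & (scores > 0)
        sel = np.where(valid)[0][ok]
        counts[sel] = np.round(1.0 / scores[ok])
        return counts

    def mean_kmer_alignability(self, chrom: str, p: int, l: int) -> float:
        """Mean occurrence count of the l-k+1 k-mers of a probe at [p, p+l).

        Returns +infinity if any constituent k-mer is unmappable.
        """
        if l < self.k:
            raise ValueError(f"probe length {l} shorter than k-mer size {self.k}")
        counts = self.counts_in(chrom, p, p + l - self.k + 1)
        if np.any(np.isinf(counts)):
            return math.inf
        return float(counts.sum() / counts.size)


def load_alignability(path: str, k: int = 50) -> AlignabilityMap:
    """Convenience wrapper for :meth:`AlignabilityMap.from_bedgraph`."""
    return AlignabilityMap.from_bedgraph(path, k=k)
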