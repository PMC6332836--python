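"""Indexed random access to a soft-masked FASTA genome.

All coordinates are 0-based, half-open. Sequence case is preserved:
lowercase bases mark repeat-masked sequence (UCSC soft-masking) and are
the definition of repeat content throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyfaidx import Fasta

__all__ = [
    "GenomeHandle",
    "SequenceStats",
    "gc_fraction",
    "at_fraction",
    "repeat_fraction",
    "sequence_stats",
]

_GC = frozenset("GCgc")
_AT = frozenset("ATat")
_UNAMBIGUOUS = frozenset("ACGTacgt")


class GenomeHandle:
    """Random access to a multi-FASTA genome with a standard .fai index.

    Parameters
    ----------
    path : str
        Path to the FASTA file. A ``.fai`` sidecar index is created on
        first use if absent.
    """

    def __init__(self, path: str):
        self.path = str(path)
        self._fasta = Fasta(self.path, as_raw=True, rebuild=False)
        self.chrom_lengths: dict[str, int] = {
            name: len(rec) for name, rec in self._fasta.items()
        }

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def _check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        length = self.chrom_lengths[chrom]
        if not (0 <= start <= end <= length):
            raise ValueError(
                f"interval [{start}, {end}) out of range for {chrom} "
                f"(length {length})"
            )

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``chrom[start:end)``, case preserved."""
        self._check(chrom, start, end)
        if start == end:
            return ""
        return str(self._fasta[chrom][start:end])

    def close(self) -> None:
        self._fasta.close()

    def __enter__(self) -> "GenomeHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


@dataclass(frozen=True)
class SequenceStats:
    """Base composition of a sequence: GC and soft-mask (repeat) fractions."""

    gc_fraction: float
    repeat_fraction: float


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases, case-insensitive.

    Ambiguity codes (N etc.) count in the denominator only. The empty
    sequence has GC fraction 0 by definition.
    """
    if not seq:
        return 0.0
    return sum(1 for c in seq if c in _GC) / len(seq)


def at_fraction(seq: str) -> float:
    """Fraction of A/T bases, by the same counting rule as :func:`gc_fraction`."""
    if not seq:
        return 0.0
    return sum(1 for c in seq if c in _AT) / len(seq)


def repeat_fraction(seq: str) -> float:
    """Fraction of lowercase (soft-masked) bases; empty sequence gives 0."""
    if not seq:
        return 0.0
    return sum(1 for c in seq if c.islower()) / len(seq)


def has_ambiguity(seq: str) -> bool:
    """True if the sequence contains any character outside {A,C,G,T} (any case)."""
    return any(c not in _UNAMBIGUOUS for c in seq)


def sequence_stats(seq: str) -> SequenceStats:
    return SequenceStats(gc_fraction(seq), repeat_fraction(seq))
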