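"""In-silico restriction digestion of a genome.

A digest is a restriction fragment: the interval between two consecutive
cut positions (or a chromosome end). Digests tile each chromosome exactly,
with no gaps or overlaps, so every genomic position belongs to exactly one
digest.

Only palindromic recognition sites are fully supported; a non-palindromic
site is scanned on the forward strand only and a warning is logged.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .genome import GenomeHandle, gc_fraction, repeat_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "RestrictionEnzyme",
    "Digest",
    "ENZYMES",
    "get_enzyme",
    "find_cut_positions",
    "digest_genome",
    "mean_digest_size",
    "digest_at",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(site: str) -> str:
    return site.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: recognition motif plus cut offset.

    ``cut_offset`` is the cut position within the motif, e.g. HindIII
    A^AGCTT has site AAGCTT and offset 1; DpnII ^GATC has offset 0.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if len(site) < 4:
            raise ValueError(f"{self.name}: site must be at least 4 bp")
        if set(site) - set("ACGT"):
            raise ValueError(f"{self.name}: site must be over A/C/G/T")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(f"{self.name}: cut offset outside motif")
        if _revcomp(site) != site:
            logger.warning(
                "enzyme %s site %s is not palindromic; scanning forward strand only",
                self.name, site,
            )

    @property
    def is_palindromic(self) -> bool:
        return _revcomp(self.site) == self.site


#: Built-in enzymes. User-defined enzymes can be supplied as
#: ``name,site,offset`` strings via :func:`get_enzyme`.
ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name.lower(): e
    for e in [
        RestrictionEnzyme("HindIII", "AAGCTT", 1),
        RestrictionEnzyme("DpnII", "GATC", 0),
        RestrictionEnzyme("MboI", "GATC", 0),
        RestrictionEnzyme("EcoRI", "GAATTC", 1),
        RestrictionEnzyme("BglII", "AGATCT", 1),
        RestrictionEnzyme("NlaIII", "CATG", 4),
        RestrictionEnzyme("NdeI", "CATATG", 2),
        RestrictionEnzyme("BamHI", "GGATCC", 1),
    ]
}


def get_enzyme(spec: str) -> RestrictionEnzyme:
    """Look up a built-in enzyme by name, or parse ``name,site,offset``."""
    if "," in spec:
        parts = spec.split(",")
        if len(parts) != 3:
            raise ValueError(f"custom enzyme must be name,site,offset: {spec!r}")
        return RestrictionEnzyme(parts[0].strip(), parts[1].strip(), int(parts[2]))
    try:
        return ENZYMES[spec.strip().lower()]
    except KeyError:
        known = ", ".join(sorted(e.name for e in ENZYMES.values()))
        raise KeyError(f"unknown enzyme {spec!r}; built-in: {known}") from None


@dataclass
class Digest:
    """One restriction fragment.

    Coordinates are 0-based half-open; ``index_on_chrom`` is the 1-based
    ordinal of the digest on its chromosome. ``selected`` and the
    per-margin probe counts are filled in during viewpoint creation.
    """

    chrom: str
    start: int
    end: int
    index_on_chrom: int
    gc_fraction: float = 0.0
    repeat_fraction: float = 0.0
    selected: bool = False
    probes_5p: int = 0
    probes_3p: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"digest must have start < end: [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def find_cut_positions(seq: str, enzymes: Iterable[RestrictionEnzyme]) -> list[int]:
    """All cut positions of the given enzymes in ``seq``, sorted, deduplicated.

    Matching is case-insensitive and overlapping motif occurrences all
    produce cuts (the scan advances by one base, not by the motif length).
    """
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    upper = seq.upper()
    cuts: set[int] = set()
    for enz in enzymes:
        idx = upper.find(enz.site)
        while idx != -1:
            cuts.add(idx + enz.cut_offset)
            idx = upper.find(enz.site, idx + 1)
    return sorted(cuts)


def digest_genome(
    genome: GenomeHandle, enzymes: Iterable[RestrictionEnzyme]
) -> dict[str, list[Digest]]:
    """Cut every chromosome and return the digest lists keyed by chromosome.

    Per chromosome the digests are the intervals between consecutive cut
    positions plus the two flanking intervals to the chromosome ends; they
    partition ``[0, chrom_length)``. GC and repeat fractions are computed
    from the digest sequence.
    """
    enzymes = list(enzymes)
    result: dict[str, list[Digest]] = {}
    for chrom, length in genome.chrom_lengths.items():
        seq = genome.fetch(chrom, 0, length)
        cuts = find_cut_positions(seq, enzymes)
        boundaries = [0] + [c for c in cuts if 0 < c < length] + [length]
        digests = []
        for i, (s, e) in enumerate(zip(boundaries[:-1], boundaries[1:]), start=1):
            sub = seq[s:e]
            digests.append(
                Digest(
                    chrom=chrom, start=s, end=e, index_on_chrom=i,
                    gc_fraction=gc_fraction(sub),
                    repeat_fraction=repeat_fraction(sub),
                )
            )
        result[chrom] = digests
    return result


def mean_digest_size(digest_map: Mapping[str, list[Digest]]) -> float:
    """Arithmetic mean length of all digests genome-wide."""
    lengths = [d.length for digests in digest_map.values() for d in digests]
    if not lengths:
        raise ValueError("no digests: cannot compute mean digest size")
    return sum(lengths) / len(lengths)


def digest_at(digests: list[Digest], position: int) -> int:
    """Index in ``digests`` of the digest containing ``position``.

    Relies on the partition invariant (sorted, adjacent, tiling).
    """
    starts = [d.start for d in digests]
    i = bisect_right(starts, position) - 1
    if i < 0 or position >= digests[i].end:
        raise ValueError(f"position {position} outside the digest partition")
    return i
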