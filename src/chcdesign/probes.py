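"""Margin definition, probe usability testing and outermost-in placement.

Valid Hi-C read pairs concentrate near restriction cut sites, so probes
are placed only within the margins (default 250 bp) at the two ends of a
digest. Placement starts flush with the cut site and moves inward one base
at a time, keeping the first usable probes encountered; probes are allowed
to overlap each other but never to span a cut site.

A digest is *balanced* when each margin holds at least b_min usable
probes, *unbalanced* when the two margins together hold at least 2*b_min
but with unequal numbers per side, and *rejected* otherwise (including
digests shorter than the minimum digest size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .alignability import AlignabilityMap
from .digestion import Digest
from .genome import GenomeHandle, gc_fraction, has_ambiguity, repeat_fraction
from .params import DesignParameters

__all__ = [
    "Margin",
    "Probe",
    "margins_of",
    "probe_usable",
    "select_probes_in_margin",
    "classify_digest",
    "BALANCED",
    "UNBALANCED",
    "REJECTED",
]

BALANCED = "balanced"
UNBALANCED = "unbalanced"
REJECTED = "rejected"


@dataclass(frozen=True)
class Margin:
    """One end region of a digest (5p = toward lower coordinates)."""

    digest: Digest
    side: str  # "5p" | "3p"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.side not in ("5p", "3p"):
            raise ValueError(f"side must be 5p or 3p, got {self.side!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Probe:
    """A candidate or selected bait."""

    chrom: str
    start: int
    end: int
    side: str
    sequence: str
    gc_fraction: float
    repeat_fraction: float
    mean_alignability: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def margins_of(digest: Digest, margin_size: int) -> tuple[Margin, Margin]:
    """The 5' and 3' margins of a digest.

    The effective margin width is ``min(margin_size, floor(length/2))`` so
    the two margins never overlap; for odd short digests the middle base
    belongs to neither margin.
    """
    m = min(margin_size, digest.length // 2)
    return (
        Margin(digest, "5p", digest.start, digest.start + m),
        Margin(digest, "3p", digest.end - m, digest.end),
    )


def probe_usable(probe: Probe, params: DesignParameters) -> bool:
    """GC within [gc_min, gc_max], finite MKA <= alignability_max, no ambiguity.

    All threshold comparisons are inclusive: a probe with GC exactly at a
    bound or MKA exactly at the maximum passes.
    """
    if has_ambiguity(probe.sequence):
        return False
    if not params.gc_min <= probe.gc_fraction <= params.gc_max:
        return False
    if math.isinf(probe.mean_alignability):
        return False
    return probe.mean_alignability <= params.alignability_max


def _make_probe(
    genome: GenomeHandle,
    amap: AlignabilityMap,
    chrom: str,
    start: int,
    side: str,
    params: DesignParameters,
) -> Probe:
    seq = genome.fetch(chrom, start, start + params.probe_length)
    if has_ambiguity(seq):
        mka = math.inf
    else:
        mka = amap.mean_kmer_alignability(chrom, start, params.probe_length)
    return Probe(
        chrom=chrom,
        start=start,
        end=start + params.probe_length,
        side=side,
        sequence=seq,
        gc_fraction=gc_fraction(seq),
        repeat_fraction=repeat_fraction(seq),
        mean_alignability=mka,
    )


def select_probes_in_margin(
    margin: Margin,
    genome: GenomeHandle,
    amap: AlignabilityMap,
    params: DesignParameters,
    max_probes: Optional[int] = None,
) -> list[Probe]:
    """First ``max_probes`` (default b_min) usable probes, outermost first.

    For a 5' margin, candidate start positions move inward from the cut
    site one base at a time; for a 3' margin candidate end positions do.
    A candidate must lie entirely inside the digest and its anchored end
    (start for 5p, end for 3p) must fall within the margin. Fewer probes
    are returned when the supply of usable candidates is exhausted.
    """
    if max_probes is None:
        max_probes = params.b_min
    digest = margin.digest
    L = params.probe_length
    selected: list[Probe] = []
    if margin.side == "5p":
        # starts within [margin.start, margin.end), probe inside the digest
        for start in range(margin.start, margin.end):
            if start + L > digest.end:
                break
            probe = _make_probe(genome, amap, digest.chrom, start, "5p", params)
            if probe_usable(probe, params):
                selected.append(probe)
                if len(selected) >= max_probes:
                    break
    else:
        # ends within (margin.start, margin.end], probe inside the digest
        for end in range(margin.end, margin.start, -1):
            start = end - L
            if start < digest.start:
                break
            probe = _make_probe(genome, amap, digest.chrom, start, "3p", params)
            if probe_usable(probe, params):
                selected.append(probe)
                if len(selected) >= max_probes:
                    break
    return selected


def classify_digest(
    digest: Digest,
    genome: GenomeHandle,
    amap: AlignabilityMap,
    params: DesignParameters,
) -> tuple[str, list[Probe], list[Probe]]:
    """Classify a digest and return its class with the probes per margin.

    Digests shorter than the minimum digest size are rejected outright.
    Otherwise each margin is scanned for up to b_min usable probes; when
    both sides reach b_min the digest is balanced. When unbalanced digests
    are allowed and a side falls short, scanning continues on the richer
    margin first up to 2*b_min probes in total; reaching that total makes
    the digest unbalanced. Anything else is rejected (its probes are not
    reported).
    """
    if digest.length < params.min_digest_size:
        return REJECTED, [], []
    m5, m3 = margins_of(digest, params.margin_size)
    p5 = select_probes_in_margin(m5, genome, amap, params, max_probes=params.b_min)
    p3 = select_probes_in_margin(m3, genome, amap, params, max_probes=params.b_min)
    if len(p5) >= params.b_min and len(p3) >= params.b_min:
        return BALANCED, p5, p3
    if params.allow_unbalanced:
        need = 2 * params.b_min
        # rescan the richer margin first (ties to 5'), stopping at 2*b_min total
        first, second = (m5, m3) if len(p5) >= len(p3) else (m3, m5)
        second_initial = p3 if first is m5 else p5
        first_probes = select_probes_in_margin(
            first, genome, amap, params, max_probes=need - len(second_initial)
        )
        remaining = need - len(first_probes)
        second_probes = (
            select_probes_in_margin(second, genome, amap, params, max_probes=remaining)
            if remaining > 0
            else []
        )
        p5x, p3x = (
            (first_probes, second_probes)
            if first.side == "5p"
            else (second_probes, first_probes)
        )
        if len(p5x) + len(p3x) >= need:
            return UNBALANCED, p5x, p3x
    return REJECTED, [], []
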