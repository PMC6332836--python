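"""Synthetic genomes, alignability maps and annotations with planted structure.

Every generated file has a known answer by construction: restriction
motifs occur exactly at the planted cut sites and nowhere else (the
filler sequence is repaired until motif-free), GC-controlled blocks hit
their target fraction to within rounding, soft-masked runs are lowercase,
alignability intervals (including unmappable gaps) are placed verbatim,
and genes emit strand-aware TSS at the requested positions. This makes
every stage of the design pipeline testable without reference downloads.

These fixtures emulate the coordinate structure of real inputs, not their
biology: no repeat landscapes, no promoter base composition, no isochore
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pyfaidx import Faidx

from .digestion import ENZYMES, get_enzyme

__all__ = [
    "GeneSpec",
    "FixtureSpec",
    "make_genome",
    "make_alignability",
    "make_annotation",
    "make_bed6",
    "demo_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class GeneSpec:
    """A synthetic gene: a symbol with a strand-aware TSS."""

    symbol: str
    chrom: str
    strand: str
    tss: int
    transcript_id: Optional[str] = None
    tx_length: int = 2000


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic data set.

    ``cut_sites`` maps chromosome -> enzyme name -> cut positions: the
    enzyme's motif is planted so that its cut falls exactly there.
    ``alignability`` maps chromosome -> (start, end, score) intervals;
    ``None`` means uniform coverage at score 1.0. Uncovered positions in
    an explicit map are unmappable gaps.
    """

    chrom_lengths: dict[str, int]
    cut_sites: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    gc_blocks: list[tuple[str, int, int, float]] = field(default_factory=list)
    default_gc: float = 0.5
    masked_runs: list[tuple[str, int, int]] = field(default_factory=list)
    alignability: Optional[dict[str, list[tuple[int, int, float]]]] = None
    genes: list[GeneSpec] = field(default_factory=list)
    bed_regions: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    avoid_motifs: tuple[str, ...] = ()
    seed: int = 1

    def _enzyme_names(self) -> list[str]:
        names: list[str] = []
        for per_chrom in self.cut_sites.values():
            for name in per_chrom:
                if name not in names:
                    names.append(name)
        return names


def _exact_gc_block(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """n bases with exactly round(n*gc) G/C, shuffled."""
    n_gc = int(round(n * gc))
    gc_part = rng.choice(np.frombuffer(b"GC", dtype="S1"), size=n_gc)
    at_part = rng.choice(np.frombuffer(b"AT", dtype="S1"), size=n - n_gc)
    block = np.concatenate([gc_part, at_part])
    rng.shuffle(block)
    return block


def _plant_and_repair(
    seq: np.ndarray,
    planted: dict[str, set[int]],
    rng: np.random.Generator,
    gc: float,
    max_rounds: int = 200,
) -> np.ndarray:
    """Plant motifs at their positions and scrub spurious occurrences.

    ``planted`` maps motif -> allowed start positions. Bases inside a
    planted motif footprint are protected; a spurious occurrence made
    entirely of protected bases is infeasible and raises.
    """
    protected = np.zeros(seq.size, dtype=bool)
    for motif, starts in planted.items():
        m = np.frombuffer(motif.encode(), dtype="S1")
        for s in starts:
            if s < 0 or s + len(motif) > seq.size:
                raise ValueError(f"planted motif {motif} at {s} outside chromosome")
            seq[s : s + len(motif)] = m
            protected[s : s + len(motif)] = True
    for _ in range(max_rounds):
        dirty = False
        text = seq.tobytes()
        for motif, starts in planted.items():
            needle = motif.encode()
            idx = text.find(needle)
            while idx != -1:
                if idx not in starts:
                    free = [
                        i for i in range(idx, idx + len(needle)) if not protected[i]
                    ]
                    if not free:
                        raise RuntimeError(
                            f"cannot remove spurious {motif} at {idx}: all bases "
                            "belong to planted motifs"
                        )
                    pos = int(rng.choice(free))
                    current = seq[pos]
                    choices = _BASES[_BASES != current]
                    # bias replacement toward the block GC target
                    weights = np.array(
                        [gc / 2 if b in (b"G", b"C") else (1 - gc) / 2 for b in choices]
                    )
                    weights /= weights.sum()
                    seq[pos] = rng.choice(choices, p=weights)
                    dirty = True
                idx = text.find(needle, idx + 1)
        if not dirty:
            return seq
    raise RuntimeError("motif-free filler generation did not converge")


def make_genome(spec: FixtureSpec, path: str) -> str:
    """Write the FASTA described by ``spec`` (plus .fai index); returns the path.

    Deterministic for a fixed spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = {get_enzyme(name).site for name in spec._enzyme_names()}
    motifs |= {m.upper() for m in spec.avoid_motifs}
    path = str(path)
    with open(path, "wt") as fh:
        for chrom, length in spec.chrom_lengths.items():
            seq = _exact_gc_block(rng, length, spec.default_gc)
            for c, s, e, gc in spec.gc_blocks:
                if c == chrom:
                    seq[s:e] = _exact_gc_block(rng, e - s, gc)
            planted: dict[str, set[int]] = {m: set() for m in motifs}
            for name, cuts in spec.cut_sites.get(chrom, {}).items():
                enz = get_enzyme(name)
                for cut in cuts:
                    planted.setdefault(enz.site, set()).add(cut - enz.cut_offset)
            if planted:
                seq = _plant_and_repair(seq, planted, rng, spec.default_gc)
            text = seq.tobytes().decode()
            for c, s, e in spec.masked_runs:
                if c == chrom:
                    text = text[:s] + text[s:e].lower() + text[e:]
            fh.write(f">{chrom}\n")
            for i in range(0, length, 60):
                fh.write(text[i : i + 60] + "\n")
    Faidx(path, rebuild=True)
    return path


def make_alignability(spec: FixtureSpec, path: str) -> str:
    """Write the bedGraph alignability map; uniform 1.0 when unspecified."""
    path = str(path)
    with open(path, "wt") as fh:
        if spec.alignability is None:
            for chrom, length in spec.chrom_lengths.items():
                fh.write(f"{chrom}\t0\t{length}\t1\n")
        else:
            for chrom, intervals in spec.alignability.items():
                for s, e, score in sorted(intervals):
                    fh.write(f"{chrom}\t{s}\t{e}\t{score:g}\n")
    return path


def make_annotation(spec: FixtureSpec, path: str) -> str:
    """Write a refGene-style TSV for the spec's genes."""
    path = str(path)
    with open(path, "wt") as fh:
        for i, g in enumerate(spec.genes, start=1):
            length = spec.chrom_lengths[g.chrom]
            if g.strand == "+":
                tx_start = g.tss
                tx_end = min(g.tss + g.tx_length, length)
            else:
                tx_end = g.tss + 1
                tx_start = max(g.tss + 1 - g.tx_length, 0)
            tid = g.transcript_id or f"NM_{i:06d}"
            fields = [
                "0", tid, g.chrom, g.strand, str(tx_start), str(tx_end),
                str(tx_start), str(tx_end), "1", f"{tx_start},", f"{tx_end},",
                "0", g.symbol, "cmpl", "cmpl", "0,",
            ]
            fh.write("\t".join(fields) + "\n")
    return path


def make_bed6(spec: FixtureSpec, path: str) -> str:
    """Write the spec's BED regions as BED6."""
    path = str(path)
    with open(path, "wt") as fh:
        for chrom, s, e, name, strand in spec.bed_regions:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")
    return path


def demo_spec(seed: int = 1) -> FixtureSpec:
    """A small single-chromosome design scenario.

    One 50 kb chromosome cut by DpnII every 430 bp (the genome-wide mean
    digest size of a typical 4-cutter), a handful of genes on both
    strands, a mostly unique alignability map with a couple of
    multi-mapping intervals and one unmappable gap, and two BED regions
    mimicking GWAS hits.
    """
    length = 50_000
    cuts = list(range(430, length, 430))
    genes = [
        GeneSpec("GENE1", "chr1", "+", 5_160),
        GeneSpec("GENE2", "chr1", "-", 12_947),
        GeneSpec("GENE3", "chr1", "+", 21_505),
        GeneSpec("GENE4", "chr1", "-", 30_100),
        GeneSpec("GENE5", "chr1", "+", 41_800),
        # second TSS for GENE5, as for genes with alternative promoters
        GeneSpec("GENE5", "chr1", "+", 43_520, transcript_id="NM_900001"),
    ]
    alignability = {
        "chr1": [
            (0, 24_000, 1.0),
            (24_000, 24_500, 0.5),
            (24_500, 35_000, 1.0),
            # unmappable gap [35_000, 35_200)
            (35_200, 44_000, 1.0),
            (44_000, 44_300, 0.25),
            (44_300, length, 1.0),
        ]
    }
    return FixtureSpec(
        chrom_lengths={"chr1": length},
        cut_sites={"chr1": {"DpnII": cuts}},
        masked_runs=[("chr1", 36_000, 36_400)],
        alignability=alignability,
        genes=genes,
        bed_regions=[
            ("chr1", 8_000, 8_001, "hit1", "+"),
            ("chr1", 33_000, 33_200, "hit2", "-"),
        ],
        seed=seed,
    )
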