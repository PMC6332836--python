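"""Target resolution: gene symbols or BED6 regions -> strand-aware positions.

For promoter designs, one viewpoint target is created for every distinct
transcription start site of every matched gene symbol; symbols absent
from the annotation (e.g. outdated aliases such as P53 for TP53) are
reported verbatim so the user can look up the current symbol. For non-TSS
applications (GWAS hits, region tiling) a BED6 file supplies one target
per record, anchored at the center of the interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Transcript",
    "Target",
    "parse_transcripts",
    "read_gene_list",
    "tss_of",
    "resolve_symbols",
    "all_symbols",
    "targets_from_bed6",
    "suggest_corrections",
]


@dataclass(frozen=True)
class Transcript:
    """One transcript from a refGene-style annotation (0-based half-open)."""

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"transcript must have tx_start < tx_end: {self.transcript_id}"
            )


@dataclass(frozen=True)
class Target:
    """A viewpoint anchor: a labelled strand-aware genomic position."""

    label: str
    chrom: str
    position: int
    strand: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.position, self.strand)


def parse_transcripts(path: str) -> list[Transcript]:
    """Read a UCSC refGene-style TSV.

    Expected columns (tab-separated): bin, name, chrom, strand, txStart,
    txEnd, ..., name2 at column 13. Non-canonical chromosomes are
    retained; comment lines starting with '#' are skipped.
    """
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 13:
                raise ValueError(
                    f"{path}:{lineno}: expected >=13 refGene columns, got {len(fields)}"
                )
            try:
                transcripts.append(
                    Transcript(
                        gene_symbol=fields[12],
                        transcript_id=fields[1],
                        chrom=fields[2],
                        strand=fields[3],
                        tx_start=int(fields[4]),
                        tx_end=int(fields[5]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return transcripts


def read_gene_list(path: str) -> list[str]:
    """Read a gene-symbol list: one symbol per line, '#' comments ignored."""
    symbols: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                symbols.append(sym)
    return symbols


def tss_of(t: Transcript) -> int:
    """Strand-aware transcription start site (0-based).

    Plus strand: tx_start. Minus strand: tx_end - 1, the last base of the
    half-open interval.
    """
    return t.tx_start if t.strand == "+" else t.tx_end - 1


def resolve_symbols(
    symbols: Sequence[str], transcripts: Iterable[Transcript]
) -> tuple[list[Target], list[str]]:
    """Match gene symbols (case-sensitively) to targets, one per distinct TSS.

    Returns the targets plus the unmatched symbols verbatim, in input
    order. Duplicate input symbols and isoforms sharing a TSS do not
    produce duplicate targets.
    """
    by_symbol: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_symbol.setdefault(t.gene_symbol, []).append(t)
    targets: list[Target] = []
    seen_positions: set[tuple[str, int, str]] = set()
    seen_symbols: set[str] = set()
    unmapped: list[str] = []
    for sym in symbols:
        if sym in seen_symbols:
            continue
        seen_symbols.add(sym)
        if sym not in by_symbol:
            unmapped.append(sym)
            continue
        for t in by_symbol[sym]:
            tgt = Target(label=sym, chrom=t.chrom, position=tss_of(t), strand=t.strand)
            if tgt.key not in seen_positions:
                seen_positions.add(tgt.key)
                targets.append(tgt)
    return targets, unmapped


def all_symbols(transcripts: Iterable[Transcript]) -> list[str]:
    """Every distinct gene symbol in the annotation, in first-seen order."""
    seen: dict[str, None] = {}
    for t in transcripts:
        seen.setdefault(t.gene_symbol, None)
    return list(seen)


def suggest_corrections(
    unmapped: Sequence[str], transcripts: Iterable[Transcript]
) -> dict[str, list[str]]:
    """Case-insensitive fallback suggestions for unmapped symbols."""
    by_lower: dict[str, set[str]] = {}
    for t in transcripts:
        by_lower.setdefault(t.gene_symbol.lower(), set()).add(t.gene_symbol)
    return {
        sym: sorted(by_lower.get(sym.lower(), set()))
        for sym in unmapped
    }


def targets_from_bed6(path: str) -> list[Target]:
    """One target per BED6 record, at the floor midpoint of the interval.

    Strand '.' is treated as '+'. Fewer than six columns or an empty
    interval is an error.
    """
    targets: list[Target] = []
    seen: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 required (6 columns), got {len(fields)}"
                )
            chrom, name = fields[0], fields[3]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty interval [{start},{end})")
            strand = fields[5] if fields[5] in ("+", "-") else "+"
            tgt = Target(
                label=name, chrom=chrom, position=(start + end) // 2, strand=strand
            )
            if tgt.key not in seen:
                seen.add(tgt.key)
                targets.append(tgt)
    return targets
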