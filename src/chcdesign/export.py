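"""Design summary and the seven documented output files.

Overlapping viewpoints (multiple TSS on the same digest) produce
redundant digests and probes; everything exported is first made unique by
genomic coordinates, and the summary reports unique counts only. The
capture size is the total number of bases covered by the union of unique
probe intervals and drives reagent cost.

All BED output is 0-based half-open; the digest and viewpoint tables use
1-based inclusive display coordinates.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .digestion import Digest
from .genome import GenomeHandle, gc_fraction, repeat_fraction
from .params import DesignParameters
from .probes import BALANCED, Probe, UNBALANCED, margins_of
from .viewpoints import Viewpoint

__all__ = [
    "DesignSummary",
    "deduplicate",
    "summarize",
    "interval_union_size",
    "write_outputs",
    "read_digested_genome",
    "ucsc_url",
]

DIGEST_HEADER = (
    "Chromosome\tFragment_Start_Position\tFragment_End_Position\tFragment_Number\t"
    "Length\tFive_Prime_GC_Content\tFive_Prime_Repeat_Content\t"
    "Three_Prime_GC_Content\tThree_Prime_Repeat_Content\tSelected\t"
    "Five_Prime_Probes\tThree_Prime_Probes"
)

#: Agilent-style upload columns; the dialect is supplier-specific, so the
#: column order can be overridden via ``write_outputs(agilent_columns=...)``.
DEFAULT_AGILENT_COLUMNS = (
    "TargetID",
    "ProbeID",
    "Sequence",
    "Replication",
    "Strand",
    "Chromosome",
    "Start",
    "Stop",
)


@dataclass(frozen=True)
class DesignSummary:
    """Headline numbers of a finished design."""

    n_target_genes: int
    n_genes_with_valid_viewpoint: int
    n_viewpoints: int
    n_valid_viewpoints: int
    mean_viewpoint_size: float
    n_unique_digests: int
    n_balanced: int
    n_unbalanced: int
    n_probes: int
    capture_size: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSummary":
        return cls(**d)


def interval_union_size(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals (single sequence)."""
    total = 0
    cur_s: Optional[int] = None
    cur_e = 0
    for s, e in sorted(intervals):
        if cur_s is None or s > cur_e:
            if cur_s is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def deduplicate(
    viewpoints: Sequence[Viewpoint],
) -> tuple[list["_UniqueDigest"], list[Probe]]:
    """Unique selected digests and probes across all viewpoints.

    Digests (probes) identical by (chrom, start, end) collapse to one
    record; digest records carry the class and per-margin probe counts.
    """
    digests: dict[tuple[str, int, int], _UniqueDigest] = {}
    probes: dict[tuple[str, int, int], Probe] = {}
    for vp in viewpoints:
        for cand in vp.selected:
            if cand.key not in digests:
                digests[cand.key] = _UniqueDigest(
                    digest=cand.digest,
                    digest_class=cand.digest_class,
                    probes_5p=len(cand.probes_5p),
                    probes_3p=len(cand.probes_3p),
                )
            for p in cand.probes:
                probes.setdefault(p.key, p)
    return (
        [digests[k] for k in sorted(digests)],
        [probes[k] for k in sorted(probes)],
    )


@dataclass(frozen=True)
class _UniqueDigest:
    digest: Digest
    digest_class: str
    probes_5p: int
    probes_3p: int


def summarize(
    viewpoints: Sequence[Viewpoint], params: DesignParameters
) -> DesignSummary:
    """Compute the design summary over deduplicated digests and probes."""
    uniq_digests, uniq_probes = deduplicate(viewpoints)
    valid = [vp for vp in viewpoints if vp.is_valid]
    genes = {vp.target.label for vp in viewpoints}
    genes_valid = {vp.target.label for vp in valid}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in uniq_probes:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    capture = sum(interval_union_size(ivs) for ivs in by_chrom.values())
    mean_size = (
        sum(vp.span_length for vp in valid) / len(valid) if valid else 0.0
    )
    return DesignSummary(
        n_target_genes=len(genes),
        n_genes_with_valid_viewpoint=len(genes_valid),
        n_viewpoints=len(viewpoints),
        n_valid_viewpoints=len(valid),
        mean_viewpoint_size=mean_size,
        n_unique_digests=len(uniq_digests),
        n_balanced=sum(1 for d in uniq_digests if d.digest_class == BALANCED),
        n_unbalanced=sum(1 for d in uniq_digests if d.digest_class == UNBALANCED),
        n_probes=len(uniq_probes),
        capture_size=capture,
    )


def sync_digest_flags(
    viewpoints: Sequence[Viewpoint], digest_map: Mapping[str, list[Digest]]
) -> None:
    """Propagate viewpoint selections onto the genome-wide digest list."""
    uniq, _ = deduplicate(viewpoints)
    by_key = {u.digest.key: u for u in uniq}
    for digests in digest_map.values():
        for d in digests:
            u = by_key.get(d.key)
            if u is None:
                d.selected = False
                d.probes_5p = d.probes_3p = 0
            else:
                d.selected = True
                d.probes_5p = u.probes_5p
                d.probes_3p = u.probes_3p


def ucsc_url(
    chrom: str,
    span: Optional[tuple[int, int]],
    target_position: int,
    genome_build: str = "custom",
) -> str:
    """UCSC browser position URL, padded by one viewpoint length per side.

    An empty viewpoint gets a 2 kb window centred on the target.
    """
    if span is None:
        lo, hi = target_position - 1000, target_position + 1000
    else:
        pad = span[1] - span[0]
        lo, hi = span[0] - pad, span[1] + pad
    lo = max(lo, 0)
    return (
        "https://genome.ucsc.edu/cgi-bin/hgTracks?"
        f"db={genome_build}&position={chrom}%3A{lo + 1}-{hi}"
    )


def _score_gray(score01: float) -> str:
    g = min(max(round(200 * (1.0 - score01)), 0), 200)
    return f"{g},{g},{g}"


def _probe_gray(mka: float, alignability_max: float) -> str:
    if alignability_max <= 1.0:
        g = 0
    else:
        g = min(max(round(200 * (mka - 1.0) / (alignability_max - 1.0)), 0), 200)
    return f"{g},{g},{g}"


def _score01(vp: Viewpoint) -> float:
    return vp.score / 100.0 if vp.approach == "extended" else vp.score


def write_outputs(
    out_dir: str,
    prefix: str,
    viewpoints: Sequence[Viewpoint],
    digest_map: Mapping[str, list[Digest]],
    genome: GenomeHandle,
    params: DesignParameters,
    genome_build: str = "custom",
    agilent_columns: Sequence[str] = DEFAULT_AGILENT_COLUMNS,
) -> dict[str, str]:
    """Write the seven export files; returns name -> path.

    Files: the genome-wide digest table, the viewpoint table, unique
    target digests (BED), their margins, a five-section UCSC custom-track
    file, the probe BED, and the zipped supplier upload file with probe
    sequences.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sync_digest_flags(viewpoints, digest_map)
    uniq_digests, uniq_probes = deduplicate(viewpoints)
    paths: dict[str, str] = {}

    # 1. genome-wide digest table
    p = out / f"{prefix}_DigestedGenome.txt"
    with open(p, "wt") as fh:
        fh.write(DIGEST_HEADER + "\n")
        for chrom in digest_map:
            for d in digest_map[chrom]:
                m5, m3 = margins_of(d, params.margin_size)
                s5 = genome.fetch(d.chrom, m5.start, m5.end)
                s3 = genome.fetch(d.chrom, m3.start, m3.end)
                fh.write(
                    f"{d.chrom}\t{d.start + 1}\t{d.end}\t{d.index_on_chrom}\t"
                    f"{d.length}\t{gc_fraction(s5):.4f}\t{repeat_fraction(s5):.4f}\t"
                    f"{gc_fraction(s3):.4f}\t{repeat_fraction(s3):.4f}\t"
                    f"{'T' if d.selected else 'F'}\t{d.probes_5p}\t{d.probes_3p}\n"
                )
    paths["digested_genome"] = str(p)

    # 2. viewpoint table
    p = out / f"{prefix}_viewPoints.tsv"
    with open(p, "wt") as fh:
        fh.write(
            "Gene_Symbol\tTarget_Position\tSpan\tUCSC_URL\tN_Selected_Digests\t"
            "Score\tLength\tTSS_Digest_Selected\tApproach\tManually_Edited\n"
        )
        for vp in viewpoints:
            t = vp.target
            span = vp.span
            span_txt = (
                f"{t.chrom}:{span[0] + 1}-{span[1]}" if span else "n/a"
            )
            url = ucsc_url(t.chrom, span, t.position, genome_build)
            fh.write(
                f"{t.label}\t{t.chrom}:{t.position + 1}\t{span_txt}\t{url}\t"
                f"{len(vp.selected)}\t{vp.score:.4f}\t{vp.span_length}\t"
                f"{'T' if vp.tss_digest_selected else 'F'}\t{vp.approach}\t"
                f"{'T' if vp.manually_edited else 'F'}\n"
            )
    paths["viewpoints"] = str(p)

    # 3. unique target digests
    p = out / f"{prefix}_uniqueTargetDigests.bed"
    with open(p, "wt") as fh:
        for u in uniq_digests:
            d = u.digest
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t"
                f"digest_{d.chrom}_{d.index_on_chrom}\n"
            )
    paths["unique_digests"] = str(p)

    # 4. unique target digest margins
    p = out / f"{prefix}_uniqueTargetDigestMargins.txt"
    with open(p, "wt") as fh:
        fh.write("Chromosome\tStart\tEnd\tName\n")
        for u in uniq_digests:
            d = u.digest
            for m in margins_of(d, params.margin_size):
                fh.write(
                    f"{d.chrom}\t{m.start + 1}\t{m.end}\t"
                    f"margin_{d.chrom}_{d.index_on_chrom}_{m.side}\n"
                )
    paths["margins"] = str(p)

    # 5. five-section UCSC custom-track file
    p = out / f"{prefix}_allTracks.bed"
    with open(p, "wt") as fh:
        fh.write(f'track name="{prefix} genomic positions" visibility=1\n')
        for vp in viewpoints:
            t = vp.target
            fh.write(
                f"{t.chrom}\t{t.position}\t{t.position + 1}\t{t.label}\t0\t{t.strand}\n"
            )
        fh.write(f'track name="{prefix} viewpoints" itemRgb="On" visibility=1\n')
        for vp in viewpoints:
            span = vp.span
            if span is None:
                continue
            t = vp.target
            s01 = _score01(vp)
            fh.write(
                f"{t.chrom}\t{span[0]}\t{span[1]}\t{t.label}\t"
                f"{min(max(round(1000 * s01), 0), 1000)}\t{t.strand}\t"
                f"{span[0]}\t{span[1]}\t{_score_gray(s01)}\n"
            )
        fh.write(f'track name="{prefix} restriction fragments" itemRgb="On" visibility=1\n')
        seen: set[tuple[str, int, int]] = set()
        for vp in viewpoints:
            for cand in vp.candidates:
                d = cand.digest
                if d.key in seen:
                    continue
                seen.add(d.key)
                fh.write(
                    f"{d.chrom}\t{d.start}\t{d.end}\t"
                    f"digest_{d.chrom}_{d.index_on_chrom}\t0\t+\t"
                    f"{d.start}\t{d.end}\t0,0,255\n"
                )
        fh.write(f'track name="{prefix} target regions" itemRgb="On" visibility=1\n')
        for u in uniq_digests:
            d = u.digest
            for m in margins_of(d, params.margin_size):
                fh.write(
                    f"{d.chrom}\t{m.start}\t{m.end}\t"
                    f"margin_{d.chrom}_{d.index_on_chrom}_{m.side}\t0\t+\t"
                    f"{m.start}\t{m.end}\t0,0,255\n"
                )
        fh.write(f'track name="{prefix} probes" itemRgb="On" visibility=1\n')
        for i, pr in enumerate(uniq_probes, start=1):
            fh.write(
                f"{pr.chrom}\t{pr.start}\t{pr.end}\tprobe_{i}\t0\t+\t"
                f"{pr.start}\t{pr.end}\t"
                f"{_probe_gray(pr.mean_alignability, params.alignability_max)}\n"
            )
    paths["all_tracks"] = str(p)

    # 6. probe BED
    p = out / f"{prefix}_ProbeFile.bed"
    with open(p, "wt") as fh:
        for i, pr in enumerate(uniq_probes, start=1):
            fh.write(f"{pr.chrom}\t{pr.start}\t{pr.end}\tprobe_{i}\n")
    paths["probes_bed"] = str(p)

    # 7. zipped supplier upload file
    p = out / f"{prefix}_agilentProbeFile.txt.zip"
    lines = ["\t".join(agilent_columns)]
    for i, pr in enumerate(uniq_probes, start=1):
        values = {
            "TargetID": f"{pr.chrom}_{pr.start}_{pr.end}",
            "ProbeID": f"probe_{i}",
            "Sequence": pr.sequence.upper(),
            "Replication": "1",
            "Strand": "+",
            "Chromosome": pr.chrom,
            "Start": str(pr.start + 1),
            "Stop": str(pr.end),
        }
        lines.append("\t".join(values[c] for c in agilent_columns))
    with zipfile.ZipFile(p, "w", zipfile.ZIP_DEFLATED) as zf:
        # fixed timestamp keeps the archive bit-reproducible across runs
        info = zipfile.ZipInfo(
            f"{prefix}_agilentProbeFile.txt", date_time=(1980, 1, 1, 0, 0, 0)
        )
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, "\n".join(lines) + "\n")
    paths["agilent"] = str(p)

    return paths


def read_digested_genome(path: str) -> list[Digest]:
    """Re-parse a digest table into Digest records (round-trip helper).

    GC/repeat fields of the returned digests are the 5'/3' margin values
    averaged into the digest-level slots is *not* attempted; they are
    left at 0 because the file stores margin-level composition.
    """
    digests: list[Digest] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("Chromosome"):
            raise ValueError(f"{path}: not a digest table (bad header)")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns")
            digests.append(
                Digest(
                    chrom=fields[0],
                    start=int(fields[1]) - 1,
                    end=int(fields[2]),
                    index_on_chrom=int(fields[3]),
                    selected=fields[9] == "T",
                    probes_5p=int(fields[10]),
                    probes_3p=int(fields[11]),
                )
            )
    return digests
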