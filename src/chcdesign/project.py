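"""Design pipeline orchestration and project persistence.

A project file is a versioned, human-readable JSON document recording the
parameters, input files (with checksums to detect drift), resolved
targets, every viewpoint including manual-edit snapshots, and the design
summary. The genome-wide digest list is not persisted: it is a pure
function of the genome and enzyme set and is regenerated on demand.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .alignability import AlignabilityMap, load_alignability
from .digestion import Digest, digest_genome, get_enzyme
from .export import DesignSummary, summarize, sync_digest_flags, write_outputs
from .genome import GenomeHandle
from .params import DesignParameters
from .probes import Probe
from .targets import (
    Target,
    all_symbols,
    parse_transcripts,
    read_gene_list,
    resolve_symbols,
    suggest_corrections,
    targets_from_bed6,
)
from .viewpoints import (
    CandidateDigest,
    ScoreModel,
    Viewpoint,
    build_extended_viewpoint,
    build_simple_viewpoint,
    patch_viewpoint,
)

logger = logging.getLogger(__name__)

PROJECT_VERSION = "1"

__all__ = [
    "DesignConfig",
    "Project",
    "DesignRun",
    "run_design",
    "save_project",
    "load_project",
]


@dataclass
class DesignConfig:
    """Inputs of a design run; all parameters default to the standard values."""

    genome: str
    alignability: str
    annotation: Optional[str] = None
    gene_list: Optional[str] = None
    symbols: Optional[Sequence[str]] = None
    bed6: Optional[str] = None
    all_genes: bool = False
    params: DesignParameters = field(default_factory=DesignParameters)
    genome_build: str = "custom"

    def validate(self) -> None:
        for name in ("genome", "alignability"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} file missing: {p!r}")
        wants_genes = self.gene_list or self.symbols or self.all_genes
        if wants_genes and not self.annotation:
            raise ValueError("gene-symbol targets require an annotation file")
        if not wants_genes and not self.bed6:
            raise ValueError("no targets: give symbols, a gene list, a BED6 file, "
                             "or all_genes with an annotation")
        for name in ("annotation", "gene_list", "bed6"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} file missing: {p!r}")


@dataclass
class Project:
    """The persisted record of a design."""

    params: DesignParameters
    genome_path: str
    alignability_path: str
    annotation_path: Optional[str]
    bed6_path: Optional[str]
    genome_build: str
    checksums: dict[str, str]
    targets: list[Target]
    unmapped: list[str]
    mu_D_bar: float
    viewpoints: list[Viewpoint]
    summary: DesignSummary
    version: str = PROJECT_VERSION


@dataclass
class DesignRun:
    """A finished run: the project plus the runtime objects behind it."""

    project: Project
    genome: GenomeHandle
    amap: AlignabilityMap
    digest_map: dict[str, list[Digest]]
    model: ScoreModel

    def export(self, out_dir: str, prefix: str) -> dict[str, str]:
        return write_outputs(
            out_dir,
            prefix,
            self.project.viewpoints,
            self.digest_map,
            self.genome,
            self.project.params,
            genome_build=self.project.genome_build,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_targets(config: DesignConfig) -> tuple[list[Target], list[str]]:
    if config.bed6 and not (config.gene_list or config.symbols or config.all_genes):
        return targets_from_bed6(config.bed6), []
    transcripts = parse_transcripts(config.annotation)
    if config.all_genes:
        symbols = all_symbols(transcripts)
    elif config.symbols is not None:
        symbols = list(config.symbols)
    else:
        symbols = read_gene_list(config.gene_list)
    targets, unmapped = resolve_symbols(symbols, transcripts)
    if unmapped:
        hints = suggest_corrections(unmapped, transcripts)
        for sym in unmapped:
            hint = f" (did you mean {', '.join(hints[sym])}?)" if hints[sym] else ""
            logger.warning("unmappable symbol: %s%s", sym, hint)
    return targets, unmapped


def run_design(config: DesignConfig) -> DesignRun:
    """Run the full pipeline: digest, resolve targets, build viewpoints, summarize."""
    config.validate()
    params = config.params
    logger.info("loading genome %s", config.genome)
    genome = GenomeHandle(config.genome)
    logger.info("loading alignability map %s", config.alignability)
    amap = load_alignability(config.alignability, k=params.k)
    logger.info("digesting genome with %s", ", ".join(params.enzymes))
    enzymes = [get_enzyme(e) for e in params.enzymes]
    digest_map = digest_genome(genome, enzymes)
    model = ScoreModel.from_design(digest_map, params)
    logger.info("mean digest size: %.1f bp", model.mu_D_bar)
    targets, unmapped = _resolve_targets(config)
    if not targets:
        raise ValueError("no valid targets could be resolved")
    logger.info("resolved %d targets (%d unmappable symbols)", len(targets), len(unmapped))
    viewpoints: list[Viewpoint] = []
    for target in targets:
        if params.approach == "extended":
            vp = build_extended_viewpoint(target, digest_map, genome, amap, params, model)
        else:
            vp = build_simple_viewpoint(target, digest_map, genome, amap, params, model)
            if params.allow_patching:
                vp = patch_viewpoint(vp, params, model)
        viewpoints.append(vp)
    logger.info("built %d viewpoints (%d valid)",
                len(viewpoints), sum(vp.is_valid for vp in viewpoints))
    sync_digest_flags(viewpoints, digest_map)
    summary = summarize(viewpoints, params)
    checksums = {
        "genome": _sha256(config.genome),
        "alignability": _sha256(config.alignability),
    }
    if config.annotation:
        checksums["annotation"] = _sha256(config.annotation)
    if config.bed6:
        checksums["bed6"] = _sha256(config.bed6)
    project = Project(
        params=params,
        genome_path=str(config.genome),
        alignability_path=str(config.alignability),
        annotation_path=config.annotation,
        bed6_path=config.bed6,
        genome_build=config.genome_build,
        checksums=checksums,
        targets=targets,
        unmapped=unmapped,
        mu_D_bar=model.mu_D_bar,
        viewpoints=viewpoints,
        summary=summary,
    )
    return DesignRun(project, genome, amap, digest_map, model)


# ---------------------------------------------------------------------------
# serialization


def _probe_to_dict(p: Probe) -> dict:
    return {
        "chrom": p.chrom, "start": p.start, "end": p.end, "side": p.side,
        "sequence": p.sequence, "gc_fraction": p.gc_fraction,
        "repeat_fraction": p.repeat_fraction,
        "mean_alignability": p.mean_alignability
        if p.mean_alignability != float("inf") else "inf",
    }


def _probe_from_dict(d: dict) -> Probe:
    mka = d["mean_alignability"]
    return Probe(
        chrom=d["chrom"], start=d["start"], end=d["end"], side=d["side"],
        sequence=d["sequence"], gc_fraction=d["gc_fraction"],
        repeat_fraction=d["repeat_fraction"],
        mean_alignability=float("inf") if mka == "inf" else float(mka),
    )


def _digest_to_dict(d: Digest) -> dict:
    return {
        "chrom": d.chrom, "start": d.start, "end": d.end,
        "index_on_chrom": d.index_on_chrom,
        "gc_fraction": d.gc_fraction, "repeat_fraction": d.repeat_fraction,
        "selected": d.selected, "probes_5p": d.probes_5p, "probes_3p": d.probes_3p,
    }


def _viewpoint_to_dict(vp: Viewpoint) -> dict:
    return {
        "target": vp.target.__dict__,
        "approach": vp.approach,
        "tss_digest_key": list(vp.tss_digest_key) if vp.tss_digest_key else None,
        "score": vp.score,
        "patched": vp.patched,
        "manually_edited": vp.manually_edited,
        "snapshot": [list(k) for k in vp.snapshot],
        "candidates": [
            {
                "digest": _digest_to_dict(c.digest),
                "digest_class": c.digest_class,
                "selected": c.selected,
                "probes_5p": [_probe_to_dict(p) for p in c.probes_5p],
                "probes_3p": [_probe_to_dict(p) for p in c.probes_3p],
            }
            for c in vp.candidates
        ],
    }


def _viewpoint_from_dict(d: dict) -> Viewpoint:
    return Viewpoint(
        target=Target(**d["target"]),
        approach=d["approach"],
        candidates=[
            CandidateDigest(
                digest=Digest(**c["digest"]),
                digest_class=c["digest_class"],
                probes_5p=[_probe_from_dict(p) for p in c["probes_5p"]],
                probes_3p=[_probe_from_dict(p) for p in c["probes_3p"]],
                selected=c["selected"],
            )
            for c in d["candidates"]
        ],
        tss_digest_key=tuple(d["tss_digest_key"]) if d["tss_digest_key"] else None,
        score=d["score"],
        patched=d["patched"],
        manually_edited=d["manually_edited"],
        snapshot=tuple(tuple(k) for k in d["snapshot"]),
    )


def save_project(project: Project, path: str) -> None:
    """Write the project as versioned JSON."""
    doc = {
        "format": "chcdesign-project",
        "version": project.version,
        "params": project.params.to_dict(),
        "genome_path": project.genome_path,
        "alignability_path": project.alignability_path,
        "annotation_path": project.annotation_path,
        "bed6_path": project.bed6_path,
        "genome_build": project.genome_build,
        "checksums": project.checksums,
        "targets": [t.__dict__ for t in project.targets],
        "unmapped": project.unmapped,
        "mu_D_bar": project.mu_D_bar,
        "viewpoints": [_viewpoint_to_dict(vp) for vp in project.viewpoints],
        "summary": project.summary.to_dict(),
    }
    with open(path, "wt") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_project(path: str) -> Project:
    """Load a project file; refuses files of a different format version."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "chcdesign-project":
        raise ValueError(f"{path}: not a chcdesign project file")
    version = doc.get("version")
    if version != PROJECT_VERSION:
        raise ValueError(
            f"{path}: project version {version!r} not supported by this tool "
            f"(expected {PROJECT_VERSION!r})"
        )
    return Project(
        params=DesignParameters.from_dict(doc["params"]),
        genome_path=doc["genome_path"],
        alignability_path=doc["alignability_path"],
        annotation_path=doc["annotation_path"],
        bed6_path=doc["bed6_path"],
        genome_build=doc["genome_build"],
        checksums=doc["checksums"],
        targets=[Target(**t) for t in doc["targets"]],
        unmapped=list(doc["unmapped"]),
        mu_D_bar=doc["mu_D_bar"],
        viewpoints=[_viewpoint_from_dict(v) for v in doc["viewpoints"]],
        summary=DesignSummary.from_dict(doc["summary"]),
        version=version,
    )
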