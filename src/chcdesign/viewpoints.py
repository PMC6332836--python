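"""Viewpoint construction and quality scores.

Three strategies build viewpoints around a target position (typically a
TSS):

* **simple** — the single digest overlapping the target is selected if it
  passes the digest filters; its two neighbours are kept as toggleable
  candidates.
* **simple-patched** — simple, plus a rescue heuristic: when the simple
  score falls below a threshold (default 0.6, i.e. the target sits near a
  digest boundary), the adjacent digest closer to the target is added if
  it passes the same filters.
* **extended** — every digest overlapping a strand-aware window
  [target - up_max, target + down_max] that passes the filters is
  selected.

Scores. The simple score models the region of interest around the target
as a normal distribution centred on it with standard deviation
sigma = mean_digest_size / 6, and equals the probability mass of that
normal over the span of selected digests: ~1 for a long, well-centred
digest; ~0.5 when the target sits at a digest end. The extended score
uses an asymmetric pair of half-normals (sigma = up_max/6 upstream,
down_max/6 downstream, each side carrying probability 0.5) and reports
the covered mass as a percentage: digests near the target contribute
most, and full coverage of the window approaches 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import norm

from .alignability import AlignabilityMap
from .digestion import Digest, digest_at, mean_digest_size
from .genome import GenomeHandle
from .params import DesignParameters
from .probes import BALANCED, Probe, REJECTED, UNBALANCED, classify_digest
from .targets import Target

__all__ = [
    "ScoreModel",
    "CandidateDigest",
    "Viewpoint",
    "simple_score",
    "extended_score",
    "build_simple_viewpoint",
    "patch_viewpoint",
    "build_extended_viewpoint",
    "set_digest_selected",
    "reset_viewpoint",
]


@dataclass(frozen=True)
class ScoreModel:
    """Standard deviations of the normal score models.

    ``sigma_simple`` is one sixth of the genome-wide mean digest size;
    ``sigma_up``/``sigma_down`` are one sixth of the extended-viewpoint
    window sizes, so that six standard deviations (~99.999% of each
    half-normal's mass) span exactly the allowed extension.
    """

    mu_D_bar: float
    up_max: int
    down_max: int

    @property
    def sigma_simple(self) -> float:
        return self.mu_D_bar / 6.0

    @property
    def sigma_up(self) -> float:
        return self.up_max / 6.0

    @property
    def sigma_down(self) -> float:
        return self.down_max / 6.0

    def __post_init__(self) -> None:
        if self.mu_D_bar <= 0 or self.up_max <= 0 or self.down_max <= 0:
            raise ValueError("score-model scales must be positive")

    @classmethod
    def from_design(
        cls, digest_map: Mapping[str, list[Digest]], params: DesignParameters
    ) -> "ScoreModel":
        """Estimate the model from the digest of the enzyme set in use."""
        return cls(
            mu_D_bar=mean_digest_size(digest_map),
            up_max=params.up_max,
            down_max=params.down_max,
        )


def simple_score(
    span_start: int, span_end: int, tss: int, model: ScoreModel
) -> float:
    """Normal probability mass over the selected span, centred at the TSS.

    Phi((end-tss)/sigma) - Phi((start-tss)/sigma); an empty span scores 0.
    Symmetric in the two sides, so strand never matters.
    """
    if span_end <= span_start:
        return 0.0
    s = model.sigma_simple
    return float(norm.cdf((span_end - tss) / s) - norm.cdf((span_start - tss) / s))


def extended_score(
    intervals: Iterable[tuple[int, int]], tss: int, strand: str, model: ScoreModel
) -> float:
    """Covered half-normal mass of the selected digests, as a percentage.

    Each covered interval is split at the TSS; upstream parts (strand
    aware: lower coordinates for '+', higher for '-') contribute mass
    under a half-normal with sigma_up, downstream parts under one with
    sigma_down. The target base itself counts as downstream. Coverage is
    not truncated at the window edge; mass beyond six sigma is < 1e-9.
    """
    total = 0.0
    for s, e in intervals:
        if e <= s:
            continue
        if strand == "-":
            rel_lo, rel_hi = tss - e + 1, tss - s + 1
        else:
            rel_lo, rel_hi = s - tss, e - tss
        hi_u = min(rel_hi, 0)
        if rel_lo < hi_u:
            total += float(
                norm.cdf(hi_u / model.sigma_up) - norm.cdf(rel_lo / model.sigma_up)
            )
        lo_d = max(rel_lo, 0)
        if lo_d < rel_hi:
            total += float(
                norm.cdf(rel_hi / model.sigma_down) - norm.cdf(lo_d / model.sigma_down)
            )
    return 100.0 * total


@dataclass
class CandidateDigest:
    """A digest evaluated for a viewpoint, with its class and probes."""

    digest: Digest
    digest_class: str  # balanced | unbalanced | rejected
    probes_5p: list[Probe] = field(default_factory=list)
    probes_3p: list[Probe] = field(default_factory=list)
    selected: bool = False

    @property
    def available(self) -> bool:
        """False means the digest cannot be chosen (shown as "n/a")."""
        return self.digest_class != REJECTED

    @property
    def probes(self) -> list[Probe]:
        return self.probes_5p + self.probes_3p

    @property
    def key(self) -> tuple[str, int, int]:
        return self.digest.key


@dataclass
class Viewpoint:
    """A target plus its candidate and selected digests and quality score."""

    target: Target
    approach: str  # simple | extended
    candidates: list[CandidateDigest]
    tss_digest_key: Optional[tuple[str, int, int]]
    score: float = 0.0
    patched: bool = False
    manually_edited: bool = False
    snapshot: tuple[tuple[str, int, int], ...] = ()

    @property
    def selected(self) -> list[CandidateDigest]:
        return [c for c in self.candidates if c.selected]

    @property
    def is_valid(self) -> bool:
        """A valid viewpoint has at least one selected digest."""
        return any(c.selected for c in self.candidates)

    @property
    def span(self) -> Optional[tuple[int, int]]:
        """Union span of the selected digests (None when invalid)."""
        sel = self.selected
        if not sel:
            return None
        return (min(c.digest.start for c in sel), max(c.digest.end for c in sel))

    @property
    def span_length(self) -> int:
        span = self.span
        return 0 if span is None else span[1] - span[0]

    @property
    def tss_digest_selected(self) -> bool:
        return any(c.selected and c.key == self.tss_digest_key for c in self.candidates)

    @property
    def probes(self) -> list[Probe]:
        return [p for c in self.selected for p in c.probes]

    def candidate_by_key(self, key: tuple[str, int, int]) -> CandidateDigest:
        for c in self.candidates:
            if c.key == key:
                return c
        raise KeyError(f"digest {key} is not a candidate of this viewpoint")

    def take_snapshot(self) -> None:
        self.snapshot = tuple(c.key for c in self.selected)


def _selectable(digest_class: str, params: DesignParameters) -> bool:
    if digest_class == BALANCED:
        return True
    return digest_class == UNBALANCED and params.allow_unbalanced


def _recompute_score(vp: Viewpoint, model: ScoreModel) -> None:
    tss = vp.target.position
    if vp.approach == "extended":
        intervals = [(c.digest.start, c.digest.end) for c in vp.selected]
        vp.score = extended_score(intervals, tss, vp.target.strand, model)
    else:
        span = vp.span
        vp.score = 0.0 if span is None else simple_score(span[0], span[1], tss, model)


def build_simple_viewpoint(
    target: Target,
    digest_map: Mapping[str, list[Digest]],
    genome: GenomeHandle,
    amap: AlignabilityMap,
    params: DesignParameters,
    model: ScoreModel,
) -> Viewpoint:
    """Simple strategy: select the digest overlapping the target.

    The TSS digest is selected iff it classifies as balanced (or
    unbalanced when allowed); the two adjacent digests are evaluated and
    stored as toggleable candidates. Viewpoints with no selected digest
    are retained but invalid.
    """
    if target.chrom not in digest_map:
        raise KeyError(f"no digests for chromosome {target.chrom!r}")
    digests = digest_map[target.chrom]
    i = digest_at(digests, target.position)
    candidates: list[CandidateDigest] = []
    for j in range(max(i - 1, 0), min(i + 2, len(digests))):
        cls, p5, p3 = classify_digest(digests[j], genome, amap, params)
        cand = CandidateDigest(digests[j], cls, p5, p3)
        if j == i and _selectable(cls, params):
            cand.selected = True
        candidates.append(cand)
    vp = Viewpoint(
        target=target,
        approach="simple",
        candidates=candidates,
        tss_digest_key=digests[i].key,
    )
    _recompute_score(vp, model)
    vp.take_snapshot()
    return vp


def patch_viewpoint(
    vp: Viewpoint,
    params: DesignParameters,
    model: ScoreModel,
) -> Viewpoint:
    """Simple-patched rescue: add the nearer adjacent digest when the score is low.

    If the simple score is below the patching threshold, the adjacent
    digest on the side of the digest boundary nearer the target is added,
    provided it passes the same length/class criteria as primary
    selection. At most one digest is added; the score is recomputed over
    the union span and the post-patch state becomes the reset snapshot.
    """
    if vp.approach != "simple":
        raise ValueError("patching applies to simple viewpoints only")
    if vp.score >= params.patch_threshold:
        return vp
    if vp.tss_digest_key is None:
        return vp
    tss_cand = vp.candidate_by_key(vp.tss_digest_key)
    d = tss_cand.digest
    tss = vp.target.position
    # the neighbour adjacent to the boundary nearer the TSS; ties go 5'
    side_5p = (tss - d.start) <= (d.end - 1 - tss)
    neighbour = None
    for c in vp.candidates:
        if side_5p and c.digest.end == d.start:
            neighbour = c
        elif not side_5p and c.digest.start == d.end:
            neighbour = c
    if neighbour is None or neighbour.selected:
        return vp
    if not _selectable(neighbour.digest_class, params):
        return vp
    neighbour.selected = True
    vp.patched = True
    _recompute_score(vp, model)
    vp.take_snapshot()
    return vp


def build_extended_viewpoint(
    target: Target,
    digest_map: Mapping[str, list[Digest]],
    genome: GenomeHandle,
    amap: AlignabilityMap,
    params: DesignParameters,
    model: ScoreModel,
) -> Viewpoint:
    """Extended strategy: select all passing digests in the strand-aware window.

    The window is [target - up_max, target + down_max] for '+' targets
    and reflected for '-' targets. Digests overlapping it that classify
    as balanced (or unbalanced when allowed) are selected; the rest stay
    as unselected candidates for manual toggling.
    """
    if target.chrom not in digest_map:
        raise KeyError(f"no digests for chromosome {target.chrom!r}")
    digests = digest_map[target.chrom]
    tss = target.position
    if target.strand == "-":
        lo, hi = tss - params.down_max, tss + params.up_max + 1
    else:
        lo, hi = tss - params.up_max, tss + params.down_max + 1
    candidates: list[CandidateDigest] = []
    for dig in digests:
        if dig.end <= lo or dig.start >= hi:
            continue
        cls, p5, p3 = classify_digest(dig, genome, amap, params)
        cand = CandidateDigest(dig, cls, p5, p3)
        cand.selected = _selectable(cls, params)
        candidates.append(cand)
    tss_key = digests[digest_at(digests, tss)].key
    vp = Viewpoint(
        target=target,
        approach="extended",
        candidates=candidates,
        tss_digest_key=tss_key,
    )
    _recompute_score(vp, model)
    vp.take_snapshot()
    return vp


def set_digest_selected(
    vp: Viewpoint,
    key: tuple[str, int, int],
    flag: bool,
    model: ScoreModel,
) -> Viewpoint:
    """Manually select or deselect a candidate digest.

    Candidates whose class is rejected cannot be selected (the "n/a"
    case). The score is recomputed and the viewpoint flagged as edited.
    """
    cand = vp.candidate_by_key(key)
    if flag and not cand.available:
        raise ValueError(
            f"digest {key} cannot be selected: no usable probe placement (n/a)"
        )
    cand.selected = flag
    vp.manually_edited = True
    _recompute_score(vp, model)
    return vp


def reset_viewpoint(vp: Viewpoint, model: ScoreModel) -> Viewpoint:
    """Restore the original (post-construction) selection and clear the flag."""
    snapshot = set(vp.snapshot)
    for c in vp.candidates:
        c.selected = c.key in snapshot
    vp.manually_edited = False
    _recompute_score(vp, model)
    return vp
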