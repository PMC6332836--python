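"""Design parameters for a capture Hi-C probe design run.

The defaults reproduce the standard settings for promoter capture Hi-C:
120 bp baits, GC content between 35% and 65%, mean 50-mer alignability of
at most 2, 250 bp digest margins, a 120 bp minimum digest size, one probe
per margin, and a 5000/1500 bp upstream/downstream window for extended
viewpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class DesignParameters:
    """Full parameter set controlling digest, probe and viewpoint selection.

    Attributes
    ----------
    probe_length : int
        Length of each bait in bp.
    gc_min, gc_max : float
        Inclusive bounds on probe GC fraction.
    alignability_max : float
        Maximum mean k-mer alignability of a usable probe (inclusive).
    margin_size : int
        Width in bp of the outermost stretch of each digest end that is
        tiled with probes.
    min_digest_size : int
        Digests shorter than this cannot be selected.
    b_min : int
        Minimum number of probes per margin of a balanced digest; an
        unbalanced digest needs at least ``2 * b_min`` probes in total.
    allow_unbalanced : bool
        Whether digests with unequal probe counts per margin may be
        selected automatically.
    allow_patching : bool
        Whether simple viewpoints scoring below ``patch_threshold`` get an
        adjacent digest added (the simple-patched strategy).
    patch_threshold : float
        Score below which patching is attempted.
    up_max, down_max : int
        Strand-aware extension of extended viewpoints in bp.
    enzymes : tuple of str
        Names of the restriction enzymes used for the in-silico digest.
    approach : str
        ``"simple"`` or ``"extended"``.
    k : int
        k-mer size of the alignability map.
    """

    probe_length: int = 120
    gc_min: float = 0.35
    gc_max: float = 0.65
    alignability_max: float = 2.0
    margin_size: int = 250
    min_digest_size: int = 120
    b_min: int = 1
    allow_unbalanced: bool = False
    allow_patching: bool = False
    patch_threshold: float = 0.6
    up_max: int = 5000
    down_max: int = 1500
    enzymes: tuple[str, ...] = ("DpnII",)
    approach: str = "simple"
    k: int = 50

    def __post_init__(self) -> None:
        if isinstance(self.enzymes, list):
            self.enzymes = tuple(self.enzymes)
        if not 0.0 <= self.gc_min <= self.gc_max <= 1.0:
            raise ValueError(
                f"need 0 <= gc_min <= gc_max <= 1, got {self.gc_min}, {self.gc_max}"
            )
        for name in ("probe_length", "margin_size", "min_digest_size",
                     "up_max", "down_max", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.b_min < 1:
            raise ValueError("b_min must be >= 1")
        if self.alignability_max <= 0:
            raise ValueError("alignability_max must be positive")
        if self.approach not in ("simple", "extended"):
            raise ValueError(f"unknown approach {self.approach!r}")

    def with_(self, **kwargs) -> "DesignParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "probe_length": self.probe_length,
            "gc_min": self.gc_min,
            "gc_max": self.gc_max,
            "alignability_max": self.alignability_max,
            "margin_size": self.margin_size,
            "min_digest_size": self.min_digest_size,
            "b_min": self.b_min,
            "allow_unbalanced": self.allow_unbalanced,
            "allow_patching": self.allow_patching,
            "patch_threshold": self.patch_threshold,
            "up_max": self.up_max,
            "down_max": self.down_max,
            "enzymes": list(self.enzymes),
            "approach": self.approach,
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignParameters":
        return cls(**{**d, "enzymes": tuple(d.get("enzymes", ("DpnII",)))})
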