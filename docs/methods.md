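# Methods

## The design problem

Capture Hi-C enriches a Hi-C library for chosen viewpoints by
hybridization to biotinylated probes. Hybrid molecules produced by
re-ligation and sonication carry, on each side, roughly the outermost
300–500 bp of a restriction digest, so probes are only useful near cut
sites. `chcdesign` therefore treats only the margins of digests (default
250 bp per end) as target regions, and formalizes the probe, digest and
viewpoint selection rules so a design is reproducible and documentable.

All internal coordinates are 0-based, half-open; conversions to 1-based
inclusive coordinates happen only when writing the digest and viewpoint
tables. There is no randomness anywhere in the pipeline: identical
inputs produce bit-identical outputs (the supplier zip archive is
written with a fixed timestamp for this reason).

## In-silico digestion

Each chromosome is scanned case-insensitively for every enzyme's
recognition motif; a cut falls at `motif_start + cut_offset` (HindIII
A^AGCTT → offset 1, DpnII ^GATC → offset 0). The scan advances one base
at a time so overlapping motif occurrences all cut. Digests are the
intervals between consecutive cuts plus the two flanking intervals, so
they partition `[0, chrom_length)` exactly; cuts falling at position 0
or at the chromosome end are absorbed into the partition rather than
producing zero-length digests. Only palindromic sites are fully
supported; a non-palindromic site is scanned on the forward strand only
and a warning is logged, since every enzyme in routine CHC use
(HindIII, DpnII, MboI, EcoRI, BglII, NlaIII, …) is palindromic.

## Probe usability

A probe (default 120 bp) is usable iff

* GC fraction lies in `[gc_min, gc_max]` (defaults 0.35/0.65,
  **inclusive** at both ends — "between 35 and 65%" is read as a closed
  interval, and a mean alignability of exactly 2.0 passes because only
  values *above* 2 are rejected);
* its mean k-mer alignability is finite and ≤ `alignability_max`;
* it contains no ambiguity codes (N probes cannot be synthesized
  reliably).

The mean k-mer alignability of a probe of length *l* at position *p* is
the mean of the genome-wide occurrence counts of its *l−k+1* constituent
k-mers (k = 50 by default, matching standard 50-mer alignability
tracks). Counts come from a standardized bedGraph score *s* ∈ [0, 1] via
`round(1/s)` — 0.25 ⇔ 4 occurrences. Rounding (rather than flooring)
was chosen so that float representations such as 0.3333 invert to
exactly 3. Positions not covered by any bedGraph interval are
unmappable: their count is +∞ and any probe overlapping them is
rejected, because mappability software emits no line at all for
unalignable k-mers and treating a gap as "0 occurrences" would wrongly
pass the threshold. Interval lookup is by binary search
(`numpy.searchsorted` over the sorted interval starts).

Repeat content is defined as the soft-mask (lowercase) fraction of the
sequence, the convention of UCSC soft-masked genomes; no attempt is made
to parse RepeatMasker output.

## Probe placement and digest classes

Margins are `min(margin_size, floor(length/2))` wide so they never
overlap; for odd short digests the middle base belongs to neither
margin. Placement starts flush with the cut site and moves inward 1 bp
at a time, keeping the first `b_min` usable probes per margin; probes
may overlap each other (consecutive selected probes typically differ by
1 bp) but must lie entirely inside their digest — a probe never spans a
cut site — and their anchored end (start for the 5' margin, end for the
3') must fall inside the margin.

A digest shorter than `min_digest_size` (default 120 bp) is rejected
outright. Otherwise it is *balanced* when both margins reach `b_min`
probes. When unbalanced digests are allowed and a side falls short, the
richer margin (ties to 5') is rescanned up to `2·b_min` probes in
total; reaching that total makes the digest *unbalanced*. The original
tool does not document how the extra probes are distributed in this
case; scanning the richer margin first and stopping at the total
minimizes probe spend and reproduces the documented 2·b_min arithmetic.

## Viewpoint strategies and scores

*Simple.* The digest overlapping the target position is selected iff it
passes the class rule (balanced, or unbalanced when allowed); the two
adjacent digests are evaluated and stored as toggleable candidates
(unusable neighbours are flagged unavailable, the "n/a" case). A
viewpoint with no selected digest is kept but marked invalid.

The simple score models the region of interest as a normal distribution
centred at the TSS with σ = μ̄_D/6, where μ̄_D is the mean digest length
over **all** digests of the same enzyme set, and equals the probability
mass over the span of the selected digests. Six standard deviations on
each side carry essentially all of the mass, so a digest extending a
full average-digest-length on both sides of the TSS scores ≈ 1, while a
TSS flush with a cut site scores ≈ 0.5. After patching or manual edits
the score is recomputed over the **union span** of all selected digests
(the original description defines it only for the single TSS digest;
integrating the union is the natural extension and keeps the score
monotone under adding digests).

*Simple-patched.* When the simple score is below `patch_threshold`
(default 0.6, exposed as a parameter), the adjacent digest on the side
of the digest boundary nearer the TSS (ties broken toward the 5' side)
is added, provided it passes the same length and class criteria as
primary selection — the stricter reading of "satisfies length,
alignability, and GC content criteria". At most one digest is added.

*Extended.* All digests overlapping the strand-aware window
`[TSS − up_max, TSS + down_max]` (reflected for minus-strand targets)
that pass the filters are selected. The score uses two half-normals
with σ_up = up_max/6 and σ_down = down_max/6: each covered interval is
split at the TSS, each part contributes its CDF mass on its side, and
the total is reported ×100 as a percentage — full coverage of both
windows approaches 100, and digests near the TSS contribute most.
Coverage is deliberately not truncated at the window edge: a digest
overhanging the boundary contributes its full mass, which beyond 6σ is
< 1e-9 and numerically immaterial. The TSS base itself counts as
downstream (offset 0 belongs to the downstream half-normal); this is an
arbitrary but fixed convention.

Manual curation is supported through `set_digest_selected` /
`reset_viewpoint`: toggling recomputes probes and score and flags the
viewpoint as edited; reset restores the snapshot taken at construction
(after patching, when patching ran) and clears the flag.

## Targets

Gene symbols are matched case-sensitively against a refGene-style
annotation; each matched gene contributes one target per **distinct**
TSS (isoforms sharing a start are merged, exact positions only — nearby
TSS are not clustered). Unmatched symbols are reported verbatim, with
case-insensitive suggestions where available. BED6 records produce one
target at the floor midpoint of the interval (ties toward the lower
coordinate); strand `.` is treated as `+`, which is harmless for the
symmetric simple score and documented for the asymmetric extended
window.

## Outputs

Digests and probes shared between overlapping viewpoints are
deduplicated by coordinates before counting and export; the capture
size is the length of the union of unique probe intervals. The digest
table reports margin-level GC and repeat content for both margins (the
file layout is documented in the header line) alongside selection flags
and per-margin probe counts, and round-trips losslessly. In the UCSC
custom-track file, viewpoints and probes are shaded on a linear
grayscale ramp, `g = 200·(1 − score)` and
`g = 200·(MKA − 1)/(alignability_max − 1)` respectively, clipped to
[0, 200]: a perfect viewpoint and a uniquely mapping probe are black,
as in the original track convention; the ramp between the endpoints is
this package's choice. The supplier upload file uses a common
Agilent-style column set (TargetID, ProbeID, Sequence, Replication,
Strand, Chromosome, Start, Stop); vendors differ, so the column order
is overridable.

## Synthetic data

The fixture generator emits genomes in which every structural feature
is planted: enzyme motifs occur exactly at the requested cut positions
and nowhere else (the filler is rejection-repaired until motif-free),
GC-controlled blocks hit their target fraction by exact base counts,
soft-masked runs are lowercase, alignability intervals and unmappable
gaps are written verbatim, and genes emit strand-aware TSS. The demo
scenario uses a 50 kb chromosome with DpnII sites every 430 bp — the
genome-wide mean digest size typical of a 4-cutter — five genes
including one with two promoters, multi-mapping intervals at scores 0.5
and 0.25, and one alignability gap. These fixtures reproduce the
coordinate semantics of real inputs but none of their biology (no
repeat landscape, no promoter GC elevation, no realistic digest-length
dispersion), so passing tests demonstrate correctness of the selection
logic and scores, not expected yields on a real genome.

The acceptance script measures, on such fixtures, the patching
activation boundary (bisection over TSS offsets at 1 bp resolution on a
43 kb / 100-digest genome, resolving the boundary to one score step of
about 0.006), the score→count inversion at 0.25, and the boundary-TSS
score on a 50-digest genome whose target digest spans more than ten
standard deviations. Problem sizes were chosen so the whole script runs
in seconds on one CPU.

## Known limitations

* Non-palindromic enzymes are scanned on one strand only.
* Methylation-sensitive or partial digestion is not modelled.
* Probe thermodynamics (melting temperature, secondary structure) are
  out of scope; GC and alignability are the only usability criteria.
* Symbol aliasing (HGNC history) is not consulted; unmapped symbols are
  only reported.
* bigWig alignability tracks must be converted to bedGraph first.
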