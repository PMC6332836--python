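# chcdesign

Probe (bait) design for capture Hi-C (CHC) experiments.

CHC enriches a Hi-C library for viewpoints of interest — typically gene
promoters, but also GWAS hits or arbitrary genomic regions — using
biotinylated oligonucleotide probes. Because valid Hi-C read pairs map
almost exclusively to the ends of restriction fragments ("digests"),
probes belong in the *margins* of digests, next to the cut sites.
`chcdesign` performs the full design in silico:

1. **Digestion** — cut a soft-masked FASTA genome with one or more
   restriction enzymes (HindIII, DpnII, … or custom `name,site,offset`),
   producing the genome-wide digest partition.
2. **Probe placement** — within each digest margin (default 250 bp),
   scan from the cut site inward and keep the first *b*<sub>min</sub>
   probes with GC content in [35%, 65%] and mean 50-mer alignability
   (MKA) ≤ 2. A digest is *balanced* when both margins hold
   *b*<sub>min</sub> probes, *unbalanced* when 2·*b*<sub>min</sub> probes
   sit unevenly across the margins.
3. **Viewpoints** — three strategies:
   * *simple*: the one digest overlapping each TSS;
   * *simple-patched*: additionally rescue viewpoints whose score falls
     below 0.6 by adding the adjacent digest nearer the TSS;
   * *extended*: every passing digest overlapping a strand-aware window
     `[TSS − up_max, TSS + down_max]` (defaults 5000/1500 bp).
4. **Export** — the seven standard output files (digest table, viewpoint
   table, unique target digests and margins, a five-track UCSC custom
   track file, probe BED, zipped supplier upload file with sequences).

Viewpoint quality is scored with a normal model centred on the TSS. For
simple viewpoints the score is the probability mass
Φ((end−TSS)/σ) − Φ((start−TSS)/σ) over the selected span, with
σ = μ̄<sub>D</sub>/6 estimated from the genome-wide mean digest size: ≈ 1
for long, well-centred digests and ≈ 0.5 when the TSS sits on a cut
site. Extended viewpoints use an asymmetric pair of half-normals
(σ = up_max/6 and down_max/6) and report covered mass as a percentage.

## Worked example

Everything runs on synthetic data with planted, known-answer structure
(no downloads). Generate the demo data set — a 50 kb chromosome with
DpnII sites every 430 bp, five genes on both strands, and an
alignability map containing multi-mapping intervals and one unmappable
gap — then design probes for all genes with patching enabled:

```sh
chcdesign fixtures --out-dir fixtures --seed 1
chcdesign design \
    --genome fixtures/genome.fa \
    --alignability fixtures/alignability.bedgraph \
    --annotation fixtures/annotation.txt \
    --all-genes --allow-patching \
    --out-dir design --prefix demo
```

which prints:

```
targets: 5 genes -> 6 viewpoints (6 valid, 5 genes)
unique digests: 9 (9 balanced, 0 unbalanced)
probes: 18, capture size: 2160 bp
```

Six viewpoints are created for five genes because GENE5 has two distinct
TSS, each of which gets its own viewpoint. Three viewpoints start below
the 0.6 score threshold (their TSS sits on or within a few bp of a cut
site) and are patched with the adjacent digest, which is why 9 unique
digests are selected rather than 6. With one probe per margin that gives
18 probes of 120 bp; none overlap, so the capture size — the union of
probe intervals, the main driver of reagent cost — is 2160 bp.

`design/` then contains the seven export files plus
`demo_project.json`, a versioned project record (parameters, input
checksums, every viewpoint with its edit snapshot) that can be reloaded
with `chcdesign export` or `chcdesign.load_project`.

The same pipeline is available as a library:

```python
from chcdesign import DesignConfig, DesignParameters, run_design

run = run_design(DesignConfig(
    genome="fixtures/genome.fa",
    alignability="fixtures/alignability.bedgraph",
    annotation="fixtures/annotation.txt",
    all_genes=True,
    params=DesignParameters(approach="extended", enzymes=("DpnII",)),
))
print(run.project.summary)
run.export("design", "extended")
```

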