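"""Deduplication, design summary and the seven export files."""

import zipfile

import pytest

from chcdesign.digestion import Digest
from chcdesign.export import (
    _probe_gray,
    _score_gray,
    deduplicate,
    interval_union_size,
    read_digested_genome,
    summarize,
    ucsc_url,
    write_outputs,
)
from chcdesign.genome import GenomeHandle
from chcdesign.params import DesignParameters
from chcdesign.probes import BALANCED, Probe
from chcdesign.targets import Target
from chcdesign.viewpoints import CandidateDigest, Viewpoint


def mk_probe(start, side="5p"):
    return Probe("chr1", start, start + 120, side, "A" * 120, 0.5, 0.0, 1.0)


def mk_vp(label, tss, digest, probes, selected=True):
    cand = CandidateDigest(
        digest, BALANCED, probes_5p=probes, probes_3p=[], selected=selected
    )
    return Viewpoint(
        target=Target(label, "chr1", tss, "+"),
        approach="simple",
        candidates=[cand],
        tss_digest_key=digest.key,
        score=0.9,
    )


class TestDeduplication:
    def test_shared_digest_counted_once(self):
        d = Digest("chr1", 1000, 2000, 3)
        p = mk_probe(1000)
        vps = [mk_vp("A", 1100, d, [p]), mk_vp("B", 1900, d, [p])]
        digests, probes = deduplicate(vps)
        assert len(digests) == 1 and len(probes) == 1

    def test_disjoint_viewpoints_sum(self):
        vps = [
            mk_vp("A", 1100, Digest("chr1", 1000, 2000, 3), [mk_probe(1000)]),
            mk_vp("B", 5100, Digest("chr1", 5000, 6000, 9), [mk_probe(5000)]),
        ]
        digests, probes = deduplicate(vps)
        assert len(digests) == 2 and len(probes) == 2

    def test_identical_probes_from_both_margins_collapse(self):
        d = Digest("chr1", 1000, 1240, 3)
        shared_5p = mk_probe(1060, side="5p")
        shared_3p = mk_probe(1060, side="3p")
        cand = CandidateDigest(d, BALANCED, [shared_5p], [shared_3p], selected=True)
        vp = Viewpoint(Target("A", "chr1", 1100, "+"), "simple", [cand], d.key)
        _, probes = deduplicate([vp])
        assert len(probes) == 1


class TestSummary:
    def test_capture_size_of_disjoint_probes(self):
        vp = mk_vp("A", 1100, Digest("chr1", 1000, 2000, 3),
                   [mk_probe(1000), mk_probe(1500)])
        s = summarize([vp], DesignParameters())
        assert s.capture_size == 240 and s.n_probes == 2

    def test_capture_size_of_heavily_overlapping_probes(self):
        vp = mk_vp("A", 1100, Digest("chr1", 1000, 2000, 3),
                   [mk_probe(1000), mk_probe(1001)])
        assert summarize([vp], DesignParameters()).capture_size == 121

    def test_no_valid_viewpoints_gives_zero_summary(self):
        vp = mk_vp("A", 1100, Digest("chr1", 1000, 2000, 3), [], selected=False)
        s = summarize([vp], DesignParameters())
        assert s.n_unique_digests == s.n_probes == s.capture_size == 0
        assert s.n_genes_with_valid_viewpoint == 0
        assert s.n_target_genes == 1

    def test_balanced_plus_unbalanced_equals_unique(self, demo_run):
        s = demo_run.project.summary
        assert s.n_balanced + s.n_unbalanced == s.n_unique_digests
        assert s.capture_size <= s.n_probes * demo_run.project.params.probe_length

    def test_interval_union(self):
        assert interval_union_size([(0, 10), (5, 15), (20, 25)]) == 20
        assert interval_union_size([]) == 0


class TestUcscUrl:
    def test_span_padded_by_one_viewpoint_length(self):
        url = ucsc_url("chrX", (1000, 2000), 1500, "hg19")
        assert "chrX%3A" in url and "db=hg19" in url
        assert "position=chrX%3A1-3000" in url  # 1-based, clipped at start

    def test_empty_viewpoint_centres_on_target(self):
        url = ucsc_url("chr2", None, 5000)
        assert "position=chr2%3A4001-6000" in url and "db=custom" in url


class TestGrayscaleRamps:
    def test_score_endpoints(self):
        assert _score_gray(1.0) == "0,0,0"       # perfect score is black
        assert _score_gray(0.0) == "200,200,200"

    def test_probe_endpoints(self):
        assert _probe_gray(1.0, 2.0) == "0,0,0"  # unique probes are black
        assert _probe_gray(2.0, 2.0) == "200,200,200"


@pytest.fixture(scope="module")
def exported(demo_run, tmp_path_factory):
    out = tmp_path_factory.mktemp("export")
    paths = write_outputs(
        str(out), "demo", demo_run.project.viewpoints, demo_run.digest_map,
        demo_run.genome, demo_run.project.params,
    )
    return paths


class TestOutputFiles:
    def test_all_seven_files_exist(self, exported):
        assert len(exported) == 7
        import os
        for path in exported.values():
            assert os.path.exists(path)

    def test_digest_file_roundtrip(self, exported, demo_run):
        reparsed = read_digested_genome(exported["digested_genome"])
        in_memory = [d for ds in demo_run.digest_map.values() for d in ds]
        assert len(reparsed) == len(in_memory)
        for a, b in zip(reparsed, in_memory):
            assert (a.chrom, a.start, a.end, a.index_on_chrom) == (
                b.chrom, b.start, b.end, b.index_on_chrom)
            assert (a.selected, a.probes_5p, a.probes_3p) == (
                b.selected, b.probes_5p, b.probes_3p)

    def test_unique_digests_bed_matches_design(self, exported):
        lines = open(exported["unique_digests"]).read().splitlines()
        assert lines == [
            "chr1\t5160\t5590\tdigest_chr1_13",
            "chr1\t12900\t13330\tdigest_chr1_31",
            "chr1\t21500\t21930\tdigest_chr1_51",
            "chr1\t30100\t30530\tdigest_chr1_71",
            "chr1\t41710\t42140\tdigest_chr1_98",
            "chr1\t43430\t43860\tdigest_chr1_102",
        ]

    def test_probe_bed_is_valid_bed(self, exported, demo_run):
        for line in open(exported["probes_bed"]):
            chrom, s, e, name = line.split("\t")
            assert chrom in demo_run.genome.chrom_lengths
            assert 0 <= int(s) < int(e) <= demo_run.genome.chrom_lengths[chrom]
            assert name.startswith("probe_")

    def test_agilent_sequences_match_genome(self, exported, demo_run):
        with zipfile.ZipFile(exported["agilent"]) as zf:
            text = zf.read(zf.namelist()[0]).decode()
        header, *rows = text.splitlines()
        cols = header.split("\t")
        bed = {l.split("\t")[3]: l.split("\t") for l in
               open(exported["probes_bed"]).read().splitlines()}
        assert len(rows) == len(bed)
        for row in rows:
            rec = dict(zip(cols, row.split("\t")))
            chrom, start, stop = rec["Chromosome"], int(rec["Start"]), int(rec["Stop"])
            fetched = demo_run.genome.fetch(chrom, start - 1, stop)
            assert rec["Sequence"] == fetched.upper()
            assert bed[rec["ProbeID"]][0] == chrom
            assert int(bed[rec["ProbeID"]][1]) == start - 1

    def test_alltracks_has_five_sections_in_order(self, exported):
        track_lines = [l for l in open(exported["all_tracks"]) if l.startswith("track")]
        assert len(track_lines) == 5
        for line, word in zip(
            track_lines,
            ["genomic positions", "viewpoints", "restriction fragments",
             "target regions", "probes"],
        ):
            assert word in line

    def test_alltracks_probe_colors_follow_alignability(self, exported):
        # demo probes sit on uniquely mappable sequence -> MKA 1 -> black
        section = None
        for line in open(exported["all_tracks"]):
            if line.startswith("track"):
                section = line
                continue
            if section and "probes" in section:
                assert line.rstrip().endswith("0,0,0")

    def test_viewpoint_tsv_coordinates_are_one_based_inclusive(self, exported, demo_run):
        rows = open(exported["viewpoints"]).read().splitlines()[1:]
        by_label = {}
        for r in rows:
            f = r.split("\t")
            by_label.setdefault(f[0], []).append(f)
        vp = demo_run.project.viewpoints[0]
        row = by_label[vp.target.label][0]
        chrom, pos1 = row[1].split(":")
        assert (chrom, int(pos1) - 1) == (vp.target.chrom, vp.target.position)
        span_lo, span_hi = row[2].split(":")[1].split("-")
        assert (int(span_lo) - 1, int(span_hi)) == vp.span
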