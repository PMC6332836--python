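import pytest
from hypothesis import HealthCheck, settings
from pyfaidx import Faidx

from chcdesign.fixtures import (
    demo_spec,
    make_alignability,
    make_annotation,
    make_bed6,
    make_genome,
)
from chcdesign.params import DesignParameters
from chcdesign.project import DesignConfig, run_design

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def write_fasta(path, records: dict[str, str]) -> str:
    """Write a small FASTA with a .fai index; returns the path."""
    path = str(path)
    with open(path, "wt") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    Faidx(path, rebuild=True)
    return path


def write_bedgraph(path, lines: list[tuple[str, int, int, float]]) -> str:
    path = str(path)
    with open(path, "wt") as fh:
        for chrom, s, e, score in lines:
            fh.write(f"{chrom}\t{s}\t{e}\t{score:g}\n")
    return path


@pytest.fixture(scope="session")
def demo_files(tmp_path_factory):
    """The standard synthetic data set, generated once per session."""
    d = tmp_path_factory.mktemp("demo")
    spec = demo_spec(seed=1)
    return {
        "spec": spec,
        "genome": make_genome(spec, d / "genome.fa"),
        "alignability": make_alignability(spec, d / "alignability.bedgraph"),
        "annotation": make_annotation(spec, d / "annotation.txt"),
        "bed6": make_bed6(spec, d / "targets.bed"),
    }


@pytest.fixture(scope="session")
def demo_run(demo_files):
    """A finished simple-approach design on the demo data set."""
    cfg = DesignConfig(
        genome=demo_files["genome"],
        alignability=demo_files["alignability"],
        annotation=demo_files["annotation"],
        all_genes=True,
        params=DesignParameters(approach="simple"),
    )
    return run_design(cfg)
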