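import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tilecov.fixtures import GenomeSpec, Segment, make_synthetic_bam

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bam(tmp_path_factory):
    """A 3-Mb two-reference sample with a hemizygous 300-kb segment on chr1;
    shared across tests that need a real BAM + BAI on disk."""
    d = tmp_path_factory.mktemp("small")
    spec = GenomeSpec(
        references=[("chr1", 2_000_000), ("chrX", 1_000_000)],
        segments={"chr1": [Segment(500_000, 800_000, 0.5)]},
        depth=10.0,
        read_length=150,
        seed=3,
    )
    path = str(d / "s1.bam")
    n_records = make_synthetic_bam(spec, path, sample_name="s1")
    return {"path": path, "spec": spec, "n_records": n_records}


@pytest.fixture(scope="session")
def empty_bam(tmp_path_factory):
    """A valid, indexed BAM containing zero alignments."""
    d = tmp_path_factory.mktemp("empty")
    spec = GenomeSpec(references=[("chr1", 200_000)], depth=0.0, seed=1)
    path = str(d / "empty.bam")
    make_synthetic_bam(spec, path, sample_name="empty")
    return path


#: Whole-chromosome dosage multipliers (X, Y) per synthetic karyotype.
COHORT_KARYOTYPES = {
    "femaleA": (1.0, 0.0),
    "femaleB": (1.0, 0.0),
    "maleA": (0.5, 0.5),
    "maleB": (0.5, 0.5),
    "xyy": (0.5, 1.0),
}


@pytest.fixture(scope="session")
def sex_cohort(tmp_path_factory):
    """Five karyotyped samples plus one male whose BAI is byte-truncated.

    chr1 4 Mb at 10x anchors the autosomal baseline; chrX/chrY dosage per
    karyotype.  Returns paths keyed by sample id, in a deterministic order.
    """
    from tilecov.fixtures import make_truncated_index

    d = tmp_path_factory.mktemp("cohort")
    refs = [("chr1", 4_000_000), ("chrX", 2_000_000), ("chrY", 1_000_000)]
    paths = {}
    for i, (name, (mx, my)) in enumerate(COHORT_KARYOTYPES.items()):
        spec = GenomeSpec(
            references=refs,
            segments={
                "chrX": [Segment(0, 2_000_000, mx)],
                "chrY": [Segment(0, 1_000_000, my)],
            },
            depth=10.0,
            read_length=150,
            seed=100 + i,
        )
        p = str(d / f"{name}.bam")
        make_synthetic_bam(spec, p, sample_name=name)
        paths[name] = p
    # a male sample whose index was cut off mid-copy
    spec = GenomeSpec(
        references=refs,
        segments={
            "chrX": [Segment(0, 2_000_000, 0.5)],
            "chrY": [Segment(0, 1_000_000, 0.5)],
        },
        depth=10.0,
        read_length=150,
        seed=200,
    )
    p = str(d / "truncated.bam")
    make_synthetic_bam(spec, p, sample_name="truncated")
    make_truncated_index(p + ".bai", p + ".bai", 0.5)
    paths["truncated"] = p
    return {"refs": refs, "paths": paths}


@pytest.fixture(scope="session")
def cohort_run(sex_cohort, tmp_path_factory):
    """Full pipeline output over the six-sample sex cohort."""
    import pandas as pd

    from tilecov.cli import RunConfig, run

    outdir = tmp_path_factory.mktemp("cohort_out")
    config = RunConfig(
        inputs=list(sex_cohort["paths"].values()),
        directory=str(outdir),
        prefix="cohort",
    )
    assert run(config) == 0
    ped = pd.read_csv(outdir / "cohort-tilecov.ped", sep="\t").set_index("sample_id")
    return {"dir": outdir, "ped": ped, "refs": sex_cohort["refs"]}


def uniform_profile(n_tiles_per_ref, value=1.0, sample_id="u"):
    """Hand-built CoverageProfile for tests that need no BAM."""
    from tilecov.coverage import CoverageProfile

    by_ref = {
        name: np.full(nt, value, dtype=np.float64) for name, nt in n_tiles_per_ref.items()
    }
    return CoverageProfile(sample_id=sample_id, by_ref=by_ref, baseline=1.0 if value else 0.0)
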