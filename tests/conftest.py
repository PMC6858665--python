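import numpy as np
import pytest

from telncrna.intervals import GenomicInterval
from telncrna.pipeline import PipelineConfig, run_pipeline
from telncrna.simulate import GroundTruth, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One full default synthetic dataset, shared across tests."""
    outdir = tmp_path_factory.mktemp("dataset")
    cfg = SimulationConfig(seed=11)
    tr, ann, te, counts, sheet, truth, fasta = simulate_dataset(cfg, outdir)
    return {
        "cfg": cfg,
        "dir": outdir,
        "transcripts": tr,
        "ann": ann,
        "te": te,
        "counts": counts,
        "samples": sheet.frame,
        "truth": truth,
        "fasta": fasta,
    }


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """The full pipeline executed once on the default dataset."""
    results = tmp_path_factory.mktemp("results")
    cfg = PipelineConfig(
        dataset_dir=str(default_dataset["dir"]), results_dir=str(results), seed=11
    )
    bundle = run_pipeline(cfg)
    bundle["results_dir"] = results
    bundle["truth"] = default_dataset["truth"]
    return bundle


def random_intervals(rng, n, chrom="chr1", lo=0, hi=1000, max_len=120):
    out = []
    for _ in range(n):
        s = int(rng.integers(lo, hi - 1))
        e = int(rng.integers(s + 1, min(s + max_len, hi) + 1))
        out.append(GenomicInterval(chrom, s, e))
    return out


def per_base_union(intervals):
    covered = set()
    for iv in intervals:
        covered.update(range(iv.start, iv.end))
    return covered
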