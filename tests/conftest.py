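import numpy as np
import pytest

from tadhub.genome_io import GenomicInterval, TadRecord
from tadhub.synthetic_data import SimulationConfig, simulate_dataset

RES = 10_000


def make_tads(spans, cell_line="test", caller="ontad"):
    """Build TadRecords from (chrom, start, end) triples."""
    return [
        TadRecord(GenomicInterval(c, s, e), cell_line=cell_line, caller=caller)
        for c, s, e in spans
    ]


def random_nested_tads(rng, max_tads=12, chrom="chr1", nbins=400):
    """Random grid-aligned TAD set: arbitrary intervals >= 3 bins, allowing
    shared endpoints and nesting.  Independent of the generator under test."""
    n = int(rng.integers(1, max_tads + 1))
    spans = []
    endpoints = list(rng.integers(0, nbins - 3, size=max(2, n)))
    for _ in range(n):
        if endpoints and rng.random() < 0.5:
            s = min(int(endpoints[int(rng.integers(0, len(endpoints)))]), nbins - 3)
        else:
            s = int(rng.integers(0, nbins - 3))
        length = int(rng.integers(3, min(60, nbins - s) + 1))
        spans.append((chrom, s * RES, (s + length) * RES))
        endpoints.append(s)
        endpoints.append(s + length)
    return make_tads(spans)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11, chrom_sizes={"chrS1": 15_000_000}, n_top_tads=40
    )
    return simulate_dataset(cfg)
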