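"""Shared fixtures: a paper-scale simulated instance and small helpers."""

import pytest

from synbreak.annotations import GeneAnnotation
from synbreak.simulate import FishSimulator, paper_scale_config


@pytest.fixture(scope="session")
def paper_sim() -> FishSimulator:
    """One noise-free paper-scale instance, shared read-only across tests."""
    return FishSimulator(paper_scale_config(seed=1))


def make_genes(spans, chrom="X", prefix="g"):
    """Build GeneAnnotations from (start, end) pairs, ids g1, g2, ..."""
    return [
        GeneAnnotation(chrom=chrom, start=s, end=e, gene_id=f"{prefix}{i + 1}")
        for i, (s, e) in enumerate(spans)
    ]
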