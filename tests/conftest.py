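import numpy as np
import pandas as pd
import pytest

import lineagedep as ld
from lineagedep.simulate import (
    DependencySimParams,
    RegulatorySimParams,
    generate_dependency_bundle,
    generate_regulatory_bundle,
)


@pytest.fixture(scope="session")
def clean_bundle():
    """Dependency bundle with no resistant lines: pure LD recovery setting."""
    params = DependencySimParams(resistant_fraction=0.0, n_acquired_per_lineage=0)
    return generate_dependency_bundle(
        n_lineages=5, lines_per_lineage=12, n_genes=120, n_tfs=60,
        params=params, seed=11,
    )


@pytest.fixture(scope="session")
def resistant_bundle():
    """Dependency bundle with a 30% resistant subset per lineage."""
    params = DependencySimParams(resistant_fraction=0.3)
    return generate_dependency_bundle(
        n_lineages=4, lines_per_lineage=20, n_genes=100, n_tfs=50,
        params=params, seed=7,
    )


@pytest.fixture(scope="session")
def regulatory_bundle():
    return generate_regulatory_bundle(
        n_peaks=300, n_reads=4000, n_genes=600, n_samples=60, n_clusters=4,
        seed=13,
    )


@pytest.fixture
def small_peaks():
    """Two peaks whose 501-bp consensus windows collide, plus one far away."""
    def mk(name, chrom, summit, q):
        return ld.Peak(
            interval=ld.GenomicInterval(chrom, summit - 300, summit + 300),
            summit=summit, neg_log10_q=q, name=name,
        )
    return [mk("a", "chr1", 1000, 30.0), mk("b", "chr1", 1200, 10.0),
            mk("c", "chr1", 5000, 5.0)]
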