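"""Shared fixtures: toy genomes, hand-built gene models, and session-scoped
synthetic study bundles (everything generated programmatically)."""

import numpy as np
import pytest

from phosphobind.core import GeneModel, Genome, Tag
from phosphobind.coverage import TagLibrary
from phosphobind.pipeline import run_bundle
from phosphobind.simulate import SimulationConfig, generate


@pytest.fixture
def toy_genome():
    return Genome.from_sizes({"chr1": 1000, "chr2": 800})


@pytest.fixture
def toy_gene_genome():
    return Genome.from_sizes({"chr1": 100_000})


@pytest.fixture
def toy_gene():
    """The worked '+' example: tx [30000,40000), exons [30000,31000) and
    [35000,40000)."""
    return GeneModel(
        "geneX", "chr1", "+", 30_000, 40_000, (30_000, 35_000), (31_000, 40_000)
    )


def random_tags(rng, genome, n):
    chroms = list(genome.chrom_names)
    tags = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        pos = int(rng.integers(0, genome.size(chrom)))
        strand = "+" if rng.random() < 0.5 else "-"
        tags.append(Tag(chrom, pos, strand))
    return tags


@pytest.fixture
def toy_library(toy_genome):
    rng = np.random.default_rng(42)
    return TagLibrary("toy", "total", "A", random_tags(rng, toy_genome, 50))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced study used where full defaults are not needed."""
    cfg = SimulationConfig(
        seed=11,
        chrom_sizes={"chr1": 200_000},
        n_genes=12,
        n_sites=24,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition study bundle."""
    return generate(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def default_results(default_bundle):
    """Full pipeline results on the default bundle."""
    return run_bundle(default_bundle)
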