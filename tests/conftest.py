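import numpy as np
import pytest

from circdimorph import synthio
from circdimorph.core_io import (
    BackSpliceJunction,
    CircCall,
    GeneModel,
    GenomeRef,
    Transcript,
)


@pytest.fixture(scope="session")
def tiny_config():
    return synthio.SimConfig(
        error_rate=0.0,
        class_counts={"null": 18, "female_specific": 3, "female_biased": 3},
        n_cirna=4,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    genome, models = synthio.generate_genome(12, 7, tiny_config)
    return genome, models


@pytest.fixture(scope="session")
def tiny_truth(tiny_world, tiny_config):
    genome, models = tiny_world
    design = synthio.default_design()
    return synthio.plant_truth(genome, models, design, 8, tiny_config)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_gene():
    """Hand-built plus-strand 3-exon gene on a 1 kb contig.

    Exons [100,200), [300,400), [500,650); CDS [150,560).
    """
    rng = np.random.default_rng(99)
    seq = _random_seq(rng, 1000)
    genome = GenomeRef({"chrT": seq})
    tx = Transcript("tg.t1", ((100, 200), (300, 400), (500, 650)), (150, 560))
    gene = GeneModel("tg", "chrT", "+", "coding", [tx])
    return genome, gene


@pytest.fixture()
def toy_gene_minus():
    rng = np.random.default_rng(99)
    seq = _random_seq(rng, 1000)
    genome = GenomeRef({"chrT": seq})
    tx = Transcript("tm.t1", ((100, 200), (300, 400), (500, 650)), (150, 560))
    gene = GeneModel("tm", "chrT", "-", "coding", [tx])
    return genome, gene


def make_exonic_call(gene: GeneModel, i: int, j: int, counts=None) -> CircCall:
    exons = gene.canonical.exons
    return CircCall(
        junction=BackSpliceJunction(gene.contig, gene.strand,
                                    exons[i][0], exons[j][1]),
        circ_type="exonic",
        gene_id=gene.gene_id,
        exon_chain=tuple(exons[i : j + 1]),
        counts=counts or {},
    )
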