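import numpy as np
import pytest

from enuscreen.genome import GeneModel, GenomeModel, generate_genome_model
from enuscreen.channels import encode


@pytest.fixture(scope="session")
def small_genome():
    """A quick 120-gene genome shared by unit tests."""
    return generate_genome_model(
        n_genes=120, n_pathways=10, mean_cds_length=600, seed=42
    )


@pytest.fixture(scope="session")
def fullscale_genome():
    """The default-scale screen genome (19000 genes, 100 pathways).

    Session-scoped: the site index and per-gene change tables are cached on
    the instance and reused by the acceptance tests.
    """
    gm = generate_genome_model(
        n_genes=19000, n_pathways=100, mean_cds_length=900, seed=20210
    )
    gm.site_index  # build once
    return gm


def make_single_gene_genome(cds: str, gene_id: str = "G0", pad: int = 20) -> GenomeModel:
    """A one-gene genome with the CDS embedded in a small chromosome."""
    rng = np.random.default_rng(0)
    spacer = "".join(np.random.default_rng(1).choice(list("ACGT"), size=pad))
    chrom_seq = spacer + cds + spacer
    gene = GeneModel(
        gene_id=gene_id,
        chrom="chr1",
        cds_start=pad + 1,
        strand="+",
        coding_sequence=cds,
    )
    return GenomeModel(
        genes=[gene],
        pathway_collection={},
        chrom_codes={"chr1": encode(chrom_seq)},
    )


@pytest.fixture
def single_gene_genome_factory():
    return make_single_gene_genome
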