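import numpy as np
import pytest
from hypothesis import settings

from ptcpop import synthetic as syn
from ptcpop.annotation import GeneModel, Isoform

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    return syn.SyntheticConfig(n_genes=12, n_strains=100, seed=11)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return syn.generate_reference(small_config)


def make_single_exon_gene(cds, gene_id="g1", chrom="chr", strand="+", offset=10):
    """Embed a CDS in a chromosome as a one-exon plus/minus-strand gene.

    Returns (reference dict, GeneModel). ``offset`` is 0-based; flanks are
    fixed A-runs so coordinates are easy to reason about.
    """
    from ptcpop.seq import revcomp

    genomic = cds if strand == "+" else revcomp(cds)
    seq = "A" * offset + genomic + "A" * 10
    lo, hi = offset + 1, offset + len(cds)
    gene = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        isoforms=(Isoform(f"{gene_id}.t1", ((lo, hi),)),),
    )
    return {chrom: seq}, gene


@pytest.fixture
def rng():
    return np.random.default_rng(0)
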