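import pytest

from polykaryo import simulate as sim
from polykaryo.model import GeneModel, GenomeAnnotation


@pytest.fixture(scope="session")
def small_ancestor():
    """22-block ancestor with 10 genes per block (fast shared fixture)."""
    kary, genome = sim.build_ancestral_karyotype(22, 10)
    return kary, genome


@pytest.fixture(scope="session")
def small_diploid(small_ancestor):
    _, anc = small_ancestor
    scenario = sim.standard_scenario(seed=11)
    return sim.apply_scenario(anc, scenario, "diploid"), scenario


def make_annotation(genome_id, chrom_starts, gene_len=2000):
    """Annotation from {chromosome: [(gene_id, start), ...]}."""
    genes = [
        GeneModel(gid, chrom, start, start + gene_len)
        for chrom, entries in chrom_starts.items()
        for gid, start in entries
    ]
    return GenomeAnnotation(genome_id, genes)


def grid_annotation(genome_id, n, prefix="g", chrom="chr1", spacing=10_000, gene_len=2000):
    """One chromosome with n genes on a uniform grid."""
    return make_annotation(
        genome_id,
        {chrom: [(f"{prefix}{i:03d}", i * spacing) for i in range(n)]},
        gene_len,
    )
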