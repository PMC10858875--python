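import pytest

from phageome import synthetic_data as sim


@pytest.fixture(scope="session")
def community():
    """A small phage community with planted population structure."""
    genomes, gene_table, truth = sim.generate_community(
        n_votus=6, members_per_votu=3, genome_len=10_000, seed=11
    )
    return genomes, gene_table, truth


@pytest.fixture(scope="session")
def community_with_hosts(community):
    genomes, gene_table, truth = community
    hosts = sim.generate_hosts(
        genomes,
        truth,
        phage_gene_table=gene_table,
        n_hosts=4,
        spacers_per_host=2,
        shared_genes_per_pair=1,
        seed=12,
    )
    return genomes, gene_table, truth, hosts
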