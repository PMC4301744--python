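import pytest

from paleorder.formats_io import GeneRecord, GenomeTable, parse_species_tree

FIVE_LEAF_NEWICK = "((s1,s2)anc1,(s3,(s4,s5)anc3)anc2)root;"


@pytest.fixture
def stree5():
    """Five extant species, four named ancestors."""
    return parse_species_tree(FIVE_LEAF_NEWICK)


@pytest.fixture
def stree3():
    return parse_species_tree("((s1,s2)anc1,s3)root;")


def make_genome(species, chromosomes):
    """Build a GenomeTable from {chrom: [(gene_id, strand), ...]}."""
    records = []
    for chrom, genes in chromosomes.items():
        for i, (gene_id, strand) in enumerate(genes):
            start = (i + 1) * 1000
            records.append(GeneRecord(species, chrom, start, start + 500,
                                      strand, gene_id))
    return GenomeTable(species, records)
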