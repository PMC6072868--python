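import pytest

from cloneseq import build_gene_model, toy_locus


@pytest.fixture(scope="session")
def toy():
    """Plus-strand toy locus: 3 x 100 nt exons at 1001-1100, 1201-1300,
    1401-1500 with 100 nt introns, plus its synthetic genome."""
    return toy_locus()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_genome(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_minus():
    """Minus-strand 4-exon toy locus."""
    return toy_locus(n_exons=4, strand="-")


@pytest.fixture(scope="session")
def long_tx_model():
    """A synthetic transcript long enough to express CDS positions in the
    thousands (three exons totalling 12,000 nt, CDS over the full length).
    Used to exercise deletion naming at realistic coordinate magnitudes."""
    return build_gene_model(
        gene_symbol="SYN1", chrom="chrS", strand="+",
        transcript_accession="SYN1.1",
        exon_genomic=[(10_001, 14_000), (20_001, 24_000), (30_001, 34_000)],
        exon_labels=["1", "2", "3"],
    )
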