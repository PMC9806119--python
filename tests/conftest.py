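import pytest

from splicefidelity.annotation import GenomeSequence, load_annotation
from splicefidelity.simulate import paper_shape_config, write_fixture_bundle

BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Preset fixture bundle: 50 genes, two conditions, two replicates each."""
    outdir = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(paper_shape_config(BUNDLE_SEED, n_genes=50), outdir)


@pytest.fixture(scope="session")
def bundle_index(bundle):
    return load_annotation(bundle.gtf, bundle.expression)


@pytest.fixture(scope="session")
def bundle_genome(bundle):
    return GenomeSequence.from_fasta(bundle.genome)


TOY_GTF = """\
chrT\ttest\tgene\t1\t300\t.\t+\t.\tgene_id "GA";
chrT\ttest\ttranscript\t1\t300\t.\t+\t.\tgene_id "GA"; transcript_id "TA1";
chrT\ttest\texon\t1\t50\t.\t+\t.\tgene_id "GA"; transcript_id "TA1";
chrT\ttest\texon\t101\t150\t.\t+\t.\tgene_id "GA"; transcript_id "TA1";
chrT\ttest\texon\t201\t300\t.\t+\t.\tgene_id "GA"; transcript_id "TA1";
chrT\ttest\ttranscript\t1\t300\t.\t+\t.\tgene_id "GA"; transcript_id "TA2";
chrT\ttest\texon\t1\t50\t.\t+\t.\tgene_id "GA"; transcript_id "TA2";
chrT\ttest\texon\t201\t300\t.\t+\t.\tgene_id "GA"; transcript_id "TA2";
chrT\ttest\tgene\t401\t700\t.\t-\t.\tgene_id "GB";
chrT\ttest\ttranscript\t401\t700\t.\t-\t.\tgene_id "GB"; transcript_id "TB1";
chrT\ttest\texon\t401\t450\t.\t-\t.\tgene_id "GB"; transcript_id "TB1";
chrT\ttest\texon\t601\t700\t.\t-\t.\tgene_id "GB"; transcript_id "TB1";
"""

TOY_EXPR = "gene_id\ttpm\nGA\t50.0\n"


@pytest.fixture(scope="session")
def toy_index(tmp_path_factory):
    """Two genes: GA (+, 3 exons, a skip transcript TA2) and GB (-, 2 exons).

    GB is absent from the expression table, so its tpm defaults to 0.
    """
    d = tmp_path_factory.mktemp("toy")
    gtf = d / "toy.gtf"
    gtf.write_text(TOY_GTF)
    expr = d / "expr.tsv"
    expr.write_text(TOY_EXPR)
    return load_annotation(gtf, expr)
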