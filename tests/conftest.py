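import numpy as np
import pytest

from mixsquare import GeneLocus, TranscriptModel
from mixsquare.fixtures import seven_test_genes


@pytest.fixture(scope="session")
def gene_panel():
    return seven_test_genes()


@pytest.fixture
def two_isoform_locus():
    """A 2000 bp and a 1000 bp transcript sharing their last junction:
    the long one adds an upstream exon."""
    long_t = TranscriptModel(
        id="tx_long", gene_id="G1", chrom="chr1", strand="+",
        exons=((5000, 5999), (6500, 7499)),
    )
    short_t = TranscriptModel(
        id="tx_short", gene_id="G1", chrom="chr1", strand="+",
        exons=((5500, 5999), (6500, 6999)),
    )
    return GeneLocus(gene_id="G1", transcripts=[long_t, short_t])


@pytest.fixture
def minus_strand_transcript():
    return TranscriptModel(
        id="tx_minus", gene_id="G2", chrom="chr2", strand="-",
        exons=((100, 299), (500, 799), (1200, 1399)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
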