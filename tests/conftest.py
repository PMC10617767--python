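import numpy as np
import pytest
from hypothesis import strategies as st

from ampliconlens.genome_model import GenomicInterval, Transcript, load_fixture
from ampliconlens.synthetic_data import make_gene_models


@pytest.fixture(scope="session")
def fgfr1():
    return load_fixture("FGFR1")


@pytest.fixture(scope="session")
def nsd3():
    return load_fixture("NSD3")


@pytest.fixture(scope="session")
def synthetic_fixtures():
    return make_gene_models(42)


def build_transcript(
    gene="G",
    chrom="chrT",
    strand="+",
    exon_lengths=(60, 90, 45),
    intron_lengths=(50, 70),
    offset=1000,
    utr5=9,
    utr3=12,
    seq_rng=None,
):
    """Construct a toy transcript with a CDS spanning all exons minus the
    given UTR lengths; CDS length is trimmed to a codon multiple."""
    total = sum(exon_lengths)
    cds_len = total - utr5 - utr3
    cds_len -= cds_len % 3
    assert cds_len >= 6
    ivals = []
    cur = offset
    for i, L in enumerate(exon_lengths):
        ivals.append(GenomicInterval(chrom, cur, cur + L, strand))
        cur += L + (intron_lengths[i] if i < len(intron_lengths) else 0)
    if strand == "-":
        ivals = ivals[::-1]
    rng = seq_rng or np.random.default_rng(0)
    cds_seq = "ATG" + "".join(
        rng.choice(list("ACGT")) for _ in range(cds_len - 6)
    ) + "TAA"
    tr = Transcript(gene, chrom, strand, ivals, cds_sequence=cds_seq)
    # place cds_start utr5 bases into the transcript
    tr.cds_start = tr.tx_to_genomic(utr5)
    tr.cds_end = tr.tx_to_genomic(utr5 + cds_len - 1)
    return Transcript(
        gene, chrom, strand, ivals, tr.cds_start, tr.cds_end, cds_seq
    )


@st.composite
def transcript_models(draw):
    """Random small transcript models for property tests."""
    strand = draw(st.sampled_from(["+", "-"]))
    n_exons = draw(st.integers(min_value=1, max_value=5))
    exon_lengths = [draw(st.integers(min_value=12, max_value=80)) for _ in range(n_exons)]
    intron_lengths = [draw(st.integers(min_value=5, max_value=60)) for _ in range(n_exons - 1)]
    total = sum(exon_lengths)
    utr5 = draw(st.integers(min_value=0, max_value=max(0, total // 4)))
    max_utr3 = max(0, total - utr5 - 6)
    utr3 = draw(st.integers(min_value=0, max_value=max_utr3 // 2))
    if total - utr5 - utr3 < 6:
        utr3 = 0
    offset = draw(st.integers(min_value=0, max_value=10_000))
    return build_transcript(
        strand=strand,
        exon_lengths=tuple(exon_lengths),
        intron_lengths=tuple(intron_lengths),
        offset=offset,
        utr5=utr5,
        utr3=utr3,
    )
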