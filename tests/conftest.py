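import numpy as np
import pytest

from mik.genome_io import GeneModel, GenomicInterval, Transcript


def make_transcript(exons, tx_id="tx1", gene_id="g1", cds=None):
    return Transcript(tx_id, gene_id, tuple(GenomicInterval(*e) for e in exons), cds)


@pytest.fixture
def plus_two_exon_tx():
    # transcript positions [0,100) -> [1000,1100), [100,200) -> [2000,2100)
    return make_transcript(
        [("chr1", 1000, 1100, "+"), ("chr1", 2000, 2100, "+")]
    )


@pytest.fixture
def minus_single_exon_tx():
    return make_transcript([("chr1", 500, 600, "-")])


@pytest.fixture
def coding_gene():
    """Coding gene on '+': exon [1000,1300), CDS [1050,1250);
    UTR5 [1000,1050), UTR3 [1250,1300)."""
    tx = make_transcript([("chr1", 1000, 1300, "+")], "gA.t1", "gA", cds=(1050, 1250))
    gene = GeneModel("gA", "GENEA", "coding")
    gene.transcripts[tx.transcript_id] = tx
    return gene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_exon_structure(rng, n_exons=None, strand=None, seqid="chrT"):
    """Random sorted non-overlapping exon chain (1-5 exons, either strand)."""
    n = int(n_exons if n_exons is not None else rng.integers(1, 6))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    exons = []
    pos = int(rng.integers(0, 1000))
    for _ in range(n):
        length = int(rng.integers(30, 400))
        exons.append(GenomicInterval(seqid, pos, pos + length, strand))
        pos += length + int(rng.integers(50, 500))
    return tuple(exons)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """One shared default synthetic dataset for the end-to-end checks."""
    from mik.synthetic_data import simulate_all

    out = tmp_path_factory.mktemp("sim")
    manifest = simulate_all(17, out)
    return out, manifest
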