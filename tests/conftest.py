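import numpy as np
import pytest

from annoquant.annotation import Gene, GeneModel, Genome, GenomicInterval, Transcript

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def make_transcript(tx_id, symbol, strand, exon_coords, chrom="chrT"):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords)
    return Transcript(tx_id, symbol, strand, exons)


def make_model(name, *transcripts):
    model = GeneModel(name)
    by_symbol = {}
    for tx in transcripts:
        by_symbol.setdefault(tx.gene_symbol, []).append(tx)
    for symbol, txs in by_symbol.items():
        model.add_gene(Gene(symbol, tuple(txs)))
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_genome(rng):
    """One 5 kb random chromosome."""
    return Genome({"chrT": random_sequence(rng, 5000)})


@pytest.fixture
def three_exon_tx():
    return make_transcript(
        "TX1", "GA", "+", [(101, 200), (301, 420), (601, 700)]
    )


@pytest.fixture
def minus_tx():
    return make_transcript("TX2", "GB", "-", [(1001, 1100), (1301, 1400)])


@pytest.fixture
def toy_model(three_exon_tx, minus_tx):
    return make_model("toy", three_exon_tx, minus_tx)
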