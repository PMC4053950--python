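import numpy as np
import pytest

from censite.model import MiRNA, TranscriptModel

BASES = "ACGU"


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def make_transcript(seq: str, tid: str = "t1", gene: str = "g1",
                    utr5_end=None, cds_end=None) -> TranscriptModel:
    n = len(seq)
    if utr5_end is None:
        utr5_end = n // 4
    if cds_end is None:
        cds_end = 3 * n // 4
    return TranscriptModel(id=tid, gene_id=gene, sequence=seq,
                           utr5_end=utr5_end, cds_end=cds_end)


@pytest.fixture
def rng():
    return np.random.default_rng(20140314)


@pytest.fixture
def mirna(rng):
    return MiRNA("mir-sim", random_rna(rng, 22))
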