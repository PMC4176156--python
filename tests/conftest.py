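import pytest

from ribodrift import Transcript, TranscriptSet


@pytest.fixture
def toy_tx() -> Transcript:
    """1400 nt single-exon transcript: 150 nt 5'UTR, 1200 nt CDS, 50 nt 3'UTR."""
    return Transcript("tx1", length=1400, cds_start=150, cds_end=1350)


@pytest.fixture
def uorf_tx() -> Transcript:
    """Transcript with a 30 nt uORF at [100,130) in a 250 nt 5'UTR."""
    return Transcript(
        "txu", length=1600, cds_start=250, cds_end=1450, uorfs=((100, 130),)
    )


@pytest.fixture
def toy_set(toy_tx, uorf_tx) -> TranscriptSet:
    return TranscriptSet([toy_tx, uorf_tx])
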