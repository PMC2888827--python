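import pytest

from tdnakit.model import TDNALocus


def make_locus(
    seq_id="chr1",
    start=0,
    end=None,
    strand="+",
    iso_type="Ala",
    length=72,
    **kwargs,
):
    """Compact locus factory for tests."""
    if end is None:
        end = start + length
    return TDNALocus(
        seq_id=seq_id, start=start, end=end, strand=strand, iso_type=iso_type, **kwargs
    )


@pytest.fixture
def locus_factory():
    return make_locus
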