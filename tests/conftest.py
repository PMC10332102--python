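import pytest

from familyscope.synthetic_data import generate_transcriptome


@pytest.fixture(scope="session")
def small_transcriptome():
    """A small but class-complete synthetic transcriptome (fixed seed)."""
    return generate_transcriptome(
        101,
        n_erf=8,
        n_dreb=5,
        n_ap2=3,
        n_rav=2,
        n_negative=4,
        n_incomplete=3,
    )
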