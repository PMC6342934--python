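import pytest

from pamscreen import (
    LibrarySimConfig,
    NucleasePamModel,
    default_amplicon_reference,
)


@pytest.fixture(scope="session")
def ttt_model() -> NucleasePamModel:
    """Nuclease active exactly when PAM positions -4..-2 are TTT."""
    return NucleasePamModel.from_iupac("NNNNTTTN", depletion_strength=0.95)


@pytest.fixture(scope="session")
def small_screen_cfg() -> LibrarySimConfig:
    """Reduced-depth screen design for fast unit tests."""
    return LibrarySimConfig(n_plasmids=50_000, reads_per_sample=20_000, seed=7)


@pytest.fixture(scope="session")
def amplicon_ref():
    return default_amplicon_reference()
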