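import pytest

from glycaninfer import (
    GlycanComposition,
    Peak,
    Spectrum,
    default_registry,
    ssv19_fixture_topology,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def heptasaccharide():
    """The Sulfolobus sp. E11-6 host N-glycan composition."""
    return GlycanComposition.parse("QuiS1Hex4HexNAc2")


@pytest.fixture
def host_glycan_spectrum():
    """The published MS2 peak list of the bis-PMP-labeled host N-glycan:
    precursor 1629.55 with fragments 1403.53, 981.34, 755.32 ([M+H]+)."""
    return Spectrum(
        precursor_mz=1629.55,
        peaks=[
            Peak(1629.55, 100.0),
            Peak(1403.53, 40.0),
            Peak(981.34, 60.0),
            Peak(755.32, 80.0),
        ],
    )


@pytest.fixture
def ssv19_tree():
    return ssv19_fixture_topology()
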