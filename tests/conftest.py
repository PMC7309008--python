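import pytest

import oxishift as ox


@pytest.fixture(scope="session")
def extinction_table():
    return ox.reference_extinction_table()


@pytest.fixture(scope="session")
def registry():
    return ox.load_registry()


@pytest.fixture
def flat_detector():
    return ox.synthetic_detector("flat")


@pytest.fixture
def generic_pair(flat_detector):
    red, ir = ox.generic_pair_sources()
    return ox.SourceDetectorPair(red, ir, flat_detector, label="generic")


@pytest.fixture
def fine_grid():
    return ox.default_grid(step=0.2)


@pytest.fixture
def monochromatic_coefficients(extinction_table):
    """Table values at exactly 660 and 940 nm, no spectral weighting."""
    o1, h1 = ox.interpolate_extinction(extinction_table, 660.0)
    o2, h2 = ox.interpolate_extinction(extinction_table, 940.0)
    return ox.EffectiveCoefficients(
        red=ox.ChannelExtinction(o1, h1),
        ir=ox.ChannelExtinction(o2, h2),
        red_reference=ox.ChannelExtinction(o1, h1),
        ir_reference=ox.ChannelExtinction(o2, h2),
        label="monochromatic-660/940",
    )


@pytest.fixture
def toy_coefficients():
    """Hand-checkable coefficient set: eps_Hb/eps_HbO2 swap across channels."""
    return ox.EffectiveCoefficients(
        red=ox.ChannelExtinction(eps_hbo2=1.0, eps_hb=2.0),
        ir=ox.ChannelExtinction(eps_hbo2=2.0, eps_hb=1.0),
        label="toy",
    )
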