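import numpy as np
import pytest

from flashear import (
    EntryVein,
    SyntheticScenario,
    VesselSegment,
)


@pytest.fixture(scope="session")
def scenario() -> SyntheticScenario:
    return SyntheticScenario()


@pytest.fixture()
def calibrated_segments() -> list[VesselSegment]:
    """Classed vessel lengths giving a static volume of ~0.20 µl."""
    return [
        VesselSegment("t1", "thick", 16.0),
        VesselSegment("m1", "middle", 26.0),
        VesselSegment("n1", "thin", 38.0),
    ]


@pytest.fixture()
def entry_veins() -> list[EntryVein]:
    """Four thick entry veins, the calibrated flow fixture."""
    return [EntryVein(f"v{i}", 0.09) for i in range(4)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
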