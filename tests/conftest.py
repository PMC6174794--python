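import numpy as np
import pytest

import ctdosim as cd


@pytest.fixture(scope="session")
def xs():
    return cd.build_default_library()


@pytest.fixture(scope="session")
def thorax300():
    """Default 300 mm synthetic thorax: (phantom, masks, contour)."""
    return cd.make_thorax_phantom(cd.ThoraxSpec(effective_diameter_mm=300))


@pytest.fixture(scope="session")
def thorax_protocol():
    """Low-pitch helical protocol covering the default thorax."""
    return cd.ScanProtocol(mode="helical", pitch=0.059, collimation=(16, 1.5),
                           scan_range=(0.0, 200.0))


@pytest.fixture(scope="session")
def thorax_source(thorax_protocol):
    return cd.SourceModel.for_protocol(thorax_protocol)


@pytest.fixture(scope="session")
def thorax_dose(thorax300, thorax_protocol, thorax_source):
    """One shared 60k-history 4DCT run on the default thorax."""
    phantom, _, _ = thorax300
    fields = cd.helical_fields(thorax_protocol)
    return cd.run_scan(phantom, fields, thorax_source, 60_000, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
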