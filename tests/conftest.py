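import numpy as np
import pytest

from mitoscan.phenotyping import analyze_well
from mitoscan.simulate import WellSimConfig, render_well


@pytest.fixture(scope="session")
def default_well():
    """One default well (seed 7) rendered once for the whole session."""
    config = WellSimConfig(seed=7)
    image, gt = render_well(config)
    return config, image, gt


@pytest.fixture(scope="session")
def analyzed_well(default_well):
    _, image, _ = default_well
    wp, records, bridges, masks, features = analyze_well(image)
    return {"phenotypes": wp, "records": records, "bridges": bridges,
            "nuclei": masks[0], "cytoplasm": masks[1], "features": features}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
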