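import numpy as np
import pytest

import ybrca1 as yb


@pytest.fixture(scope="session")
def paper_like_panel() -> yb.AssayPanel:
    """Benchmark-structured 56-variant panel (46 classified + 10 VUS)."""
    return yb.generate_paper_like_panel(seed=7)


@pytest.fixture(scope="session")
def paper_like_calibrations(paper_like_panel):
    return yb.calibrate_panel(paper_like_panel)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def make_measurement(replicates, controls=(1.0, 1.0, 1.0, 1.0, 1.0),
                     variant_id="p.X1Y", assay=yb.Assay.INTRA_HR) -> yb.AssayMeasurement:
    return yb.AssayMeasurement(
        variant_id=variant_id, assay=assay,
        replicates=tuple(replicates), control_replicates=tuple(controls),
    )
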