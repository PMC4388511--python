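import numpy as np
import pytest

from qendosomes import DetectionParams, SimulationSpec


@pytest.fixture
def default_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def small_spec() -> SimulationSpec:
    """A compact field for fast simulation tests."""
    return SimulationSpec(
        n_endosomes=100, field_shape=(512, 512), n_cells=4, seed=42
    )


def render_spot(
    shape=(41, 41), center=None, sigma=2.07, amplitude=1652.0, background=100.0
) -> np.ndarray:
    """Analytic Gaussian spot on a flat background (no noise)."""
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return background + amplitude * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2.0 * sigma**2)
    )


@pytest.fixture
def spot_image() -> np.ndarray:
    return render_spot()
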