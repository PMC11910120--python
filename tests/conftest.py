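import numpy as np
import pytest

from idafront.detect import CalibrationModel, DetectionConfig, VialROI
from idafront.synth import RenderConfig, VialGeometry


@pytest.fixture
def geometry() -> VialGeometry:
    return VialGeometry()


@pytest.fixture
def roi(geometry: VialGeometry) -> VialROI:
    return VialROI(
        0, geometry.width_px, geometry.gel_top_row, geometry.gel_bottom_row, geometry.gel_top_row
    )


@pytest.fixture
def clean_render() -> RenderConfig:
    """Noise- and gradient-free rendering for exact pixel assertions."""
    return RenderConfig(noise_sd=0.0, illum_gradient=0.0)


@pytest.fixture
def calibration() -> CalibrationModel:
    return CalibrationModel()


@pytest.fixture
def detection() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def protocol_times() -> np.ndarray:
    """Acquisition protocol: pre-gassing frame, then every 5 min for 1 h."""
    return np.arange(0, 3601, 300, dtype=float)
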