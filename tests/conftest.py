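import numpy as np
import pytest

from hippoquant import (Calibration, DetectionParams, SceneSpec,
                        generate_scene, run_detector)

# isotropic calibrations for constructed-mask tests
ISO_1UM = Calibration(um_per_px_x=1.0, um_per_px_y=1.0, z_step_um=5.0)
ISO_HALF = Calibration(um_per_px_x=0.5, um_per_px_y=0.5, z_step_um=5.0)


def disk_mask(shape: tuple[int, int], row: float, col: float, radius_px: float) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius_px**2


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    """A reduced ROI (300 x 200 um) with few objects, for fast unit tests."""
    return SceneSpec(
        roi_width_um=300.0,
        roi_height_um=200.0,
        n_neurons=10,
        n_astrocytes=3,
        n_microglia=4,
        n_debris=6,
        n_debris_decoys=4,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_scene(small_spec)


@pytest.fixture(scope="session")
def small_result(small_scene):
    stack, _ = small_scene
    return run_detector(stack, "NeuN", DetectionParams(), gfap_channel="GFAP")
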