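import numpy as np
import pytest

from keratoptics.eye_model import (EQUIVALENT_LENS_INDEX, EyePrescription,
                                   Material, SurfaceSpec, attach_glasses,
                                   build_baseline_eye)


@pytest.fixture(scope="session")
def baseline_eye():
    return build_baseline_eye(lens_index=EQUIVALENT_LENS_INDEX)


@pytest.fixture(scope="session")
def eye_with_glasses(baseline_eye):
    return attach_glasses(baseline_eye)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_stigmatic_system(R=10.0, n=1.5, image_shift=0.0):
    """Single hyperbolic refracting surface (k = -1/n^2) focusing a
    collimated beam perfectly at the back focal distance n*R/(n-1); a
    stigmatic toy for aberration-free and pure-defocus wavefront tests."""
    bfd = n * R / (n - 1.0)
    k = -1.0 / (n * n)
    surf = SurfaceSpec("aspheric", Ry=R, Rx=R, ky=k, kx=k,
                       semi_aperture=3.0, is_stop=True, name="lens")
    img = SurfaceSpec("plane", semi_aperture=5.0, name="image")
    return EyePrescription(
        surfaces=[surf, img], media=[Material("glass", n)],
        thicknesses=[bfd + image_shift], stop_index=0, pupil_diameter=4.0,
        label="stigmatic_toy")
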