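import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hsinuclei import BandSpec, BinaryMask, SpectralCube, SubImage

settings.register_profile(
    "derandomized", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("derandomized")


def make_cube(arr, wavelengths=None, **kw) -> SpectralCube:
    arr = np.asarray(arr, dtype=float)
    if wavelengths is None:
        wavelengths = np.linspace(400.0, 400.0 + 10.0 * (arr.shape[2] - 1),
                                  arr.shape[2])
    return SpectralCube(arr, wavelengths, **kw)


def make_subimage(values, mask=None, nucleus_id="N0", class_label="REF",
                  label="test") -> SubImage:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=np.uint8)
    bm = BinaryMask(np.asarray(mask), nucleus_id=nucleus_id,
                    class_label=class_label)
    spec = BandSpec.pointwise(500.0)
    spec = BandSpec("pointwise", 500.0, 500.0, label)
    return SubImage(values=values, mask=bm, band_spec=spec,
                    nucleus_id=nucleus_id, class_label=class_label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
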