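import numpy as np
import pytest

from thermocrop import FIXTURE_PLANCK, PlanckConstants, SceneSpec, generate_scene

#: Three distinct, physically plausible calibration sets for roundtrip tests.
PLANCK_SETS = (
    FIXTURE_PLANCK,
    PlanckConstants(R1=14906.21, R2=0.010956882, B=1396.5, O=-5621.0, F=1.0),
    PlanckConstants(R1=17096.45, R2=0.046642166, B=1428.0, O=-342.0, F=1.0),
)


@pytest.fixture(params=PLANCK_SETS, ids=["camA", "camB", "camC"])
def planck(request):
    return request.param


@pytest.fixture(scope="session")
def clean_scene():
    """A deterministic noise-free scene: exact mask recovery applies."""
    return generate_scene(
        SceneSpec(seed=7, color_noise_sd=0.0, thermal_noise_sd=0.0, T_canopy_sd=0.0)
    )


@pytest.fixture(scope="session")
def default_scene():
    """A deterministic scene at the generator's default noise levels."""
    return generate_scene(SceneSpec(seed=11))


def brute_force_closing(mask: np.ndarray, k: int = 4) -> np.ndarray:
    """Pixel-loop morphological closing oracle: dilation then erosion by a
    k x k all-ones element anchored at ((k-1)//2, (k-1)//2), with values
    outside the frame treated as background for both passes."""
    a = (k - 1) // 2
    h, w = mask.shape
    m = mask.astype(bool)

    def at(arr, y, x):
        return arr[y, x] if 0 <= y < h and 0 <= x < w else False

    dil = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            dil[y, x] = any(
                at(m, y - (i - a), x - (j - a)) for i in range(k) for j in range(k)
            )
    ero = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            ero[y, x] = all(
                at(dil, y + (i - a), x + (j - a)) for i in range(k) for j in range(k)
            )
    return ero.astype(np.uint8)
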