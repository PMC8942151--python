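import warnings

import numpy as np
import pytest

from lungmech.phantom import demo_spec, generate_phantom


@pytest.fixture(scope="session")
def iso_phantom():
    """Standard isotropic breath phantom (64³, 4 phases) with ground truth."""
    spec = demo_spec("isotropic", n_steps=4)
    series, gt = generate_phantom(spec)
    return spec, series, gt


@pytest.fixture(scope="session")
def iso_phantom_clean():
    """Isotropic phantom rendered without anti-aliasing (labels == air mask)."""
    spec = demo_spec("isotropic", n_steps=4, supersample=1)
    series, gt = generate_phantom(spec)
    return spec, series, gt


@pytest.fixture(scope="session")
def recruit_phantom():
    spec = demo_spec("recruitment", n_steps=8)
    series, gt = generate_phantom(spec)
    return spec, series, gt


@pytest.fixture(scope="session")
def iso_segmentation(iso_phantom):
    """Phase-0 classification of the isotropic phantom."""
    from lungmech.segmentation import classify_structures, otsu_partition

    _, series, _ = iso_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return classify_structures(otsu_partition(series[0]))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return 2.0 * np.sum(a & b) / max(int(a.sum() + b.sum()), 1)


@pytest.fixture(scope="session")
def dice_fn():
    return dice
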