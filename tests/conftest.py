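import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import nanodomain as nd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_window():
    return nd.AnalysisWindow(3000.0, 3000.0)


def pooled_mean_anisotropy(curve):
    """Pixel-count-weighted mean of the binned anisotropy."""
    return float(np.average(curve.bin_mean_anisotropy, weights=curve.bin_pixel_count))


def analyze_field(field, seed, g=1.0, n_bins=20, roi_fraction=0.1, noise=True):
    """Field -> image pair -> anisotropy maps -> binned curve."""
    pair, _ = nd.simulate_polarized_image_pair(field, seed=seed, noise=noise)
    maps = nd.compute_anisotropy_maps(pair, g)
    roi = nd.roi_from_intensity(maps, roi_fraction)
    return nd.bin_intensity_anisotropy(maps, [roi], n_bins=n_bins)
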