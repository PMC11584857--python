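import numpy as np
import pytest

from qsfilter.ecg import ECGModelParams, generate_ecg
from qsfilter.smoothing import SmoothingConfig, build_filter_matrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240508)


@pytest.fixture(scope="session")
def clean_ecg_600():
    """One clean 600-sample synthetic ECG record (360 Hz) shared by the bench tests."""
    return generate_ecg(ECGModelParams(hr_bpm=60.0, fs=360.0, duration_s=600 / 360.0, seed=12345))


@pytest.fixture
def penta_filter():
    """Factory for exact/toeplitz filter matrices."""

    def make(N, eta, mode="exact", order=2):
        return build_filter_matrix(SmoothingConfig(eta=eta, order=order, mode=mode), N)

    return make


def dense_difference(N, order=2):
    """Independent dense oracle for the difference operator."""
    from math import comb

    ker = [(-1) ** j * comb(order, j) for j in range(order + 1)]
    D = np.zeros((N - order, N))
    for i in range(N - order):
        D[i, i : i + order + 1] = ker
    return D
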