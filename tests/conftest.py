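import numpy as np
import pytest

from maldiderep import (
    DereplicationParams,
    PeakList,
    RawSpectrum,
    SpectrumDataset,
)


@pytest.fixture
def params():
    return DereplicationParams()


@pytest.fixture
def grid():
    """1 Da grid over a narrow band, fine enough for local correlation windows."""
    return np.linspace(4000.0, 8000.0, 4001)


def gaussian_on(grid, center, amplitude, sigma):
    return amplitude * np.exp(-((grid - center) ** 2) / (2 * sigma**2))


@pytest.fixture
def make_spectrum(grid):
    """Factory: build (RawSpectrum, PeakList) from (center, amplitude) pairs."""

    def _make(sid, peaks, sigma=3.0, noise_sd=0.0, seed=0, snr=100.0):
        rng = np.random.default_rng(seed)
        signal = np.zeros_like(grid)
        for center, amplitude in peaks:
            signal += gaussian_on(grid, center, amplitude, sigma)
        if noise_sd:
            signal += np.abs(rng.normal(0, noise_sd, grid.size))
        centers = np.sort(np.array([c for c, _ in peaks], dtype=float))
        return (
            RawSpectrum(sid, grid, signal),
            PeakList(sid, centers, np.full(centers.size, snr)),
        )

    return _make


@pytest.fixture
def make_dataset():
    def _make(records, **kwargs):
        return SpectrumDataset(records={sid: rec for sid, rec in records.items()}, **kwargs)

    return _make
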