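import numpy as np
import pytest
from scipy import signal

from volumetrix import (AcquisitionConfig, ExperimentConfig, TomoImage,
                        run_phantom_experiment)

FWHM_DEFAULT = 10.59


@pytest.fixture(scope="session")
def blurred_sphere():
    """Gaussian-blurred unit sphere (d = 40 mm, FWHM 10.59 mm, 1 mm voxels).

    Computed by direct FFT convolution with an explicit normalized Gaussian
    kernel — an oracle independent of the emulator's separable-filter path.
    """
    voxel = 1.0
    radius = 20.0
    sigma = FWHM_DEFAULT / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel
    n = 101
    ax = (np.arange(n) - n // 2) * voxel
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    sphere = (np.sqrt(xx**2 + yy**2 + zz**2) <= radius).astype(float)
    ka = np.arange(-25, 26) * voxel
    kx, ky, kz = np.meshgrid(ka, ka, ka, indexing="ij")
    kern = np.exp(-(kx**2 + ky**2 + kz**2) / (2.0 * sigma**2))
    kern /= kern.sum()
    blurred = signal.fftconvolve(sphere, kern, mode="same")
    return {"image": blurred, "sphere": sphere, "radius": radius,
            "voxel": voxel, "sigma": sigma, "n": n}


@pytest.fixture(scope="session")
def phantom_run_noisy():
    """Default noisy phantom experiment (seed 1); shared across test modules."""
    return run_phantom_experiment(ExperimentConfig(seed=1))


@pytest.fixture(scope="session")
def phantom_run_noiseless():
    """Default noiseless phantom experiment; deterministic."""
    return run_phantom_experiment(ExperimentConfig(seed=1, noisy=False))


@pytest.fixture()
def binary_lobes_image():
    """Tiny binary two-blob tomographic image (lobes = 1, background = 0)."""
    grid = np.zeros((24, 12, 12))
    grid[3:9, 4:9, 4:9] = 1.0
    grid[15:21, 4:9, 4:9] = 1.0
    return TomoImage(grid, voxel_size=1.0, provenance=AcquisitionConfig())
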