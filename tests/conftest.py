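import warnings

import numpy as np
import pytest

from polspim import (
    OpticsConfig,
    ReconConfig,
    add_noise,
    forward_project,
    guv_phantom,
    make_scheme,
    reconstruct_field,
    wire_fixture,
)

# the default 130 nm voxel pitch cannot hold the full 2NA/lambda support of
# the 1.1 NA view; the model warns once per transfer-function build, which is
# expected throughout the suite
warnings.filterwarnings(
    "ignore", message="voxel spacing too coarse for the detection cutoff")


@pytest.fixture(scope="session")
def cfg():
    return OpticsConfig()


@pytest.fixture(scope="session")
def guv():
    """Small GUV phantom: (field, truth_axes, shell_mask)."""
    return guv_phantom(shape=(48, 48, 48), spacing_nm=130.0, radius_nm=2200.0,
                       shell_width_nm=390.0, kappa=5.0)


@pytest.fixture(scope="session")
def guv_roundtrip(cfg, guv):
    """Noiseless forward + reconstruction of the GUV with six_with_tilt."""
    field, truth, shell = guv
    scheme = make_scheme("six_with_tilt")
    stack = forward_project(field, scheme, cfg, pad=16)
    rec = reconstruct_field(stack, ReconConfig(eta=1e-4))
    return field, truth, shell, scheme, stack, rec


@pytest.fixture(scope="session")
def guv_roundtrip_no_tilt(cfg, guv):
    field, truth, shell = guv
    scheme = make_scheme("six_no_tilt")
    stack = forward_project(field, scheme, cfg, pad=16)
    rec = reconstruct_field(stack, ReconConfig(eta=1e-4))
    return field, truth, shell, scheme, stack, rec


@pytest.fixture(scope="session")
def guv_noisy_pipeline(cfg):
    """Full noisy pipeline at paper-scale conditions (64^3, ~6 um GUV,
    six_with_tilt, Poisson noise at 10k median total shell counts)."""
    field, truth, shell = guv_phantom(shape=(64, 64, 64), spacing_nm=130.0,
                                      radius_nm=3000.0, shell_width_nm=390.0,
                                      kappa=5.0)
    scheme = make_scheme("six_with_tilt")
    stack = forward_project(field, scheme, cfg, pad=16)
    med = np.median(stack.total_counts()[shell])
    noisy = add_noise(stack, "poisson", photons_per_unit=10000.0 / med, seed=123)
    rec = reconstruct_field(noisy)
    return truth, shell, noisy, rec


@pytest.fixture(scope="session")
def wire_roundtrip(cfg):
    """Zero-disorder single-wire fixture pushed through simulate->reconstruct."""
    wires, field, truth, mask = wire_fixture(
        "single", shape=(24, 40, 24), spacing_nm=260.0,
        fiber_halo_nm=1200.0, disordered_fraction=0.0)
    scheme = make_scheme("six_with_tilt")
    stack = forward_project(field, scheme, cfg, pad=12)
    rec = reconstruct_field(stack, ReconConfig(eta=1e-3, pad=12))
    return wires, field, truth, mask, rec


def channel_corr(a, b):
    """Pearson correlation with a 0 guard for constant inputs."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
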