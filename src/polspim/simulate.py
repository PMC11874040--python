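"""Forward model: irradiance volumes from an ODF field under a scheme.

Implements the shift-invariant spatio-angular imaging equation in the
Fourier domain: for each measurement the irradiance spectrum is
G(nu) = sum_lm H_lm(nu) F_lm(nu), evaluated with FFTs on the voxel grid.
Boundary conditions are circular; zero padding (default 16 voxels) keeps
wraparound below the PSF tails for compact objects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .optics import OpticsConfig, TransferFunction, transfer_function
from .phantom import ODFField
from .scheme import MeasurementScheme
from .sphharm import N_COEFFS


@dataclass
class IrradianceStack:
    """Registered irradiance volumes, one per measurement."""

    data: np.ndarray  # (n_meas, nz, ny, nx)
    scheme: MeasurementScheme
    cfg: OpticsConfig
    spacing_nm: float
    noise: dict | None = None  # {"model", "photons_per_unit", "seed"}

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("data must be (n_meas, nz, ny, nx)")
        if self.data.shape[0] != len(self.scheme):
            raise ValueError("volume count must match scheme length")

    @property
    def n_meas(self) -> int:
        return self.data.shape[0]

    def total_counts(self) -> np.ndarray:
        """Per-voxel signal summed across polarizations and views."""
        return self.data.sum(axis=0)


def _pad(vol: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return vol
    return np.pad(vol, [(pad, pad)] * 3 + [(0, 0)][: max(0, vol.ndim - 3)])


def forward_project(
    field: ODFField,
    scheme: MeasurementScheme,
    cfg: OpticsConfig | None = None,
    mode: str = "factored",
    pad: int = 16,
    tf: TransferFunction | None = None,
) -> IrradianceStack:
    """Noiseless irradiance stack predicted for ``field`` under ``scheme``.

    Linear in the field and spatially shift-invariant (circular boundaries
    at pad=0).  A precomputed ``tf`` on the padded shape may be passed to
    amortize transfer-function construction.
    """
    cfg = cfg or OpticsConfig()
    coeffs = field.coeffs
    if pad:
        coeffs = np.pad(coeffs, [(pad, pad)] * 3 + [(0, 0)])
    pshape = coeffs.shape[:3]
    if tf is None:
        tf = transfer_function(scheme, cfg, pshape, field.spacing_nm, mode=mode)
    if tf.shape != pshape or len(tf.specs) != len(scheme):
        raise ValueError("transfer function does not match scheme/grid")
    out = np.empty((len(scheme),) + pshape)
    if tf.mode == "factored":
        # angular projection per measurement, then scalar blur
        for i in range(len(scheme)):
            s = coeffs @ tf.A[i]
            g = np.fft.ifftn(np.fft.fftn(s) * tf.B[i])
            out[i] = g.real
    else:
        F = np.fft.fftn(coeffs, axes=(0, 1, 2))
        for i in range(len(scheme)):
            H = tf.measurement_h(i)
            G = np.einsum("kzyx,zyxk->zyx", H, F)
            g = np.fft.ifftn(G)
            if np.abs(g.imag).max() > 1e-6 * max(np.abs(g.real).max(), 1e-30):
                raise FloatingPointError("forward model produced non-real output")
            out[i] = g.real
    if pad:
        out = out[:, pad:-pad, pad:-pad, pad:-pad]
    return IrradianceStack(data=out, scheme=scheme, cfg=cfg,
                           spacing_nm=field.spacing_nm, noise=None)


def add_noise(
    stack: IrradianceStack,
    model: str = "poisson",
    photons_per_unit: float = 1000.0,
    seed: int = 0,
    gaussian_sigma: float = 1.0,
) -> IrradianceStack:
    """Apply a seeded noise model; output is in detected counts.

    poisson: counts ~ Poisson(photons_per_unit * signal) — requires a
    nonnegative input; mean preserved in expectation.
    gaussian: counts = photons_per_unit * signal + N(0, gaussian_sigma).
    """
    rng = np.random.default_rng(seed)
    expected = stack.data * photons_per_unit
    if model == "poisson":
        if np.any(stack.data < 0):
            raise ValueError("poisson noise requires nonnegative irradiance")
        noisy = rng.poisson(expected).astype(float)
    elif model == "gaussian":
        noisy = expected + rng.normal(scale=gaussian_sigma, size=expected.shape)
    else:
        raise ValueError("model must be 'poisson' or 'gaussian'")
    meta = {"model": model, "photons_per_unit": float(photons_per_unit),
            "seed": int(seed)}
    if model == "gaussian":
        meta["gaussian_sigma"] = float(gaussian_sigma)
    return dc_replace(stack, data=noisy, noise=meta)
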