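"""Tikhonov-regularized per-spatial-frequency ODF reconstruction.

The forward model is diagonal over spatial frequency: at each nu the
n_meas measured Fourier coefficients are H(nu) F(nu) with H the
n_meas x 15 spatio-angular transfer matrix.  The estimator solves, per
frequency, the ridge problem

    F_hat(nu) = argmin_F ||H F - G||^2 + eta ||F||^2
              = (H^H H + eta I)^-1 H^H G  =  H^H (H H^H + eta I)^-1 G,

the second (n_meas x n_meas) form being what is actually solved.  An
inverse FFT of the 15 coefficient channels yields the ODF field.  Outside
every view's transverse support H = 0 and the estimate is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .optics import OpticsConfig, TransferFunction, transfer_function
from .phantom import ODFField
from .simulate import IrradianceStack
from .sphharm import N_COEFFS

#: default Tikhonov weight, chosen by an L-curve-style sweep on the noisy
#: GUV phantom (see docs/methods.md)
DEFAULT_ETA = 3e-3


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction settings."""

    eta: float = DEFAULT_ETA
    mode: str = "factored"  # transfer-function fidelity mode
    pad: int = 16
    clamp_negative_density: bool = False
    scale_factors: tuple[float, ...] | None = None  # per-measurement gains
    apply_gain: bool = True  # divide counts by photons_per_unit so eta is
    # defined in photon-normalized signal units

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


def build_inverse_operators(
    H: np.ndarray, eta: float, rcond: float = 1e-10
) -> np.ndarray:
    """Per-frequency ridge inverse W(nu) = (H^H H + eta I)^-1 H^H.

    ``H`` has shape (..., n_meas, 15); returns (..., 15, n_meas).  With
    eta = 0 a pseudo-inverse with singular-value cutoff is used and a
    warning is emitted when H is rank-deficient on its support.
    """
    H = np.asarray(H)
    n_meas = H.shape[-2]
    Hh = np.conj(np.swapaxes(H, -1, -2))
    if eta > 0:
        K = H @ Hh + eta * np.eye(n_meas)
        return Hh @ np.linalg.inv(K)
    sv = np.linalg.svd(H, compute_uv=False)
    support = sv[..., 0] > 0
    if np.any(sv[..., -1][support] <= rcond * sv[..., 0][support]):
        warnings.warn("eta=0 with rank-deficient H: pseudo-inverse with "
                      f"cutoff rcond={rcond}", stacklevel=2)
    return np.linalg.pinv(H, rcond=rcond)


def reconstruct_field(
    stack: IrradianceStack,
    rcfg: ReconConfig | None = None,
    tf: TransferFunction | None = None,
) -> ODFField:
    """Estimate the ODF field from an irradiance stack.

    Per frequency: gather the n_meas Fourier coefficients into a vector,
    apply the precomputed 15 x n_meas ridge inverse, inverse-transform the
    15 coefficient channels.  Linear in the data.
    """
    rcfg = rcfg or ReconConfig()
    data = stack.data
    if rcfg.apply_gain and stack.noise and "photons_per_unit" in stack.noise:
        data = data / stack.noise["photons_per_unit"]
    n_meas = stack.n_meas
    if rcfg.scale_factors is not None:
        if len(rcfg.scale_factors) != n_meas:
            raise ValueError("need one scale factor per measurement")
        data = data / np.asarray(rcfg.scale_factors)[:, None, None, None]
    pad = rcfg.pad
    if pad:
        data = np.pad(data, [(0, 0)] + [(pad, pad)] * 3)
    pshape = data.shape[1:]
    if tf is None:
        tf = transfer_function(stack.scheme, stack.cfg, pshape,
                               stack.spacing_nm, mode=rcfg.mode)
    if tf.shape != pshape:
        raise ValueError("transfer function grid does not match the stack")
    G = np.fft.fftn(data, axes=(1, 2, 3))
    if tf.mode == "factored" and rcfg.eta > 0:
        F = _solve_factored(G, tf, rcfg.eta)
    else:
        F = _solve_generic(G, tf, rcfg.eta)
    coeffs = np.moveaxis(np.fft.ifftn(F, axes=(1, 2, 3)), 0, -1)
    imax = np.abs(coeffs.imag).max()
    if imax > 1e-6 * max(np.abs(coeffs.real).max(), 1e-30):
        raise FloatingPointError(
            f"reconstruction has non-negligible imaginary residue ({imax:.2e})")
    coeffs = coeffs.real
    if pad:
        coeffs = coeffs[pad:-pad, pad:-pad, pad:-pad]
    if rcfg.clamp_negative_density:
        coeffs[..., 0] = np.maximum(coeffs[..., 0], 0.0)
    return ODFField(coeffs=coeffs, spacing_nm=stack.spacing_nm)


def _solve_factored(G: np.ndarray, tf: TransferFunction, eta: float) -> np.ndarray:
    """Fast ridge solve exploiting H_i,lm(nu) = B_i(nu) A[i, lm].

    K(nu) = H H^H + eta I has entries B_i B_j (a_i . a_j); the 15-channel
    estimate is F_hat = sum_i B_i a_i u_i with u = K^-1 G.  All-real B and A
    keep K real symmetric.
    """
    n_meas = tf.n_meas
    gram = tf.A @ tf.A.T  # (n, n)
    B = tf.B  # (n, *shape)
    shape = B.shape[1:]
    K = (B[:, None] * B[None, :]) * gram[:, :, None, None, None] \
        + eta * np.eye(n_meas)[:, :, None, None, None]
    K = np.moveaxis(K.reshape(n_meas, n_meas, -1), -1, 0)  # (N, n, n)
    g = np.moveaxis(G.reshape(n_meas, -1), -1, 0)[..., None]  # (N, n, 1)
    u = np.linalg.solve(K, g)[..., 0]  # (N, n)
    Bu = np.moveaxis(B.reshape(n_meas, -1), -1, 0) * u  # (N, n)
    F = Bu @ tf.A  # (N, 15)
    return F.T.reshape((N_COEFFS,) + shape)


def _solve_generic(G: np.ndarray, tf: TransferFunction, eta: float) -> np.ndarray:
    """General per-frequency solve for coupled mode or eta = 0."""
    n_meas = tf.n_meas
    shape = tf.shape
    H = np.stack([tf.measurement_h(i) for i in range(n_meas)])  # (n, 15, *shape)
    H = H.reshape(n_meas, N_COEFFS, -1)
    H = np.moveaxis(H, -1, 0)  # (N, n, 15)
    g = np.moveaxis(G.reshape(n_meas, -1), -1, 0)[..., None]  # (N, n, 1)
    if eta > 0:
        Hh = np.conj(np.swapaxes(H, 1, 2))
        K = H @ Hh + eta * np.eye(n_meas)
        u = np.linalg.solve(K, g)
        F = (Hh @ u)[..., 0]  # (N, 15)
    else:
        W = build_inverse_operators(H, eta=0.0)
        F = (W @ g)[..., 0]
    return F.T.reshape((N_COEFFS,) + shape)
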