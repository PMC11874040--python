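"""Physics kernels of the polarized dual-view light-sheet microscope.

The instrument holds two orthogonal water-immersion objectives, A (NA 1.1)
and B (NA 0.67).  Each measurement illuminates with a polarized light sheet
from one objective and detects with the other.  Contrast over dipole
orientation comes from three mechanisms:

* selective excitation  -- a dipole is excited with efficiency cos^2(theta)
  to the illumination polarization;
* selective detection   -- a dipole's sin^2(phi) emission pattern is
  collected by a finite-NA cone, giving per-dipole efficiency
  C1 + C2 sin^2(phi_d) with phi_d the angle to the detection axis;
* spatio-angular coupling -- the detection PSF shape depends on dipole
  orientation (Airy-like for transverse dipoles, donut for axial ones),
  so different spatial frequencies carry different angular information.

Lab frame convention: z_hat = detection axis of view A, x_hat = detection
axis of view B, y_hat = z_hat x x_hat (the shared horizontal axis along which
light sheets are tilted).  All distances in nm, spatial frequencies in
cycles/nm, angles in radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

from . import sphharm
from .sphharm import N_COEFFS, SphereGrid, sphere_grid

VIEWS = ("A", "B")

#: detection optical axes in the lab frame
DETECTION_AXES = {
    "A": np.array([0.0, 0.0, 1.0]),
    "B": np.array([1.0, 0.0, 0.0]),
}
#: transverse (camera) basis of each view, right-handed with the axis last
VIEW_TRANSVERSE = {
    "A": (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])),
    "B": (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])),
}
#: tilt axis: sheets pivot so the propagation axis swings toward +/- y
SHEET_LATERAL = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class OpticsConfig:
    """Optical parameters of the dual-view system.

    ``sigma_det_*_nm`` default to a diffraction-scale axial estimate
    (FWHM ~ 2 n lambda / NA^2) when left as None.
    """

    na_a: float = 1.1
    na_b: float = 0.67
    n_medium: float = 1.33
    lambda_ex_nm: float = 488.0
    lambda_em_nm: float = 500.0
    sigma_ls_nm: float = 600.0
    sigma_det_a_nm: float | None = None
    sigma_det_b_nm: float | None = None
    max_tilt_rad: float = np.deg2rad(45.0)

    def __post_init__(self):
        for na in (self.na_a, self.na_b):
            if not 0 < na < self.n_medium:
                raise ValueError("require 0 < NA < n (immersion medium)")
        if self.sigma_ls_nm <= 0:
            raise ValueError("sigma_ls_nm must be positive")

    def detection_na(self, view: str) -> float:
        return {"A": self.na_a, "B": self.na_b}[view]

    def sigma_det_nm(self, view: str) -> float:
        stored = {"A": self.sigma_det_a_nm, "B": self.sigma_det_b_nm}[view]
        if stored is not None:
            return stored
        na = self.detection_na(view)
        fwhm = 2.0 * self.n_medium * self.lambda_em_nm / na**2
        return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def sigma_axial_nm(self, det_view: str) -> float:
        """Combined axial Gaussian sigma: light sheet x detection response."""
        sd = self.sigma_det_nm(det_view)
        sl = self.sigma_ls_nm
        return 1.0 / np.sqrt(sd**-2 + sl**-2)

    def transverse_cutoff(self, view: str) -> float:
        """Incoherent transverse support radius 2 NA / lambda (cycles/nm)."""
        return 2.0 * self.detection_na(view) / self.lambda_em_nm


@dataclass(frozen=True)
class MeasurementSpec:
    """One acquisition: illuminate from ``illum_view``, detect with the other.

    ``pol_angle_rad`` (psi) is measured in the plane perpendicular to the
    (possibly tilted) propagation axis, from the detection objective's axis.
    ``tilt_rad`` (tau) swings the sheet propagation axis toward +/- y.
    """

    illum_view: str
    pol_angle_rad: float
    tilt_rad: float = 0.0

    def __post_init__(self):
        if self.illum_view not in VIEWS:
            raise ValueError(f"illum_view must be one of {VIEWS}")

    @property
    def detection_view(self) -> str:
        return "B" if self.illum_view == "A" else "A"

    def propagation(self) -> np.ndarray:
        k = (
            np.cos(self.tilt_rad) * DETECTION_AXES[self.illum_view]
            + np.sin(self.tilt_rad) * SHEET_LATERAL
        )
        return k / np.linalg.norm(k)

    def polarization(self) -> np.ndarray:
        """Unit illumination polarization, perpendicular to propagation."""
        k = self.propagation()
        e1 = DETECTION_AXES[self.detection_view]
        e2 = np.cross(k, e1)
        e2 /= np.linalg.norm(e2)
        p = np.cos(self.pol_angle_rad) * e1 + np.sin(self.pol_angle_rad) * e2
        assert abs(p @ k) < 1e-12
        return p


def excitation_weight(dipole: np.ndarray, pol: np.ndarray) -> np.ndarray:
    """cos^2 of the angle between dipole axis and polarization axis."""
    dipole = np.asarray(dipole, dtype=float)
    pol = np.asarray(pol, dtype=float)
    for v, name in ((dipole, "dipole"), (pol, "pol")):
        if not np.allclose(np.linalg.norm(v, axis=-1), 1.0, atol=1e-9):
            raise ValueError(f"{name} must be unit-norm")
    return (dipole @ pol) ** 2


@lru_cache(maxsize=32)
def detection_constants(na: float, n: float) -> tuple[float, float]:
    """Per-dipole collection constants (C1, C2).

    A dipole emits the normalized pattern (3/8pi) sin^2(psi) (total power 1
    over 4pi).  Integrating over the collection cone of half-angle
    arcsin(NA/n) gives efficiency C1 + C2 sin^2(phi_d), phi_d the angle
    between the dipole axis and the detection axis.  Computed by numerical
    integration of the emission pattern over the cone.
    """
    if not 0 < na <= n:
        raise ValueError("require 0 < NA <= n")
    alpha = np.arcsin(min(na / n, 1.0))

    def eff(phi_d: float) -> float:
        mu = np.array([np.sin(phi_d), 0.0, np.cos(phi_d)])

        def ring(theta):
            # azimuthal integral of sin^2(psi) done analytically:
            # int (1 - (mu . r)^2) dphi = 2pi - pi sin^2(phi_d) sin^2(theta)
            #                              - 2pi cos^2(phi_d) cos^2(theta)
            st, ct = np.sin(theta), np.cos(theta)
            return (
                2 * np.pi
                - np.pi * (mu[0] ** 2) * st**2
                - 2 * np.pi * (mu[2] ** 2) * ct**2
            ) * st

        val, _ = quad(ring, 0.0, alpha, epsabs=1e-12, epsrel=1e-12)
        return 3.0 / (8.0 * np.pi) * val

    c1 = eff(0.0)
    c2 = eff(np.pi / 2.0) - c1
    return float(c1), float(c2)


@dataclass(frozen=True)
class AngularResponse:
    """Angular weight of one measurement and its SH coefficients (l <= 4)."""

    spec: MeasurementSpec
    coeffs: np.ndarray  # (15,) photon-normalized SH coefficients
    c1: float
    c2: float

    def weight(self, dirs: np.ndarray, cfg: OpticsConfig) -> np.ndarray:
        """Un-normalized angular weight w(s) >= 0 at unit directions."""
        dirs = np.asarray(dirs, dtype=float)
        p = self.spec.polarization()
        d = DETECTION_AXES[self.spec.detection_view]
        return (dirs @ p) ** 2 * (self.c1 + self.c2 * (1.0 - (dirs @ d) ** 2))


def _raw_angular_coeffs(spec: MeasurementSpec, cfg: OpticsConfig,
                        grid: SphereGrid) -> tuple[np.ndarray, float, float]:
    c1, c2 = detection_constants(cfg.detection_na(spec.detection_view), cfg.n_medium)
    p = spec.polarization()
    d = DETECTION_AXES[spec.detection_view]
    w = (grid.dirs @ p) ** 2 * (c1 + c2 * (1.0 - (grid.dirs @ d) ** 2))
    return sphharm.sh_project(w, grid), c1, c2


@lru_cache(maxsize=8)
def photon_normalization(cfg: OpticsConfig) -> float:
    """Signal of an isotropic unit-density ODF in the brightest untilted
    measurement; all responses are divided by this so that measurement
    reads 1.0.  Fixes the arbitrary photon gain of the model."""
    grid = sphere_grid()
    best = 0.0
    for view in VIEWS:
        for psi in np.linspace(0.0, np.pi, 91):
            spec = MeasurementSpec(view, float(psi), 0.0)
            coeffs, _, _ = _raw_angular_coeffs(spec, cfg, grid)
            # isotropic unit-density ODF: f = 1/(4 pi); signal = a00/sqrt(4 pi)
            best = max(best, coeffs[0] / np.sqrt(4.0 * np.pi))
    return float(best)


def angular_response(spec: MeasurementSpec, cfg: OpticsConfig,
                     grid: SphereGrid | None = None) -> AngularResponse:
    """Excitation x detection angular weight of one measurement, as SH
    coefficients (exactly band-limited to l <= 4), photon-normalized."""
    if abs(spec.tilt_rad) > cfg.max_tilt_rad:
        raise ValueError("tilt beyond configured maximum")
    grid = grid or sphere_grid()
    coeffs, c1, c2 = _raw_angular_coeffs(spec, cfg, grid)
    coeffs = coeffs / photon_normalization(cfg)
    return AngularResponse(spec=spec, coeffs=coeffs, c1=c1, c2=c2)


def angular_matrix(scheme, cfg: OpticsConfig,
                   grid: SphereGrid | None = None) -> np.ndarray:
    """(n_meas, 15) angular system matrix at zero spatial frequency."""
    specs = getattr(scheme, "specs", scheme)
    return np.array([angular_response(s, cfg, grid).coeffs for s in specs])


# ---------------------------------------------------------------------------
# Vectorial pupil model: dipole PSFs and spatio-angular coupling
# ---------------------------------------------------------------------------

def _pupil_fields(cfg: OpticsConfig, view: str, n_grid: int, dnu: float):
    """Pupil-plane fields of the three Cartesian dipole components.

    Returns ``E`` of shape (3, 2, n, n): dipole component (view frame:
    t1, t2, axial) x field polarization component x pupil grid, with the
    aplanatic 1/sqrt(cos theta) apodization and an anti-aliased aperture
    edge.  Channel energies are rescaled so that the collected power of each
    dipole channel matches :func:`detection_constants` exactly.
    """
    na = cfg.detection_na(view)
    lam = cfg.lambda_em_nm
    n_med = cfg.n_medium
    nu = (np.arange(n_grid) - n_grid // 2) * dnu
    nx, ny = np.meshgrid(nu, nu, indexing="ij")
    rho = np.hypot(nx, ny)
    rho_max = na / lam

    # anti-aliased aperture coverage via 4x4 subpixel sampling
    sub = (np.arange(4) + 0.5) / 4 - 0.5
    cov = np.zeros_like(rho)
    for ax in sub:
        for ay in sub:
            cov += np.hypot(nx + ax * dnu, ny + ay * dnu) <= rho_max
    cov /= 16.0

    s1 = nx * lam / n_med
    s2 = ny * lam / n_med
    s_perp2 = np.clip(s1**2 + s2**2, 0.0, 1.0 - 1e-12)
    sz = np.sqrt(1.0 - s_perp2)
    inside = cov > 0
    phi = np.arctan2(s2, s1)
    ct, st = sz, np.sqrt(s_perp2)
    cphi, sphi = np.cos(phi), np.sin(phi)

    # unit vectors before the lens (view frame): p-pol and s-pol
    p_hat = np.stack([ct * cphi, ct * sphi, -st])
    s_hat = np.stack([-sphi, cphi, np.zeros_like(sphi)])
    s_dir = np.stack([st * cphi, st * sphi, ct])

    apod = np.where(inside, np.sqrt(cov) / np.sqrt(np.maximum(ct, 1e-9)), 0.0)
    E = np.zeros((3, 2, n_grid, n_grid))
    for a in range(3):
        mu = np.zeros(3)
        mu[a] = 1.0
        # far-field radiation: transverse projection of the dipole
        f = mu[:, None, None] - np.einsum("i,ijk->jk", mu, s_dir) * s_dir
        fp = np.einsum("ijk,ijk->jk", f, p_hat)
        fs = np.einsum("ijk,ijk->jk", f, s_hat)
        # rotate (p, s) components onto the pupil-plane Cartesian basis
        E[a, 0] = (fp * cphi - fs * sphi) * apod
        E[a, 1] = (fp * sphi + fs * cphi) * apod

    # energy normalization: discrete pupil energy -> exact cone efficiency
    c1, c2 = detection_constants(na, n_med)
    target = np.array([c1 + c2, c1 + c2, c1])
    scale = 3.0 / (8.0 * np.pi) * (lam / n_med) ** 2 * dnu**2
    for a in range(3):
        g = scale * np.sum(E[a] ** 2)
        E[a] *= np.sqrt(target[a] / g)
    return E


@dataclass(frozen=True)
class DipolePSF:
    """Image-plane intensity of a single dipole emitter."""

    intensity: np.ndarray  # (n, n), sums to the collection efficiency
    pixel_nm: float
    efficiency: float  # total collected power fraction


def dipole_psf(dipole: np.ndarray, cfg: OpticsConfig, view: str,
               n_grid: int = 128) -> DipolePSF:
    """In-focus detection PSF of a dipole oriented along ``dipole`` (lab frame).

    A transverse dipole gives an Airy-like centrally peaked spot; an axial
    dipole (along the detection axis) gives a donut with a central minimum.
    The PSF integral equals the dipole's collection efficiency
    C1 + C2 sin^2(phi_d) (enforced per Cartesian channel; cross-channel
    interference integrates to zero by pupil symmetry).
    """
    dipole = np.asarray(dipole, dtype=float)
    if not np.isclose(np.linalg.norm(dipole), 1.0, atol=1e-9):
        raise ValueError("dipole must be a unit vector")
    dnu = 6.0 * (cfg.detection_na(view) / cfg.lambda_em_nm) / n_grid
    E = _pupil_fields(cfg, view, n_grid, dnu)
    t1, t2 = VIEW_TRANSVERSE[view]
    ax = DETECTION_AXES[view]
    mu_view = np.array([dipole @ t1, dipole @ t2, dipole @ ax])
    scale = 3.0 / (8.0 * np.pi) * (cfg.lambda_em_nm / cfg.n_medium) ** 2 * dnu**2
    psf = np.zeros((n_grid, n_grid))
    for i in range(2):
        pupil = np.tensordot(mu_view, E[:, i], axes=1)
        field = np.fft.ifft2(np.fft.ifftshift(pupil)) * n_grid**2
        psf += np.abs(np.fft.fftshift(field)) ** 2
    psf *= scale / n_grid**2
    return DipolePSF(intensity=psf, pixel_nm=1.0 / (n_grid * dnu),
                     efficiency=float(psf.sum()))


def coupled_transverse_kernels(cfg: OpticsConfig, view: str, n_grid: int,
                               dnu: float) -> np.ndarray:
    """Frequency-domain spatio-angular detection kernels Mhat_ab(nu).

    ``Mhat[a, b]`` is the 2D transverse transfer kernel multiplying the
    dipole dyad component s_a s_b (view frame), computed as the
    cross-correlation of the vectorial pupil fields.  Support is exactly
    |nu| < 2 NA / lambda.  Shape (3, 3, n, n), complex, fftshifted
    (zero frequency at the center), Hermitian in nu.
    """
    # compute on a doubled grid to avoid circular wrap of the correlation
    n_big = 2 * n_grid
    E = _pupil_fields(cfg, view, n_big, dnu)
    scale = 3.0 / (8.0 * np.pi) * (cfg.lambda_em_nm / cfg.n_medium) ** 2 * dnu**2
    img = np.fft.ifft2(np.fft.ifftshift(E, axes=(-2, -1)), axes=(-2, -1))
    Mhat = np.zeros((3, 3, n_big, n_big), dtype=complex)
    for a in range(3):
        for b in range(a, 3):
            m_ab = np.sum(img[a] * np.conj(img[b]), axis=0)
            # real-space kernel is Re(m_ab); its spectrum:
            spec = np.fft.fft2(m_ab.real) * scale * n_big**2
            Mhat[a, b] = np.fft.fftshift(spec)
            Mhat[b, a] = Mhat[a, b]
    lo = n_big // 2 - n_grid // 2
    return Mhat[:, :, lo:lo + n_grid, lo:lo + n_grid]


def excitation_dyad_tensor(spec: MeasurementSpec, cfg: OpticsConfig, view: str,
                           grid: SphereGrid | None = None) -> np.ndarray:
    """T[a, b, k] = int Y_k(s) exc(s) s_a s_b ds (view-frame components).

    Contracting with :func:`coupled_transverse_kernels` gives the coupled
    spatio-angular transfer function H_lm(nu) of the measurement.
    """
    grid = grid or sphere_grid()
    p = spec.polarization()
    exc = (grid.dirs @ p) ** 2
    t1, t2 = VIEW_TRANSVERSE[view]
    ax = DETECTION_AXES[view]
    comps = np.stack([grid.dirs @ t1, grid.dirs @ t2, grid.dirs @ ax])  # (3, N)
    T = np.zeros((3, 3, N_COEFFS))
    for a in range(3):
        for b in range(3):
            integrand = exc * comps[a] * comps[b]
            T[a, b] = sphharm.sh_project(integrand, grid)
    return T


def coupled_transfer_2d(spec: MeasurementSpec, cfg: OpticsConfig,
                        n_grid: int = 96, dnu: float | None = None) -> np.ndarray:
    """Coupled-mode transfer function of one measurement on a 2D transverse
    frequency grid of its detection view.  Shape (15, n, n), complex,
    fftshifted, photon-normalized.  At nu = 0 this equals the angular
    response coefficients exactly."""
    view = spec.detection_view
    if dnu is None:
        dnu = 6.0 * (cfg.detection_na(view) / cfg.lambda_em_nm) / n_grid
    Mhat = coupled_transverse_kernels(cfg, view, n_grid, dnu)
    T = excitation_dyad_tensor(spec, cfg, view)
    H = np.einsum("abk,abxy->kxy", T, Mhat)
    return H / photon_normalization(cfg)


# ---------------------------------------------------------------------------
# 3D transfer functions on a volume frequency grid
# ---------------------------------------------------------------------------

def disk_otf(rho: np.ndarray, cutoff: float) -> np.ndarray:
    """Incoherent OTF of a circular pupil ("chat" function), 1 at rho=0,
    0 at and beyond ``cutoff``."""
    x = np.clip(np.abs(rho) / cutoff, 0.0, 1.0)
    return (2.0 / np.pi) * (np.arccos(x) - x * np.sqrt(1.0 - x**2))


def _freq_grids(shape: tuple[int, int, int], spacing_nm: float):
    """fftfreq coordinate arrays (nu_z, nu_y, nu_x) for a (z, y, x) volume."""
    fz = np.fft.fftfreq(shape[0], d=spacing_nm)
    fy = np.fft.fftfreq(shape[1], d=spacing_nm)
    fx = np.fft.fftfreq(shape[2], d=spacing_nm)
    return np.meshgrid(fz, fy, fx, indexing="ij")


def scalar_otf(cfg: OpticsConfig, det_view: str, shape: tuple[int, int, int],
               spacing_nm: float) -> np.ndarray:
    """Factored-mode scalar OTF B(nu) of one detection view on a volume grid:
    disk OTF over the view's transverse frequencies times a Gaussian along
    its axial frequency (the light-sheet assumption).  B(0) = 1."""
    nz, ny, nx = _freq_grids(shape, spacing_nm)
    cutoff = cfg.transverse_cutoff(det_view)
    if 0.5 / spacing_nm < cutoff:
        warnings.warn(
            "voxel spacing too coarse for the detection cutoff 2NA/lambda; "
            "the frequency grid truncates the support", stacklevel=2)
    if det_view == "A":  # axis z, transverse (x, y)
        rho = np.sqrt(nx**2 + ny**2)
        ax = nz
    else:  # axis x, transverse (y, z)
        rho = np.sqrt(ny**2 + nz**2)
        ax = nx
    sig = cfg.sigma_axial_nm(det_view)
    return disk_otf(rho, cutoff) * np.exp(-2.0 * np.pi**2 * sig**2 * ax**2)


@dataclass
class TransferFunction:
    """Per-measurement spatio-angular transfer function on a volume grid.

    factored mode: H_i,lm(nu) = B_i(nu) * A[i, lm]  (scalar OTF x angular
    response); coupled mode: H assembled from the vectorial-pupil transverse
    kernels, so the spatial shape varies with (l, m).
    """

    specs: tuple[MeasurementSpec, ...]
    cfg: OpticsConfig
    shape: tuple[int, int, int]
    spacing_nm: float
    mode: str
    A: np.ndarray  # (n_meas, 15) angular matrix at nu = 0
    B: np.ndarray | None = None  # (n_meas, *shape) factored OTFs

    @property
    def n_meas(self) -> int:
        return len(self.specs)

    def measurement_h(self, i: int) -> np.ndarray:
        """Full H_lm(nu) of measurement ``i``, shape (15, *shape), complex."""
        if self.mode == "factored":
            return self.B[i][None] * self.A[i][:, None, None, None]
        return _coupled_h_3d(self.specs[i], self.cfg, self.shape, self.spacing_nm)

    def support_mask(self, i: int) -> np.ndarray:
        """Frequencies within the detection view's transverse support."""
        nzg, nyg, nxg = _freq_grids(self.shape, self.spacing_nm)
        view = self.specs[i].detection_view
        cutoff = self.cfg.transverse_cutoff(view)
        rho = (np.sqrt(nxg**2 + nyg**2) if view == "A"
               else np.sqrt(nyg**2 + nzg**2))
        return rho < cutoff


def _hermitian_symmetrize(a: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Enforce H(nu) = conj(H(-nu)) on fft-ordered axes (cropping a larger
    frequency grid can break the Nyquist pairing)."""
    rev = a
    for ax in axes:
        idx = (-np.arange(a.shape[ax])) % a.shape[ax]
        rev = np.take(rev, idx, axis=ax)
    return 0.5 * (a + np.conj(rev))


def _coupled_h_3d(spec: MeasurementSpec, cfg: OpticsConfig,
                  shape: tuple[int, int, int], spacing_nm: float) -> np.ndarray:
    """Coupled-mode H for one measurement on the volume's fft grid."""
    view = spec.detection_view
    # transverse fft grid of the view must match the volume's fft frequencies
    if view == "A":
        n1, n2, ax_len = shape[2], shape[1], shape[0]  # (x, y), axial z
    else:
        n1, n2, ax_len = shape[1], shape[0], shape[2]  # (y, z), axial x
    if n1 != n2:
        raise ValueError("coupled mode requires equal transverse dimensions")
    dnu = 1.0 / (n1 * spacing_nm)
    Mhat = coupled_transverse_kernels(cfg, view, n1, dnu)
    T = excitation_dyad_tensor(spec, cfg, view)
    H2 = np.einsum("abk,abxy->kxy", T, Mhat) / photon_normalization(cfg)
    H2 = np.fft.ifftshift(H2, axes=(-2, -1))  # to fft ordering
    H2 = _hermitian_symmetrize(H2, axes=(-2, -1))
    sig = cfg.sigma_axial_nm(view)
    ax_f = np.fft.fftfreq(ax_len, d=spacing_nm)
    gauss = np.exp(-2.0 * np.pi**2 * sig**2 * ax_f**2)
    if view == "A":  # H2 indexed (k, nu_x, nu_y) -> volume (k, z, y, x)
        H = H2.transpose(0, 2, 1)[:, None, :, :] * gauss[None, :, None, None]
    else:  # H2 indexed (k, nu_y, nu_z) -> volume (k, z, y, x)
        H = H2.transpose(0, 2, 1)[:, :, :, None] * gauss[None, None, None, :]
    return H


def transfer_function(scheme, cfg: OpticsConfig, shape: tuple[int, int, int],
                      spacing_nm: float, mode: str = "factored") -> TransferFunction:
    """Build the spatio-angular transfer function of a measurement scheme.

    ``scheme`` is a MeasurementScheme or sequence of MeasurementSpec.
    """
    specs = tuple(getattr(scheme, "specs", scheme))
    if not specs:
        raise ValueError("scheme must contain at least one measurement")
    if mode not in ("factored", "coupled"):
        raise ValueError("mode must be 'factored' or 'coupled'")
    for s in specs:
        if abs(s.tilt_rad) > cfg.max_tilt_rad:
            raise ValueError("tilt beyond configured maximum")
    A = angular_matrix(specs, cfg)
    B = None
    if mode == "factored":
        B = np.stack([scalar_otf(cfg, s.detection_view, shape, spacing_nm)
                      for s in specs])
    return TransferFunction(specs=specs, cfg=cfg, shape=tuple(shape),
                            spacing_nm=spacing_nm, mode=mode, A=A, B=B)
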