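"""Real spherical-harmonic basis for antipodally symmetric ODFs.

An orientation distribution function (ODF) describes how many fluorescent
dipole axes within a voxel point along each direction of the sphere.  Dipoles
are axes, not vectors, so ODFs are antipodally symmetric and contain only
even spherical-harmonic bands.  The imaging physics (cos^2 excitation times
finite-NA detection) band-limits everything to l <= 4, so a single ODF is a
vector of 15 real coefficients over the bands l in {0, 2, 4}.

Conventions
-----------
* Real, orthonormal spherical harmonics, **no** Condon-Shortley phase.
* Flat coefficient ordering (the "even-l4-v1" ordering, also used on disk)::

      k :  0    1      2      3     4     5     6      ...          14
    l,m : (0,0)(2,-2)(2,-1)(2,0)(2,1)(2,2)(4,-4)(4,-3) ... (4,3)(4,4)

* m > 0 harmonics go with cos(m*phi), m < 0 with sin(|m|*phi).
* Directions are unit 3-vectors (x, y, z); theta is the polar angle from +z,
  phi the azimuth from +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial

import numpy as np
from scipy.special import lpmv

L_MAX = 4
BANDS = (0, 2, 4)
N_COEFFS = 15

#: flat ordering of (l, m) pairs
LM_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (l, m) for l in BANDS for m in range(-l, l + 1)
)
_LM_TO_K = {lm: k for k, lm in enumerate(LM_PAIRS)}


class InvalidSHIndexError(ValueError):
    """Raised for odd l, l > L_MAX, or |m| > l."""


class DegenerateODFError(ValueError):
    """Raised when a scalar descriptor is undefined (e.g. GFA of a zero ODF)."""


def sh_index(l: int, m: int) -> int:
    """Flat index k in 0..14 for band ``l`` and intraband index ``m``."""
    try:
        return _LM_TO_K[(l, m)]
    except KeyError:
        raise InvalidSHIndexError(
            f"(l={l}, m={m}) is not a valid even-band index with l<={L_MAX}"
        ) from None


def sh_lm(k: int) -> tuple[int, int]:
    """Inverse of :func:`sh_index`."""
    if not 0 <= k < N_COEFFS:
        raise InvalidSHIndexError(f"flat index {k} outside 0..{N_COEFFS - 1}")
    return LM_PAIRS[k]


def band_slice(l: int) -> slice:
    """Slice of the flat coefficient vector covering band ``l``."""
    if l not in BANDS:
        raise InvalidSHIndexError(f"l={l} is not an even band <= {L_MAX}")
    start = _LM_TO_K[(l, -l)]
    return slice(start, start + 2 * l + 1)


def _check_unit(dirs: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    dirs = np.asarray(dirs, dtype=float)
    norms = np.linalg.norm(dirs, axis=-1)
    if not np.allclose(norms, 1.0, atol=tol):
        raise ValueError("directions must be unit vectors (|norm - 1| <= 1e-9)")
    return dirs


def real_sh_basis(l: int, m: int, dirs: np.ndarray) -> np.ndarray:
    """Evaluate one real orthonormal spherical harmonic at unit direction(s).

    Parameters
    ----------
    l, m
        Even band index (0, 2 or 4) and intraband index, |m| <= l.
    dirs
        Array of shape (..., 3) of unit vectors.

    Returns
    -------
    Array of shape (...) with the harmonic's values.
    """
    sh_index(l, m)  # validates
    dirs = _check_unit(np.atleast_2d(dirs))
    out = _sh_column(l, m, dirs)
    return out[0] if out.shape == (1,) else out


def _sh_column(l: int, m: int, dirs: np.ndarray) -> np.ndarray:
    """Unvalidated evaluation on an (N, 3) array of unit vectors."""
    z = np.clip(dirs[..., 2], -1.0, 1.0)
    phi = np.arctan2(dirs[..., 1], dirs[..., 0])
    am = abs(m)
    # lpmv includes the Condon-Shortley (-1)^m; cancel it.
    p = lpmv(am, l, z) * ((-1.0) ** am)
    norm = np.sqrt((2 * l + 1) / (4 * np.pi) * factorial(l - am) / factorial(l + am))
    if m == 0:
        return norm * p
    if m > 0:
        return np.sqrt(2.0) * norm * p * np.cos(am * phi)
    return np.sqrt(2.0) * norm * p * np.sin(am * phi)


def sh_basis_matrix(dirs: np.ndarray) -> np.ndarray:
    """Design matrix of all 15 harmonics, shape (..., 15)."""
    dirs = np.asarray(dirs, dtype=float)
    cols = [_sh_column(l, m, dirs) for l, m in LM_PAIRS]
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# Sphere quadrature grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereGrid:
    """Quadrature nodes on S^2 with weights in steradians.

    Gauss-Legendre in cos(theta) x uniform trapezoid in phi; exact for
    spherical polynomials up to ``degree``.  Antipodally symmetric by
    construction (GL nodes are symmetric about the equator and the phi grid
    contains phi + pi for every node).
    """

    dirs: np.ndarray
    weights: np.ndarray
    degree: int
    _basis: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_basis", sh_basis_matrix(self.dirs))

    @property
    def basis(self) -> np.ndarray:
        """(N, 15) matrix of harmonic values at the nodes."""
        return self._basis

    def integrate(self, values: np.ndarray) -> np.ndarray:
        """Quadrature integral over the sphere (last axis = nodes)."""
        return np.asarray(values) @ self.weights


@lru_cache(maxsize=8)
def sphere_grid(n_theta: int = 16, n_phi: int = 24) -> SphereGrid:
    """Default product quadrature grid (384 nodes, exact to degree 15)."""
    if n_phi % 2:
        raise ValueError("n_phi must be even for antipodal symmetry")
    x, w = np.polynomial.legendre.leggauss(n_theta)  # x = cos(theta)
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    ct, ph = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    dirs = np.stack(
        [st * np.cos(ph), st * np.sin(ph), ct * np.ones_like(ph)], axis=-1
    ).reshape(-1, 3)
    weights = np.repeat(w, n_phi) * (2 * np.pi / n_phi)
    degree = min(2 * n_theta - 1, n_phi - 1)
    return SphereGrid(dirs=dirs, weights=weights, degree=degree)


@lru_cache(maxsize=4)
def fibonacci_hemisphere(n: int = 8000) -> np.ndarray:
    """Quasi-uniform directions on the z >= 0 hemisphere (peak search grid)."""
    i = np.arange(n)
    z = (i + 0.5) / n  # uniform in z on [0, 1): upper hemisphere
    golden = (1 + np.sqrt(5)) / 2
    phi = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=-1)


# ---------------------------------------------------------------------------
# Projection / evaluation
# ---------------------------------------------------------------------------

def sh_project(
    values: np.ndarray,
    grid: SphereGrid | None = None,
    l_max: int = L_MAX,
    check_symmetry: bool = False,
    sym_tol: float = 1e-6,
) -> np.ndarray:
    """Project sphere samples onto the even-band basis by quadrature.

    ``values`` has the grid-node axis last; leading axes are batch axes.
    Exact (and idempotent with :func:`sh_evaluate`) for band-limited inputs
    when the grid integrates degree ``2*l_max`` products, which the default
    grid comfortably does.
    """
    grid = grid or sphere_grid()
    if l_max > L_MAX or l_max % 2:
        raise InvalidSHIndexError(f"l_max must be an even band <= {L_MAX}")
    if grid.degree < 2 * l_max:
        raise ValueError(
            f"grid quadrature degree {grid.degree} too sparse for l_max={l_max}"
        )
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != len(grid.weights):
        raise ValueError("one value per grid direction required")
    if check_symmetry:
        # antipode of node (theta, phi) is present by construction; build map once
        anti = _antipode_index(grid)
        if not np.allclose(values, values[..., anti], atol=sym_tol * max(1.0, np.abs(values).max())):
            raise ValueError("values are not antipodally symmetric within tolerance")
    coeffs = (values * grid.weights) @ grid.basis
    if l_max < L_MAX:
        coeffs = coeffs.copy()
        coeffs[..., band_slice(4)] = 0.0
    return coeffs


def _antipode_index(grid: SphereGrid) -> np.ndarray:
    d = np.round(grid.dirs, 12)
    order = {tuple(v): i for i, v in enumerate(d)}
    anti = np.array([order[tuple(v)] for v in np.round(-grid.dirs, 12)])
    return anti


def sh_evaluate(coeffs: np.ndarray, dirs_or_grid) -> np.ndarray:
    """Evaluate ODF(s) at directions; linear in the coefficients.

    ``dirs_or_grid`` may be a :class:`SphereGrid` or an (..., 3) array of unit
    vectors.  Returns shape ``coeffs.shape[:-1] + dirs.shape[:-1]``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != N_COEFFS:
        raise ValueError(f"expected {N_COEFFS} coefficients on the last axis")
    if isinstance(dirs_or_grid, SphereGrid):
        basis = dirs_or_grid.basis
    else:
        basis = sh_basis_matrix(np.asarray(dirs_or_grid, dtype=float))
    return coeffs @ np.moveaxis(basis, -1, 0)


# ---------------------------------------------------------------------------
# Scalar descriptors
# ---------------------------------------------------------------------------

def gfa(coeffs: np.ndarray) -> np.ndarray:
    """Generalized fractional anisotropy, std/rms of the ODF over the sphere.

    For an orthonormal basis this is sqrt(1 - F00^2 / sum(F^2)); 0 for an
    isotropic ODF, approaching 1 for sharply peaked ones.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    total = np.sum(coeffs**2, axis=-1)
    if np.any(total == 0):
        raise DegenerateODFError("GFA undefined for an all-zero ODF")
    val = 1.0 - coeffs[..., 0] ** 2 / total
    return np.sqrt(np.clip(val, 0.0, 1.0))


@dataclass(frozen=True)
class PeakResult:
    """Dominant dipole axis of one ODF."""

    direction: np.ndarray  # canonical hemisphere (z>=0; ties y>=0 then x>=0)
    value: float  # ODF maximum (peak-cylinder length)
    degenerate: bool  # True when the ODF is too flat to orient


def canonicalize_axis(d: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Map an axis to the z >= 0 hemisphere; ties broken by y then x >= 0."""
    d = np.asarray(d, dtype=float)
    flip = (d[..., 2] < -eps) | (
        (np.abs(d[..., 2]) <= eps)
        & ((d[..., 1] < -eps) | ((np.abs(d[..., 1]) <= eps) & (d[..., 0] < 0)))
    )
    return np.where(flip[..., None], -d, d)


def peak_orientation(
    coeffs: np.ndarray,
    n_dense: int = 8000,
    refine: bool = True,
    degenerate_tol: float = 1e-3,
) -> PeakResult:
    """Argmax of one ODF over a dense hemisphere grid with local refinement.

    Near-isotropic ODFs (max - min < tol * mean|ODF|) are flagged degenerate
    rather than assigned a noise-driven direction.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (N_COEFFS,):
        raise ValueError("peak_orientation works on a single coefficient vector")
    dirs = fibonacci_hemisphere(n_dense)
    vals = sh_evaluate(coeffs, dirs)
    vmax, vmin = vals.max(), vals.min()
    scale = max(np.abs(vals).mean(), np.finfo(float).tiny)
    if (vmax - vmin) < degenerate_tol * scale:
        return PeakResult(direction=np.array([0.0, 0.0, 1.0]), value=float(vmax), degenerate=True)
    best = dirs[int(np.argmax(vals))]
    if refine:
        best, vmax = _refine_peak(coeffs, best)
    return PeakResult(direction=canonicalize_axis(best), value=float(vmax), degenerate=False)


def _refine_peak(coeffs: np.ndarray, d0: np.ndarray) -> tuple[np.ndarray, float]:
    """Local maximization on the sphere via a tangent-plane parametrization."""
    from scipy.optimize import minimize

    e1 = np.cross(d0, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(d0, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d0, e1)

    def neg(uv):
        d = d0 + uv[0] * e1 + uv[1] * e2
        d = d / np.linalg.norm(d)
        return -sh_evaluate(coeffs, d)

    res = minimize(neg, np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 200})
    d = d0 + res.x[0] * e1 + res.x[1] * e2
    d /= np.linalg.norm(d)
    return d, float(-res.fun)


def peak_field(
    coeffs: np.ndarray,
    n_dense: int = 4000,
    degenerate_tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized grid-argmax peaks for a field of ODFs.

    Parameters
    ----------
    coeffs
        Array (..., 15).

    Returns
    -------
    axes : (..., 3) canonical peak axes
    values : (...) ODF maxima
    degenerate : (...) bool flags
    """
    coeffs = np.asarray(coeffs, dtype=float)
    lead = coeffs.shape[:-1]
    flat = coeffs.reshape(-1, N_COEFFS)
    dirs = fibonacci_hemisphere(n_dense)
    vals = flat @ sh_basis_matrix(dirs).T  # (n_vox, n_dirs)
    idx = np.argmax(vals, axis=1)
    vmax = vals[np.arange(len(flat)), idx]
    vmin = vals.min(axis=1)
    scale = np.maximum(np.abs(vals).mean(axis=1), np.finfo(float).tiny)
    degen = (vmax - vmin) < degenerate_tol * scale
    axes = canonicalize_axis(dirs[idx])
    axes[degen] = [0.0, 0.0, 1.0]
    return axes.reshape(lead + (3,)), vmax.reshape(lead), degen.reshape(lead)
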