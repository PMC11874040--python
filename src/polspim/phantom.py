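"""Synthetic ODF fields with exact ground truth.

Generators emulate the standard test objects of this instrument class:
giant unilamellar vesicles (GUVs) whose membrane dye sits normal (FM1-43
like) or tangential (in-membrane dyes) to a spherical shell, curvilinear
fibers (actin / cellulose) with dipoles along the local tangent, and
nanowire fixtures with fiber fields laid parallel to the wires.  All
concentrated ODFs are Watson distributions exp(kappa (s.mu)^2): antipodally
symmetric, dumbbell-shaped for kappa > 0, pancake-shaped (girdle) for
kappa < 0, isotropic at kappa = 0.

Geometry conventions: volumes are (z, y, x) voxel arrays with the
coefficient axis last; world coordinates are (x, y, z) vectors in nm at
voxel centers, z along the view-A detection axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import sphharm
from .sphharm import N_COEFFS, SphereGrid, sphere_grid


@dataclass
class ODFField:
    """3D grid of spherical-harmonic ODF coefficients.

    ``coeffs`` has shape (nz, ny, nx, 15); ``origin_nm`` is the world
    coordinate (x, y, z) of voxel (0, 0, 0)'s center.
    """

    coeffs: np.ndarray
    spacing_nm: float
    origin_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 4 or self.coeffs.shape[-1] != N_COEFFS:
            raise ValueError("coeffs must have shape (nz, ny, nx, 15)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")
        self.origin_nm = np.asarray(self.origin_nm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coeffs.shape[:3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (..., 3) as (x, y, z) nm."""
        nz, ny, nx = self.shape
        zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                                 indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1) * self.spacing_nm
        return pts + self.origin_nm

    def density(self) -> np.ndarray:
        """Total dipole count per voxel: integral of the ODF over the sphere."""
        return self.coeffs[..., 0] * np.sqrt(4.0 * np.pi)


@dataclass
class WireSet:
    """Straight nanowire segments (world nm coordinates)."""

    p0: np.ndarray  # (n, 3)
    p1: np.ndarray  # (n, 3)
    labels: list[str]
    diameter_nm: np.ndarray  # (n,)

    def __post_init__(self):
        self.p0 = np.atleast_2d(np.asarray(self.p0, dtype=float))
        self.p1 = np.atleast_2d(np.asarray(self.p1, dtype=float))
        if np.any(np.linalg.norm(self.p1 - self.p0, axis=-1) < 1e-9):
            raise ValueError("degenerate wire segment")
        self.diameter_nm = np.atleast_1d(np.asarray(self.diameter_nm, dtype=float))

    def __len__(self) -> int:
        return len(self.p0)

    def tangents(self) -> np.ndarray:
        t = self.p1 - self.p0
        return t / np.linalg.norm(t, axis=-1, keepdims=True)


def watson_odf(axis: np.ndarray, kappa: float,
               grid: SphereGrid | None = None) -> np.ndarray:
    """SH coefficients of a unit-mass Watson ODF about ``axis``.

    kappa > 0: polar (dumbbell); kappa < 0: girdle (pancake); 0: isotropic.
    Warns when |kappa| is too concentrated for the l <= 4 band limit
    (projection then aliases, flattening the peak).
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    grid = grid or sphere_grid()
    vals = np.exp(kappa * (grid.dirs @ axis) ** 2)
    vals = vals / grid.integrate(vals)
    coeffs = sphharm.sh_project(vals, grid)
    recon = sphharm.sh_evaluate(coeffs, grid)
    rel = np.sqrt(grid.integrate((vals - recon) ** 2) / grid.integrate(vals**2))
    if rel > 0.35:
        warnings.warn(
            f"|kappa|={abs(kappa):.3g} too concentrated for l<=4 "
            f"(band-limit residual {rel:.2f})", stacklevel=2)
    return coeffs


def _batch_watson(axes: np.ndarray, kappa: float, grid: SphereGrid) -> np.ndarray:
    """Unit-mass Watson coefficients for many axes at once; (n, 15)."""
    dots2 = (axes @ grid.dirs.T) ** 2
    vals = np.exp(kappa * dots2)
    vals /= (vals @ grid.weights)[:, None]
    return (vals * grid.weights) @ grid.basis


def guv_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing_nm: float = 130.0,
    radius_nm: float = 3000.0,
    shell_width_nm: float = 390.0,
    kappa: float = 5.0,
    mode: str = "normal",
    center_nm: np.ndarray | None = None,
    density: float = 1.0,
) -> tuple[ODFField, np.ndarray, np.ndarray]:
    """Spherical-shell phantom with membrane-normal (or tangential) ODFs.

    The default ~6 um diameter matches the GUV scale of the validation
    experiments.  Returns ``(field, truth_axes, shell_mask)`` where
    ``truth_axes`` holds the exact radial axis per voxel (zeros off-shell).
    """
    if mode not in ("normal", "tangential"):
        raise ValueError("mode must be 'normal' or 'tangential'")
    nz, ny, nx = shape
    ext = np.array([nx, ny, nz]) * spacing_nm
    if center_nm is None:
        center_nm = (ext - spacing_nm) / 2.0
    center_nm = np.asarray(center_nm, dtype=float)
    if radius_nm + shell_width_nm / 2 > min(ext) / 2:
        raise ValueError("shell does not fit inside the grid")
    fld = ODFField(np.zeros(shape + (N_COEFFS,)), spacing_nm)
    pts = fld.voxel_centers() - center_nm
    r = np.linalg.norm(pts, axis=-1)
    shell = np.abs(r - radius_nm) <= shell_width_nm / 2.0
    radial = np.zeros_like(pts)
    radial[shell] = pts[shell] / r[shell][..., None]
    grid = sphere_grid()
    k_eff = kappa if mode == "normal" else -kappa
    fld.coeffs[shell] = density * _batch_watson(radial[shell], k_eff, grid)
    return fld, radial, shell


def _point_segment_distance(points: np.ndarray, p0: np.ndarray,
                            p1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance from points (..., 3) to one segment; also the foot points."""
    d = p1 - p0
    t = np.clip(((points - p0) @ d) / (d @ d), 0.0, 1.0)
    foot = p0 + t[..., None] * d
    return np.linalg.norm(points - foot, axis=-1), foot


def fiber_phantom(
    polyline: np.ndarray,
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing_nm: float = 130.0,
    fiber_radius_nm: float = 260.0,
    kappa: float = 5.0,
    density: float = 1.0,
) -> tuple[ODFField, np.ndarray, np.ndarray]:
    """Tube of tangent-aligned Watson ODFs around a polyline.

    Overlapping/self-intersecting tubes are *summed* (linearity), producing
    multi-lobed ODFs at crossings.  Returns (field, truth_tangents, mask);
    the truth tangent at a voxel is that of the nearest polyline segment.
    """
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or len(polyline) < 2:
        raise ValueError("polyline must be (n >= 2, 3)")
    fld = ODFField(np.zeros(shape + (N_COEFFS,)), spacing_nm)
    pts = fld.voxel_centers()
    grid = sphere_grid()
    best = np.full(shape, np.inf)
    truth = np.zeros(shape + (3,))
    for a, b in zip(polyline[:-1], polyline[1:]):
        dist, _ = _point_segment_distance(pts, a, b)
        inside = dist <= fiber_radius_nm
        tangent = (b - a) / np.linalg.norm(b - a)
        if inside.any():
            fld.coeffs[inside] += density * _batch_watson(
                np.tile(tangent, (int(inside.sum()), 1)), kappa, grid)
        closer = dist < best
        best = np.minimum(best, dist)
        truth[closer] = tangent
    mask = best <= fiber_radius_nm
    truth[~mask] = 0.0
    return fld, truth, mask


def wire_fixture(
    arrangement: str = "single",
    shape: tuple[int, int, int] = (32, 48, 48),
    spacing_nm: float = 260.0,
    wire_diameter_nm: float = 200.0,
    pair_spacing_nm: float = 4000.0,
    fiber_halo_nm: float = 1500.0,
    kappa: float = 5.0,
    disordered_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[WireSet, ODFField, np.ndarray, np.ndarray]:
    """Nanowire arrangement ('single', 'paired', 'crossed') plus an
    actin-like ODF field with fibers parallel to the wires.

    Wires lie in the coverslip plane of the dual-view geometry, which is
    spanned by the shared lateral axis y and the in-plane diagonal
    u = (x - z)/sqrt(2) (the coverslip normal bisects the two detection
    axes).  'single' and 'paired' run along y; 'crossed' adds an orthogonal
    u-direction wire.  Voxels within ``fiber_halo_nm`` of a wire receive
    unit-mass Watson ODFs along the tangents of every wire in reach,
    blended by proximity — multi-lobed near crossings; a
    ``disordered_fraction`` of the mass goes along random axes (seeded).
    The truth axis is the nearest wire's tangent.  Returns
    (wires, field, truth_axes, mask).
    """
    nz, ny, nx = shape
    ext = np.array([nx, ny, nz]) * spacing_nm
    c = (ext - spacing_nm) / 2.0
    y_hat = np.array([0.0, 1.0, 0.0])
    u_hat = np.array([1.0, 0.0, -1.0]) / np.sqrt(2.0)
    half = float(np.linalg.norm(ext))  # long enough to span the box
    if arrangement == "single":
        segs = [(c - half * y_hat, c + half * y_hat)]
    elif arrangement == "paired":
        off = (pair_spacing_nm / 2.0) * u_hat
        segs = [(c - off - half * y_hat, c - off + half * y_hat),
                (c + off - half * y_hat, c + off + half * y_hat)]
    elif arrangement == "crossed":
        segs = [(c - half * y_hat, c + half * y_hat),
                (c - half * u_hat, c + half * u_hat)]
    else:
        raise ValueError("arrangement must be single, paired, or crossed")
    wires = WireSet(
        p0=np.array([s[0] for s in segs]), p1=np.array([s[1] for s in segs]),
        labels=[f"wire{i}" for i in range(len(segs))],
        diameter_nm=np.full(len(segs), wire_diameter_nm),
    )
    fld = ODFField(np.zeros(shape + (N_COEFFS,)), spacing_nm)
    pts = fld.voxel_centers()
    dist = np.stack([_point_segment_distance(pts, wires.p0[i], wires.p1[i])[0]
                     for i in range(len(wires))])
    nearest = np.argmin(dist, axis=0)
    mind = np.take_along_axis(dist, nearest[None], axis=0)[0]
    mask = mind <= fiber_halo_nm
    tangents = wires.tangents()
    truth = np.where(mask[..., None], tangents[nearest], 0.0)
    grid = sphere_grid()
    rng = np.random.default_rng(seed)
    n_in = int(mask.sum())
    # fibers blend the tangent families of all wires within reach,
    # weighted by proximity: near a crossing the ODF becomes multi-lobed
    w = np.clip(fiber_halo_nm - dist, 0.0, None)[:, mask]  # (n_wires, n_in)
    lone = w.sum(axis=0) == 0.0  # voxels exactly on the halo boundary
    if lone.any():
        w[nearest[mask][lone], np.flatnonzero(lone)] = 1.0
    w /= w.sum(axis=0, keepdims=True)
    aligned = np.zeros((n_in, N_COEFFS))
    for i in range(len(wires)):
        active = w[i] > 0
        if active.any():
            aligned[active] += w[i][active, None] * _batch_watson(
                np.tile(tangents[i], (int(active.sum()), 1)), kappa, grid)
    fld.coeffs[mask] = (1.0 - disordered_fraction) * aligned
    if disordered_fraction > 0.0:
        rand_axes = rng.normal(size=(n_in, 3))
        rand_axes /= np.linalg.norm(rand_axes, axis=-1, keepdims=True)
        fld.coeffs[mask] += disordered_fraction * _batch_watson(rand_axes, kappa, grid)
    return wires, fld, truth, mask
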