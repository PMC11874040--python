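"""Scalar and directional summaries of reconstructed ODF fields.

Mirrors the downstream analysis of the nanowire experiments: per-voxel peak
axes are compared with hand-annotated (here: synthetic) wires through two
axis metrics,

* parallelism = |p . t|, cosine to the nearest wire's tangent t;
* radiality   = |p . r|, cosine to the unit perpendicular offset r from the
  nearest wire to the voxel;

restricted to qualifying voxels (total counts above a threshold and within
a maximum distance of a wire).  Cell-scale shape is summarized by the
aspect ratio, the largest/smallest eigenvalue ratio of the density-weighted
moment-of-inertia tensor.  Group comparisons use two-sample t-tests and
Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import sphharm
from .phantom import ODFField, WireSet, _point_segment_distance
from .simulate import IrradianceStack

COUNT_THRESHOLD = 5000.0
MAX_WIRE_DIST_NM = 5000.0


@dataclass
class PeakField:
    """Per-voxel canonical peak axes of an ODF field."""

    axes: np.ndarray  # (nz, ny, nx, 3), canonical hemisphere
    values: np.ndarray  # ODF maxima (peak-cylinder lengths)
    degenerate: np.ndarray  # bool
    spacing_nm: float


def peak_map(field: ODFField, n_dense: int = 4000) -> PeakField:
    """Grid-argmax peak extraction over a whole field."""
    axes, values, degen = sphharm.peak_field(field.coeffs, n_dense=n_dense)
    return PeakField(axes=axes, values=values, degenerate=degen,
                     spacing_nm=field.spacing_nm)


def density_map(field: ODFField) -> np.ndarray:
    """Total dipole count per voxel (integral of the ODF): F00 * sqrt(4 pi)."""
    return field.density()


def gfa_map(field: ODFField, floor: float = 1e-12) -> np.ndarray:
    """Per-voxel generalized fractional anisotropy; NaN where the ODF is ~0."""
    total = np.sum(field.coeffs**2, axis=-1)
    out = np.full(field.shape, np.nan)
    ok = total > floor
    out[ok] = np.sqrt(np.clip(
        1.0 - field.coeffs[..., 0][ok] ** 2 / total[ok], 0.0, 1.0))
    return out


def nearest_wire(points: np.ndarray, wires: WireSet):
    """Nearest-segment assignment for world points (..., 3).

    Returns (distance, wire_index, tangent, foot_point); ties go to the
    lower wire index (deterministic).
    """
    dists = []
    feet = []
    for i in range(len(wires)):
        d, f = _point_segment_distance(points, wires.p0[i], wires.p1[i])
        dists.append(d)
        feet.append(f)
    dists = np.stack(dists)
    idx = np.argmin(dists, axis=0)  # argmin takes the first minimum: low label
    dmin = np.take_along_axis(dists, idx[None], axis=0)[0]
    feet = np.stack(feet)
    foot = np.take_along_axis(
        feet, idx[None, ..., None], axis=0)[0]
    tangent = wires.tangents()[idx]
    return dmin, idx, tangent, foot


def qualifying_mask(
    stack_or_counts: IrradianceStack | np.ndarray,
    count_threshold: float = COUNT_THRESHOLD,
    wires: WireSet | None = None,
    max_dist_nm: float = MAX_WIRE_DIST_NM,
    spacing_nm: float | None = None,
    origin_nm: np.ndarray = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Voxels with total counts strictly above threshold and (optionally)
    closer than ``max_dist_nm`` to the nearest wire."""
    if count_threshold <= 0 or max_dist_nm <= 0:
        raise ValueError("thresholds must be positive")
    if isinstance(stack_or_counts, IrradianceStack):
        counts = stack_or_counts.total_counts()
        spacing_nm = spacing_nm or stack_or_counts.spacing_nm
    else:
        counts = np.asarray(stack_or_counts)
        if wires is not None and spacing_nm is None:
            raise ValueError("spacing_nm required for wire distances")
    mask = counts > count_threshold  # strict: a voxel at threshold is out
    if wires is not None:
        pts = _voxel_centers(counts.shape, spacing_nm, np.asarray(origin_nm))
        dmin, _, _, _ = nearest_wire(pts, wires)
        mask &= dmin < max_dist_nm
    return mask


def _voxel_centers(shape, spacing_nm, origin_nm):
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    return np.stack([xx, yy, zz], axis=-1) * spacing_nm + origin_nm


@dataclass
class AxisMetric:
    values: np.ndarray  # per qualifying voxel
    mean: float
    sd: float
    n_excluded: int = 0


def parallelism(peaks: PeakField, wires: WireSet, mask: np.ndarray,
                origin_nm=(0.0, 0.0, 0.0), form: str = "abs_cos") -> AxisMetric:
    """|cos| (or cos^2 with form='cos2') between peak axes and the nearest
    wire tangent over the masked, nondegenerate voxels."""
    mask = mask & ~peaks.degenerate
    if not mask.any():
        raise ValueError("empty qualifying mask")
    pts = _voxel_centers(mask.shape, peaks.spacing_nm, np.asarray(origin_nm))
    _, _, tangent, _ = nearest_wire(pts[mask], wires)
    c = np.abs(np.sum(peaks.axes[mask] * tangent, axis=-1))
    vals = np.clip(c**2 if form == "cos2" else c, 0.0, 1.0)
    return AxisMetric(values=vals, mean=float(vals.mean()), sd=float(vals.std()))


def radiality(peaks: PeakField, wires: WireSet, mask: np.ndarray,
              origin_nm=(0.0, 0.0, 0.0), form: str = "abs_cos",
              eps_nm: float = 1.0) -> AxisMetric:
    """|cos| between peak axes and the perpendicular offset direction from
    the nearest wire.  Voxels on the wire axis (|offset| < eps) are excluded
    and counted in ``n_excluded``."""
    mask = mask & ~peaks.degenerate
    if not mask.any():
        raise ValueError("empty qualifying mask")
    pts = _voxel_centers(mask.shape, peaks.spacing_nm, np.asarray(origin_nm))
    p = pts[mask]
    _, _, tangent, foot = nearest_wire(p, wires)
    off = p - foot
    off_perp = off - np.sum(off * tangent, axis=-1, keepdims=True) * tangent
    norm = np.linalg.norm(off_perp, axis=-1)
    ok = norm >= eps_nm
    r_hat = off_perp[ok] / norm[ok][:, None]
    c = np.abs(np.sum(peaks.axes[mask][ok] * r_hat, axis=-1))
    vals = np.clip(c**2 if form == "cos2" else c, 0.0, 1.0)
    return AxisMetric(values=vals, mean=float(vals.mean()), sd=float(vals.std()),
                      n_excluded=int((~ok).sum()))


def aspect_ratio(density: np.ndarray, mask: np.ndarray,
                 spacing_nm: float = 1.0) -> float:
    """lambda_max / lambda_min of the density-weighted inertia tensor.

    I = sum_i m_i (||r_i - rbar||^2 Id - (r_i - rbar)(r_i - rbar)^T).
    Returns +inf for degenerate (zero smallest eigenvalue) distributions.
    """
    if not mask.any():
        raise ValueError("empty mask")
    m = np.asarray(density)[mask]
    if m.sum() <= 0:
        raise ValueError("mask must contain positive mass")
    pts = _voxel_centers(mask.shape, spacing_nm, np.zeros(3))[mask]
    rbar = (m[:, None] * pts).sum(axis=0) / m.sum()
    d = pts - rbar
    r2 = np.sum(d**2, axis=-1)
    I = np.einsum("i,ijk->jk", m, r2[:, None, None] * np.eye(3)[None]
                  - d[:, :, None] * d[:, None, :])
    ev = np.linalg.eigvalsh(I)
    if ev[0] <= 1e-12 * max(ev[-1], 1e-300):
        return float("inf")
    return float(ev[-1] / ev[0])


def angular_histogram(peaks: PeakField, mask: np.ndarray,
                      viewing_axis=(0.0, 0.0, 1.0),
                      n_rings: int = 4, bins_per_ring=(1, 9, 21, 33)):
    """Counts of peak axes on the Lambert equal-area disc about a viewing
    axis.  Axes along the viewing axis land in the central bin, in-plane
    axes at the disc edge; total counts are conserved.

    Returns (counts_per_ring: list of arrays, ring_edges: radii in [0, 1]).
    """
    mask = mask & ~peaks.degenerate
    if not mask.any():
        raise ValueError("empty qualifying mask")
    v = np.asarray(viewing_axis, dtype=float)
    v = v / np.linalg.norm(v)
    axes = peaks.axes[mask]
    # canonicalize to the viewing hemisphere
    s = np.sign(axes @ v)
    s[s == 0] = 1.0
    axes = axes * s[:, None]
    ct = np.clip(axes @ v, -1.0, 1.0)
    # Lambert azimuthal equal-area, normalized to unit radius at the equator
    r = np.sqrt(2.0) * np.sin(np.arccos(ct) / 2.0)
    # azimuth in the plane perpendicular to v
    e1 = np.cross(v, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(v, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    phi = np.arctan2(axes @ e2, axes @ e1)
    edges = np.sqrt(np.arange(n_rings + 1) / n_rings)  # equal-area rings
    counts = []
    for i in range(n_rings):
        nb = bins_per_ring[i]
        inside = (r >= edges[i]) & (r < edges[i + 1] if i < n_rings - 1
                                    else r <= edges[i + 1] + 1e-12)
        b = np.floor((phi[inside] + np.pi) / (2 * np.pi) * nb).astype(int)
        b = np.clip(b, 0, nb - 1)
        counts.append(np.bincount(b, minlength=nb))
    return counts, edges


def group_compare(rows: pd.DataFrame,
                  metrics=("parallelism_mean", "radiality_mean"),
                  group_col: str = "arrangement",
                  aspect_col: str = "aspect_ratio") -> dict:
    """Pairwise two-sample t-tests between groups and Pearson correlation of
    each metric against the aspect ratio across all rows.

    ``rows`` needs one row per cell/FOV with columns for the group label,
    the metrics, and the aspect ratio.
    """
    groups = list(rows[group_col].unique())
    if len(groups) < 2 or rows.groupby(group_col).size().min() < 2:
        raise ValueError("need >= 2 groups with >= 2 rows each")
    ttests = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            for m in metrics:
                a = rows.loc[rows[group_col] == ga, m]
                b = rows.loc[rows[group_col] == gb, m]
                t, p = stats.ttest_ind(a, b)
                ttests.append({"group_a": ga, "group_b": gb, "metric": m,
                               "t": float(t), "p": float(p)})
    correlations = {}
    if len(rows) >= 3:
        for m in metrics:
            r, p = stats.pearsonr(rows[aspect_col], rows[m])
            correlations[m] = {"r": float(r), "p": float(p)}
    return {"t_tests": pd.DataFrame(ttests), "pearson": correlations}
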