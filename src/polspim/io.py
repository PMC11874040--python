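"""File formats and run configuration.

Data volumes travel as multi-page 32-bit float TIFFs with a JSON sidecar
carrying machine metadata (voxel spacing, scheme, noise model, seed,
coefficient ordering version, config hash).  Wires and summary tables are
CSV.  Volumes are stored (z, y, x) with z along the view-A detection axis;
coefficient fields add a leading channel axis in the documented flat SH
ordering ("even-l4-v1").
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__ as _version
from .optics import MeasurementSpec, OpticsConfig
from .phantom import ODFField, WireSet
from .scheme import MeasurementScheme, make_scheme
from .simulate import IrradianceStack
from .sphharm import N_COEFFS

SH_ORDERING_VERSION = "even-l4-v1"


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk artifacts."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _load_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"missing sidecar JSON: expected {sc}")
    return json.loads(sc.read_text())


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Coefficient fields
# ---------------------------------------------------------------------------

def write_coeff_field(path, field: ODFField, extra_meta: dict | None = None):
    """15-channel float32 TIFF (channel, z, y, x) + sidecar."""
    path = Path(path)
    data = np.moveaxis(field.coeffs, -1, 0).astype(np.float32)
    tifffile.imwrite(path, data)
    meta = {
        "kind": "coefficient_field",
        "sh_ordering": SH_ORDERING_VERSION,
        "n_channels": N_COEFFS,
        "axes": "kzyx",
        "voxel_spacing_nm": float(field.spacing_nm),
        "origin_nm": [float(v) for v in field.origin_nm],
        "software_version": _version,
    }
    meta.update(extra_meta or {})
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_coeff_field(path) -> ODFField:
    path = Path(path)
    meta = _load_sidecar(path)
    if meta.get("sh_ordering") != SH_ORDERING_VERSION:
        raise FormatError(
            f"coefficient ordering {meta.get('sh_ordering')!r} does not match "
            f"this library ({SH_ORDERING_VERSION})")
    if meta.get("axes") != "kzyx":
        raise FormatError(f"unsupported axis order {meta.get('axes')!r}")
    data = tifffile.imread(path)
    if data.ndim != 4 or data.shape[0] != N_COEFFS:
        raise FormatError(
            f"expected {N_COEFFS} coefficient channels, found shape {data.shape}")
    return ODFField(coeffs=np.moveaxis(data.astype(float), 0, -1),
                    spacing_nm=meta["voxel_spacing_nm"],
                    origin_nm=np.array(meta.get("origin_nm", [0.0, 0.0, 0.0])))


# ---------------------------------------------------------------------------
# Irradiance stacks
# ---------------------------------------------------------------------------

def _spec_to_dict(s: MeasurementSpec) -> dict:
    return {"illum_view": s.illum_view, "pol_angle_rad": float(s.pol_angle_rad),
            "tilt_rad": float(s.tilt_rad)}


def _optics_to_dict(cfg: OpticsConfig) -> dict:
    return {k: getattr(cfg, k) for k in (
        "na_a", "na_b", "n_medium", "lambda_ex_nm", "lambda_em_nm",
        "sigma_ls_nm", "sigma_det_a_nm", "sigma_det_b_nm")}


def write_stack(directory, stack: IrradianceStack):
    """One multi-page float32 TIFF per measurement plus scheme sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(stack.n_meas):
        tifffile.imwrite(directory / f"meas_{i:03d}.tif",
                         stack.data[i].astype(np.float32))
    meta = {
        "kind": "irradiance_stack",
        "scheme_name": stack.scheme.name,
        "measurements": [_spec_to_dict(s) for s in stack.scheme],
        "optics": _optics_to_dict(stack.cfg),
        "voxel_spacing_nm": float(stack.spacing_nm),
        "axes": "zyx",
        "noise": stack.noise,
        "software_version": _version,
    }
    meta["config_hash"] = config_hash(meta)
    (directory / "stack.json").write_text(json.dumps(meta, indent=1))


def read_stack(directory) -> IrradianceStack:
    directory = Path(directory)
    sc = directory / "stack.json"
    if not sc.exists():
        raise FormatError(f"missing sidecar JSON: expected {sc}")
    meta = json.loads(sc.read_text())
    if meta.get("axes") != "zyx":
        raise FormatError(f"unsupported axis order {meta.get('axes')!r}")
    specs = tuple(MeasurementSpec(**d) for d in meta["measurements"])
    scheme = MeasurementScheme(specs, name=meta.get("scheme_name", "custom"))
    opt = {k: v for k, v in meta["optics"].items()}
    cfg = OpticsConfig(**opt)
    vols = [tifffile.imread(directory / f"meas_{i:03d}.tif").astype(float)
            for i in range(len(specs))]
    return IrradianceStack(data=np.stack(vols), scheme=scheme, cfg=cfg,
                           spacing_nm=meta["voxel_spacing_nm"],
                           noise=meta.get("noise"))


def write_volume(path, volume: np.ndarray, spacing_nm: float,
                 meta: dict | None = None):
    """Single scalar volume (z, y, x) as float32 TIFF + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32))
    m = {"kind": "volume", "axes": "zyx", "voxel_spacing_nm": float(spacing_nm),
         "software_version": _version}
    m.update(meta or {})
    _sidecar_path(path).write_text(json.dumps(m, indent=1))


# ---------------------------------------------------------------------------
# Wires
# ---------------------------------------------------------------------------

WIRE_COLUMNS = ["x1", "y1", "z1", "x2", "y2", "z2", "label", "diameter_nm"]


def write_wires(path, wires: WireSet):
    df = pd.DataFrame({
        "x1": wires.p0[:, 0], "y1": wires.p0[:, 1], "z1": wires.p0[:, 2],
        "x2": wires.p1[:, 0], "y2": wires.p1[:, 1], "z2": wires.p1[:, 2],
        "label": wires.labels, "diameter_nm": wires.diameter_nm,
    })
    df.to_csv(path, index=False)


def read_wires(path) -> WireSet:
    df = pd.read_csv(path)
    missing = set(WIRE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"wire CSV missing columns: {sorted(missing)}")
    return WireSet(
        p0=df[["x1", "y1", "z1"]].to_numpy(float),
        p1=df[["x2", "y2", "z2"]].to_numpy(float),
        labels=[str(v) for v in df["label"]],
        diameter_nm=df["diameter_nm"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ALLOWED_KEYS = {
    "optics": {"na_a", "na_b", "n_medium", "lambda_ex_nm", "lambda_em_nm",
               "sigma_ls_nm", "sigma_det_a_nm", "sigma_det_b_nm"},
    "scheme": {"name", "specs"},
    "phantom": {"kind", "shape", "spacing_nm", "radius_nm", "shell_width_nm",
                "kappa", "mode", "arrangement", "disordered_fraction", "seed",
                "density"},
    "noise": {"model", "photons_per_unit", "target_total_counts", "seed",
              "gaussian_sigma"},
    "recon": {"eta", "mode", "pad"},
    "analysis": {"count_threshold", "max_wire_dist_nm"},
}


def load_config(path) -> dict:
    """Strict YAML run config: unknown sections or keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for section, content in raw.items():
        if section not in _ALLOWED_KEYS:
            raise FormatError(f"unknown config section {section!r}")
        unknown = set(content or {}) - _ALLOWED_KEYS[section]
        if unknown:
            raise FormatError(
                f"unknown keys in config section {section!r}: {sorted(unknown)}")
    return raw


def build_optics(config: dict) -> OpticsConfig:
    return OpticsConfig(**(config.get("optics") or {}))


def build_scheme(config: dict) -> MeasurementScheme:
    section = dict(config.get("scheme") or {"name": "six_with_tilt"})
    name = section.pop("name", "custom")
    if "specs" in section:
        specs = [MeasurementSpec(**d) for d in section.pop("specs")]
        return MeasurementScheme(tuple(specs), name=name)
    return make_scheme(name, section or None)
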