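"""Shared readers, writers, configuration, and run manifests.

On-disk conventions: angle stacks and decay cubes are multi-page TIFF with
page order defining angle / time-bin order (no per-page metadata is assumed);
angle lists are plain text, one angle in degrees per line; optical
configuration is TOML; tables are comma-delimited UTF-8 CSV with header rows.
Heights are always in nm, bound fractions dimensionless.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, InvalidInputError
from .optics import AngleGrid, OpticalStackConfig
from .phasor import DecayImage
from .reconstruct import AngleImageStack, HeightMap, ThicknessResult

__all__ = [
    "read_angle_stack",
    "write_angle_stack",
    "read_decay_image",
    "write_decay_image",
    "load_optical_config",
    "config_hash",
    "write_height_map",
    "read_height_map",
    "write_thickness_csv",
    "read_rois_csv",
    "write_outputs",
]

_CONFIG_KEYS = {"wavelength_nm", "n_buffer", "n_oxide", "n_silicon", "d_oxide_nm"}


def _as_complex(value) -> complex:
    """Accept a scalar or a [re, im] pair from TOML."""
    if isinstance(value, (list, tuple)):
        if len(value) != 2:
            raise FormatError(f"index must be a number or [re, im] pair, got {value!r}")
        return complex(value[0], value[1])
    return complex(value)


def load_optical_config(path, d_oxide_nm: float | None = None) -> OpticalStackConfig:
    """Read an optical TOML config; unknown keys are rejected.

    ``d_oxide_nm`` overrides the file value — mirroring the per-chip oxide
    thickness measured for each wafer chip.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"unknown optical config keys: {sorted(unknown)}")
    missing = {"wavelength_nm"} - set(raw)
    if missing:
        raise FormatError(f"optical config missing keys: {sorted(missing)}")
    kwargs = {"wavelength_nm": float(raw["wavelength_nm"])}
    for key in ("n_buffer", "n_oxide", "n_silicon"):
        if key in raw:
            kwargs[key] = _as_complex(raw[key])
    if d_oxide_nm is not None:
        kwargs["d_oxide_nm"] = float(d_oxide_nm)
    elif "d_oxide_nm" in raw:
        kwargs["d_oxide_nm"] = float(raw["d_oxide_nm"])
    return OpticalStackConfig(**kwargs)


def config_hash(config: OpticalStackConfig) -> str:
    """Stable hash of every physical constant entering the optics."""
    payload = {
        "wavelength_nm": config.wavelength_nm,
        "n_buffer": [config.n_buffer.real, config.n_buffer.imag],
        "n_oxide": [config.n_oxide.real, config.n_oxide.imag],
        "n_silicon": [config.n_silicon.real, config.n_silicon.imag],
        "d_oxide_nm": config.d_oxide_nm,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def read_angle_stack(path_tiff, path_angles, config: OpticalStackConfig | None = None,
                     channel: str = "") -> AngleImageStack:
    """Load a page-per-angle TIFF plus its angle list into an AngleImageStack."""
    data = tifffile.imread(path_tiff)
    if data.ndim == 2:
        data = data[None]
    angles = np.atleast_1d(np.loadtxt(path_angles, dtype=float))
    if data.shape[0] != len(angles):
        raise FormatError(
            f"stack has {data.shape[0]} pages but angle file lists {len(angles)} angles"
        )
    if len(angles) > 1 and not np.all(np.diff(angles) > 0):
        raise FormatError("angle list must be strictly increasing")
    grid = AngleGrid(angles)
    d_ox = config.d_oxide_nm if config is not None else None
    return AngleImageStack(grid=grid, intensities=data.astype(float),
                           channel=channel or Path(path_tiff).stem, d_oxide_nm=d_ox)


def write_angle_stack(stack: AngleImageStack, path_tiff, path_angles) -> None:
    tifffile.imwrite(path_tiff, stack.intensities.astype(np.float32))
    np.savetxt(path_angles, stack.grid.angles_deg, fmt="%.6f")


def read_decay_image(path_tiff, bin_width_ns: float, rep_period_ns: float,
                     channel: str = "") -> DecayImage:
    """Load a page-per-time-bin TIFF decay cube."""
    data = tifffile.imread(path_tiff)
    if data.ndim == 2:
        data = data[None]
    return DecayImage(counts=data, bin_width_ns=bin_width_ns,
                      rep_period_ns=rep_period_ns, channel=channel)


def write_decay_image(decay: DecayImage, path_tiff) -> None:
    tifffile.imwrite(path_tiff, decay.counts.astype(np.float32))


def write_height_map(hmap: HeightMap, outdir, prefix: str = "") -> dict:
    """Write height/amplitude/offset/SSE maps (float32 TIFF) and mask (uint8 TIFF)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, arr, dtype in (
        ("height_nm", hmap.heights_nm, np.float32),
        ("height_raw_nm", hmap.heights_raw_nm, np.float32),
        ("amplitude", hmap.amplitude, np.float32),
        ("offset", hmap.offset, np.float32),
        ("sse", hmap.sse, np.float32),
        ("quality_mask", hmap.quality_mask, np.uint8),
    ):
        path = outdir / f"{prefix}{name}.tif"
        tifffile.imwrite(path, arr.astype(dtype))
        files[name] = str(path)
    return files


def read_height_map(path_height, path_mask=None) -> HeightMap:
    """Re-load a height map written by :func:`write_height_map` (height + mask only)."""
    heights = tifffile.imread(path_height).astype(float)
    if path_mask is not None:
        mask = tifffile.imread(path_mask).astype(bool)
    else:
        mask = np.isfinite(heights)
    nanless = np.where(np.isfinite(heights), heights, np.nan)
    return HeightMap(
        heights_nm=np.where(mask, nanless, np.nan),
        amplitude=np.full(heights.shape, np.nan),
        offset=np.full(heights.shape, np.nan),
        sse=np.full(heights.shape, np.nan),
        quality_mask=mask,
        heights_raw_nm=heights,
    )


def write_thickness_csv(results: list[ThicknessResult], path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "roi_id": r.roi_id,
                "mean_dye_nm": r.mean_height_dye_nm,
                "mean_ref_nm": r.mean_height_reference_nm,
                "thickness_nm": r.thickness_nm,
                "n_pixels": r.n_pixels_used,
            }
            for r in results
        ]
    )
    df.to_csv(path, index=False)
    return df


def read_rois_csv(path) -> list[tuple]:
    """ROI centers file: columns roi_id, row0, col0 (top-left corners)."""
    df = pd.read_csv(path)
    required = {"roi_id", "row0", "col0"}
    if required - set(df.columns):
        raise FormatError(f"ROI CSV must have columns {sorted(required)}")
    return [(str(r.roi_id), int(r.row0), int(r.col0)) for r in df.itertuples()]


def write_outputs(files: dict, outdir, config: OpticalStackConfig | None = None,
                  seed: int | None = None, extra: dict | None = None) -> dict:
    """Write a reproducibility manifest listing every artifact of a run.

    ``files`` maps artifact names to paths (must exist). The manifest records
    the optical-config hash and the seed so any run can be regenerated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, path in files.items():
        if not Path(path).exists():
            raise InvalidInputError(f"manifest artifact {name!r} missing at {path}")
    manifest = {
        "artifacts": {name: str(path) for name, path in sorted(files.items())},
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(path)
    return manifest
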