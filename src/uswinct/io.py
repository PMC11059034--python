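"""File formats and run configuration.

Images round-trip as 32-bit float TIFF, NIfTI or NPZ with the HU values
stored directly (NPZ additionally carries the provenance tags and is
bit-exact).  DICOM is read-only, with rescale slope/intercept applied.
Sinograms are NPZ archives (values + angle mask) with a JSON geometry
sidecar.  A run is driven by a YAML config whose persisted copy fully
reproduces the run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .phantom import ImageHU
from .projection import FanBeamGeometry, Sinogram

__all__ = [
    "read_image",
    "write_image",
    "write_sinogram",
    "read_sinogram",
    "load_run_config",
    "save_run_config",
    "DEFAULT_RUN_CONFIG",
]


class FileFormatError(IOError):
    """Unknown extension or corrupt file."""


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def write_image(path, img: ImageHU) -> None:
    path = Path(path)
    suffix = _suffix(path)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            img.pixels.astype(np.float32),
            metadata={
                "pixel_spacing_mm": img.pixel_spacing_mm,
                "patient_id": img.patient_id,
                "phase_pct": img.phase_pct,
                "slice_idx": img.slice_idx,
                "role": img.role,
            },
        )
    elif suffix in (".nii", ".nii.gz"):
        affine = np.diag([img.pixel_spacing_mm, img.pixel_spacing_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(img.pixels.astype(np.float32), affine), str(path))
    elif suffix == ".npz":
        np.savez(
            path,
            pixels=img.pixels,
            pixel_spacing_mm=img.pixel_spacing_mm,
            patient_id=img.patient_id,
            phase_pct=img.phase_pct,
            slice_idx=img.slice_idx,
            role=img.role,
        )
    else:
        raise FileFormatError(f"unsupported image extension: {path.name}")


def read_image(path) -> ImageHU:
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"no such file: {path}")
    suffix = _suffix(path)
    try:
        if suffix in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                pixels = tf.asarray().astype(np.float64)
                meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
            return ImageHU(
                pixels=pixels,
                pixel_spacing_mm=float(meta.get("pixel_spacing_mm", 1.0)),
                patient_id=str(meta.get("patient_id", "")),
                phase_pct=float(meta.get("phase_pct", 0.0)),
                slice_idx=int(meta.get("slice_idx", 0)),
                role=str(meta.get("role", "ground_truth")),
            )
        if suffix in (".nii", ".nii.gz"):
            nii = nib.load(str(path))
            spacing = float(abs(nii.affine[0, 0]))
            return ImageHU(pixels=np.asarray(nii.dataobj, dtype=np.float64), pixel_spacing_mm=spacing)
        if suffix == ".npz":
            with np.load(path) as d:
                return ImageHU(
                    pixels=d["pixels"],
                    pixel_spacing_mm=float(d["pixel_spacing_mm"]),
                    patient_id=str(d["patient_id"]),
                    phase_pct=float(d["phase_pct"]),
                    slice_idx=int(d["slice_idx"]),
                    role=str(d["role"]),
                )
        if suffix in (".dcm", ".dicom"):
            import pydicom

            ds = pydicom.dcmread(str(path))
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            pixels = ds.pixel_array.astype(np.float64) * slope + intercept
            spacing = float(ds.PixelSpacing[0]) if hasattr(ds, "PixelSpacing") else 1.0
            return ImageHU(pixels=pixels, pixel_spacing_mm=spacing, patient_id=str(getattr(ds, "PatientID", "")))
    except FileFormatError:
        raise
    except Exception as exc:  # corrupt content of a known format
        raise FileFormatError(f"cannot read {path}: {exc}") from exc
    raise FileFormatError(f"unsupported image extension: {path.name}")


def save_preview(path, img: ImageHU, display_window: tuple[float, float] = (-800.0, 1000.0)) -> None:
    """Render an HU image to a PNG with a display window (storage stays full-range)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    lo, hi = display_window
    ax.imshow(img.pixels, cmap="gray", vmin=lo, vmax=hi)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def write_sinogram(path, sino: Sinogram) -> None:
    """NPZ (values, mask, noise) plus a .json geometry sidecar; mm/degree units."""
    path = Path(path)
    np.savez(path, values=sino.values, angle_mask=sino.angle_mask, noise_sigma=sino.noise_sigma)
    geo = dataclasses.asdict(sino.geometry)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(geo, fh, indent=2)


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    try:
        with open(path.with_suffix(".json")) as fh:
            geo = json.load(fh)
        geom = FanBeamGeometry(**{k: tuple(v) if k == "angles_deg" else v for k, v in geo.items()})
        with np.load(path) as d:
            return Sinogram(
                values=d["values"],
                geometry=geom,
                angle_mask=d["angle_mask"],
                noise_sigma=float(d["noise_sigma"]),
            )
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FileFormatError(f"cannot read sinogram {path}: {exc}") from exc


DEFAULT_RUN_CONFIG: dict = {
    "rng_seed": 0,
    "output_dir": "runs/demo",
    "phantom": {
        "n_patients": 2,
        "phase_start_pct": 20.0,
        "phase_end_pct": 80.0,
        "phase_step_pct": 3.0,
        "slices_per_phase": 1,
        "H": 64,
        "W": 64,
    },
    "geometry": {
        "n_views": 180,
        "n_detectors": 128,
        "detector_spacing_mm": 3.2,
        "source_to_iso_mm": 540.0,
        "source_to_detector_mm": 950.0,
        "rotation_time_ms": 350.0,
        "fov_mm": 220.0,
    },
    "recon": {
        "filter_name": "ram-lak",
        "angular_range_deg": 120.0,
        "start_angle_deg": 120.0,
        "sart_iterations": 10,
        "sart_relaxation": 1.0,
        "tv_iterations_per_sart": 20,
        "tv_step": 0.2,
    },
    "model": {"preset": "uswin1", "predict_residual": False},
    "train": {
        "batch_size": 1,
        "epochs": 100,
        "learning_rate": 1e-5,
        "max_steps": 0,
        "k_folds": 10,
        "checkpoint_every": 0,
    },
}


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _deep_update(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_run_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file, overlaid with explicit overrides."""
    cfg = DEFAULT_RUN_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        cfg = _deep_update(cfg, user)
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def save_run_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
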