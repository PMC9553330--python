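"""Image, mask, contour-label and manifest I/O.

Raster formats (PNG/TIFF) carry no physical spacing, so the dataset
manifest (CSV) is the single source of truth for pixel spacing of raster
inputs; NIfTI spacing comes from the header.  Masks are stored on disk as
8-bit {0, 255} PNG and normalized to {0, 1} in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage

from .exceptions import ParameterError, SchemaError
from .synthetic import AcquisitionProfile, Dataset, Sample

__all__ = [
    "ImageRecord",
    "read_image",
    "write_image",
    "make_contour_label",
    "save_manifest",
    "load_manifest",
    "write_mask_png",
    "read_mask_png",
]

_FORMATS = ("png", "tiff", "nifti")


@dataclass
class ImageRecord:
    pixels: np.ndarray
    spacing: float = 1.0
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.isfinite(self.pixels).all():
            raise ParameterError("image intensities must be finite")
        if self.spacing <= 0:
            raise ParameterError("spacing must be > 0")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise ParameterError(f"unknown format {format!r}; expected one of {_FORMATS}")
        return format
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return "nifti"
    if suffixes.endswith((".tif", ".tiff")):
        return "tiff"
    if suffixes.endswith(".png"):
        return "png"
    raise ParameterError(f"cannot infer image format from {path.name!r}")


def read_image(path, format: str | None = None, spacing: float | None = None) -> ImageRecord:
    """Read a 2D grayscale image; NIfTI spacing is taken from the header."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        if fmt == "nifti":
            img = nib.load(path)
            pixels = np.asarray(img.dataobj).squeeze()
            hdr_spacing = float(img.header.get_zooms()[0])
            return ImageRecord(pixels, spacing or hdr_spacing, str(path))
        if fmt == "tiff":
            pixels = tifffile.imread(path)
        else:
            pixels = np.asarray(Image.open(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise IOError(f"could not read image {path}: {exc}") from exc
    return ImageRecord(pixels, spacing or 1.0, str(path))


def write_image(record: ImageRecord, path, format: str | None = None) -> Path:
    """Write an image; PNG is 16-bit grayscale (values must fit uint16)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels = np.asarray(record.pixels)
    if fmt == "nifti":
        affine = np.diag([record.spacing, record.spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(pixels.astype(np.float32), affine), path)
    elif fmt == "tiff":
        tifffile.imwrite(path, pixels)
    else:
        arr = np.rint(pixels)
        if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
            raise ParameterError("PNG output requires values in [0, 65535]")
        Image.fromarray(arr.astype(np.uint16)).save(path)
    return path


def write_mask_png(mask: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)
    return path


def read_mask_png(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    return (np.asarray(Image.open(path)) > 0).astype(np.uint8)


def make_contour_label(mask: np.ndarray) -> np.ndarray:
    """Inner tumor boundary: mask pixels with an 8-neighbour outside the mask.

    The image edge counts as outside, so a mask touching the border keeps a
    contour there.  The contour is a subset of the mask by construction.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ParameterError("mask must be binary with values in {0, 1}")
    interior = ndimage.binary_erosion(
        mask.astype(bool), structure=np.ones((3, 3), bool), border_value=0
    )
    return (mask.astype(bool) & ~interior).astype(np.uint8)


_REQUIRED_COLUMNS = ("case_id", "class", "spacing", "mask_path")


def save_manifest(dataset: Dataset, out_dir, image_format: str = "png") -> Path:
    """Write per-case images and masks plus a manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in dataset:
        row = {
            "case_id": sample.case_id,
            "class": sample.ki67_class,
            "spacing": sample.spacing,
            "true_adc": sample.true_adc,
        }
        for b, img in zip(sample.b_values, sample.images):
            if image_format == "png":
                # 16-bit PNG: store a fixed-point scaling so reload is faithful
                name = f"{sample.case_id}_b{int(b)}.png"
                write_image(ImageRecord(img * 64.0, sample.spacing), out_dir / name)
            else:
                name = f"{sample.case_id}_b{int(b)}.nii.gz"
                write_image(ImageRecord(img, sample.spacing), out_dir / name)
            row[f"image_b{int(b)}"] = name
        row["mask_path"] = f"{sample.case_id}_mask.png"
        write_mask_png(sample.mask, out_dir / row["mask_path"])
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_manifest(path) -> Dataset:
    """Load a manifest CSV back into an in-memory :class:`Dataset`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    image_cols = sorted(
        (c for c in df.columns if c.startswith("image_b")),
        key=lambda c: float(c.removeprefix("image_b")),
    )
    if not image_cols:
        missing.append("image_b<...>")
    if missing:
        raise SchemaError(f"manifest missing required column(s): {', '.join(missing)}")

    b_values = tuple(float(c.removeprefix("image_b")) for c in image_cols)
    base = path.parent
    samples = []
    for row in df.to_dict("records"):
        try:
            images = []
            for col in image_cols:
                rec = read_image(base / row[col], spacing=float(row["spacing"]))
                px = rec.pixels.astype(np.float32)
                if str(row[col]).endswith(".png"):
                    px /= 64.0  # undo the fixed-point PNG scaling
                images.append(px)
            mask = read_mask_png(base / row["mask_path"])
        except IOError as exc:
            raise IOError(f"case {row['case_id']}: {exc}") from exc
        samples.append(
            Sample(
                case_id=str(row["case_id"]),
                images=tuple(images),
                mask=mask,
                b_values=b_values,
                spacing=float(row["spacing"]),
                ki67_class=str(row["class"]),
                true_adc=float(row.get("true_adc", 1e-3) or 1e-3),
            )
        )
    profile = AcquisitionProfile(
        b_values=b_values,
        matrix_size=max(32, samples[0].shape[0]),
        pixel_spacing_mm=samples[0].spacing,
    )
    return Dataset(samples=samples, seed=-1, profile=profile)
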