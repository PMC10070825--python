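"""Reading and writing slices, masks, manifests and reports.

Images travel as 8-bit grayscale PNG (unit spacing, with a warning) or as
NIfTI-1 with the (row_mm, col_mm) spacing carried in the header pixdim.
Masks are stored as integer-valued single-channel files: paletted PNG with
a fixed documented palette, or integer NIfTI.  A manifest CSV ties a
dataset together: one row per (subject, phase) with paths and spacing.
Colorized overlays are a separate optional writer, never the storage
format.
"""

from __future__ import annotations

import pathlib
import warnings

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .types import CLASS_NAMES, GrayscaleSlice, LabelMask

__all__ = ["read_slice", "write_slice", "read_mask", "write_mask",
           "write_dataset", "read_manifest_dataset", "MASK_PALETTE",
           "write_overlay_png"]

# fixed mask palette: index -> RGB (presentation only; indices are canonical)
MASK_PALETTE = {0: (0, 0, 0), 1: (220, 60, 60), 2: (60, 200, 60), 3: (60, 90, 220)}

PHASE_NAMES = {"first": "ED", "last": "ES"}


def _phase_name(phase_index: int, n_phases: int) -> str:
    if phase_index == 0:
        return "ED"
    if phase_index == n_phases - 1:
        return "ES"
    return "mid"


# ---------------------------------------------------------------------------
# slices

def write_slice(path, sl: GrayscaleSlice, fmt: str | None = None) -> None:
    path = pathlib.Path(path)
    fmt = fmt or ("nifti" if ".nii" in path.name else "png")
    if fmt == "png":
        p = sl.pixels
        lo, hi = float(p.min()), float(p.max())
        scaled = np.zeros_like(p) if hi - lo < 1e-12 else (p - lo) / (hi - lo) * 255
        Image.fromarray(scaled.astype(np.uint8), mode="L").save(path)
    elif fmt == "nifti":
        affine = np.diag([sl.spacing[0], sl.spacing[1], 1.0, 1.0])
        img = nib.Nifti1Image(sl.pixels[:, :, None].astype(np.float32), affine)
        img.header.set_zooms((sl.spacing[0], sl.spacing[1], 1.0))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown slice format {fmt!r}")


def read_slice(path, fmt: str | None = None, phase_index: int = 0,
               subject_id: str = "") -> GrayscaleSlice:
    """Load one slice; PNG gets unit spacing (warned), NIfTI header spacing.

    Intensities are returned as stored — no silent rescaling.
    """
    path = pathlib.Path(path)
    fmt = fmt or ("nifti" if ".nii" in path.name else "png")
    if fmt == "png":
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.float32)
        warnings.warn(f"{path.name}: PNG carries no pixel spacing; assuming 1 mm",
                      stacklevel=2)
        spacing = (1.0, 1.0)
    elif fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        nonsingleton = [i for i, s in enumerate(data.shape) if s > 1]
        if len(nonsingleton) > 2:
            raise ValueError(f"{path.name}: volume has more than one slice; "
                             "pass a 2D (or singleton-3rd-axis) image")
        arr = np.squeeze(data).astype(np.float32)
        zooms = img.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
    else:
        raise ValueError(f"unknown slice format {fmt!r}")
    return GrayscaleSlice(arr, spacing=spacing, phase_index=phase_index,
                          subject_id=subject_id)


# ---------------------------------------------------------------------------
# masks

def write_mask(path, mask: LabelMask, fmt: str | None = None,
               spacing: tuple[float, float] = (1.0, 1.0)) -> None:
    path = pathlib.Path(path)
    fmt = fmt or ("nifti" if ".nii" in path.name else "png")
    if fmt == "png":
        im = Image.fromarray(mask.labels, mode="P")
        palette = []
        for i in range(256):
            palette.extend(MASK_PALETTE.get(i, (0, 0, 0)))
        im.putpalette(palette)
        im.save(path)
    elif fmt == "nifti":
        affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
        img = nib.Nifti1Image(mask.labels[:, :, None].astype(np.uint8), affine)
        img.header.set_zooms((spacing[0], spacing[1], 1.0))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown mask format {fmt!r}")


def read_mask(path, fmt: str | None = None) -> LabelMask:
    """Load a mask, rejecting any label outside {0, 1, 2, 3}."""
    path = pathlib.Path(path)
    fmt = fmt or ("nifti" if ".nii" in path.name else "png")
    if fmt == "png":
        with Image.open(path) as im:
            if im.mode not in ("P", "L", "I", "I;16"):
                raise ValueError(f"{path.name}: not an integer-valued mask PNG")
            arr = np.asarray(im, dtype=np.int64)
    elif fmt == "nifti":
        arr = np.squeeze(np.asanyarray(nib.load(str(path)).dataobj))
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path.name}: mask voxels are not integers")
        arr = np.round(arr).astype(np.int64)
    else:
        raise ValueError(f"unknown mask format {fmt!r}")
    bad = np.setdiff1d(np.unique(arr), list(CLASS_NAMES))
    if bad.size:
        raise ValueError(f"{path.name}: out-of-alphabet label values {bad.tolist()}")
    return LabelMask(arr)


def write_overlay_png(path, mask: LabelMask) -> None:
    """Optional RGB visualization of a mask using the fixed palette."""
    rgb = np.zeros((*mask.shape, 3), dtype=np.uint8)
    for idx, color in MASK_PALETTE.items():
        rgb[mask.labels == idx] = color
    Image.fromarray(rgb, mode="RGB").save(path)


# ---------------------------------------------------------------------------
# datasets + manifests

MANIFEST_COLUMNS = ["subject_id", "phase_index", "phase_name", "image_path",
                    "mask_path", "spacing_row_mm", "spacing_col_mm"]


def write_dataset(dataset, out_dir, fmt: str = "nifti") -> pathlib.Path:
    """Write (slice, mask) pairs plus a manifest CSV; returns manifest path.

    Coordinate convention: row-major 0-based pixel indices; spacing columns
    are (row_mm, col_mm).
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if fmt == "nifti" else ".png"
    n_phases = 1 + max(sl.phase_index for sl, _ in dataset)
    rows = []
    for sl, mask in dataset:
        stem = f"{sl.subject_id}_phase{sl.phase_index}"
        img_path = out / f"{stem}_image{ext}"
        msk_path = out / f"{stem}_mask{ext}"
        write_slice(img_path, sl, fmt=fmt)
        write_mask(msk_path, mask, fmt=fmt, spacing=sl.spacing)
        rows.append({"subject_id": sl.subject_id, "phase_index": sl.phase_index,
                     "phase_name": _phase_name(sl.phase_index, n_phases),
                     "image_path": img_path.name, "mask_path": msk_path.name,
                     "spacing_row_mm": sl.spacing[0], "spacing_col_mm": sl.spacing[1]})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_manifest_dataset(manifest_path, with_masks: bool = True):
    """Load a dataset back from its manifest; returns (slice, mask|None) pairs."""
    manifest_path = pathlib.Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    dup = df.duplicated(subset=["subject_id", "phase_index"])
    if dup.any():
        raise ValueError("manifest has duplicate (subject_id, phase_index) rows")
    pairs = []
    for _, row in df.iterrows():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # PNG spacing warning handled here
            sl = read_slice(base / row["image_path"],
                            phase_index=int(row["phase_index"]),
                            subject_id=str(row["subject_id"]))
        sl.spacing = (float(row["spacing_row_mm"]), float(row["spacing_col_mm"]))
        mask = None
        if with_masks and isinstance(row.get("mask_path"), str) and row["mask_path"]:
            mask = read_mask(base / row["mask_path"])
            if mask.shape != sl.shape:
                raise ValueError(f"{row['mask_path']}: mask shape {mask.shape} "
                                 f"does not match image {sl.shape}")
        pairs.append((sl, mask))
    return pairs
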