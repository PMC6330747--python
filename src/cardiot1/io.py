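"""Reading and writing image stacks, masks and maps.

A slice stack is eleven T1-weighted images with their inversion times.
On disk: NIfTI (one 3-D file per slice, inversion times in a JSON sidecar
because NIfTI has no TI field) or a DICOM series (InversionTime tag).
Masks travel as 16-bit PNG or NIfTI; T1 maps as float32 NIfTI in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math
import os

import numpy as np
import nibabel as nib
import pydicom
from PIL import Image

__all__ = [
    "T1wStack",
    "write_stack_nifti",
    "read_stack_nifti",
    "read_stack_dicom",
    "read_stack",
    "write_mask_png",
    "read_mask_png",
    "write_t1_map_nifti",
    "pad_or_crop",
]

#: JSON has no infinity literal; the sidecar stores the infinite TI as this.
_INF_TOKEN = "inf"


@dataclass
class T1wStack:
    """Eleven T1-weighted images of one slice, TI-sorted (infinite TI last)."""

    images: np.ndarray          # float (K, H, W)
    tis: list[float]            # ms; math.inf allowed
    pixel_spacing: float = 2.1  # mm

    def __post_init__(self):
        if self.images.shape[0] != len(self.tis):
            raise ValueError("one TI per image required")

    def sorted_by_ti(self) -> "T1wStack":
        order = np.argsort(self.tis)   # inf sorts last
        return T1wStack(images=self.images[order],
                        tis=[self.tis[i] for i in order],
                        pixel_spacing=self.pixel_spacing)


def pad_or_crop(image: np.ndarray, size: int = 256) -> np.ndarray:
    """Unify matrix size: symmetric zero-padding, centred cropping."""
    h, w = image.shape
    out = image
    if h < size:
        top = (size - h) // 2
        out = np.pad(out, ((top, size - h - top), (0, 0)))
    elif h > size:
        top = (h - size) // 2
        out = out[top:top + size, :]
    h2, w2 = out.shape
    if w2 < size:
        left = (size - w2) // 2
        out = np.pad(out, ((0, 0), (left, size - w2 - left)))
    elif w2 > size:
        left = (w2 - size) // 2
        out = out[:, left:left + size]
    return out


def _ti_to_json(ti: float):
    return _INF_TOKEN if math.isinf(ti) else ti


def _ti_from_json(v) -> float:
    return math.inf if v == _INF_TOKEN else float(v)


def write_stack_nifti(stack: T1wStack, path: str) -> None:
    """One 3-D NIfTI (H, W, K) plus a ``<path>.json`` TI sidecar."""
    affine = np.diag([stack.pixel_spacing, stack.pixel_spacing, 1.0, 1.0])
    data = np.moveaxis(stack.images, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), path)
    sidecar = {"inversion_times_ms": [_ti_to_json(t) for t in stack.tis],
               "pixel_spacing_mm": stack.pixel_spacing}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_stack_nifti(path: str, target_size: int = 256) -> T1wStack:
    sidecar_path = str(path) + ".json"
    if not os.path.exists(sidecar_path):
        raise FileNotFoundError(
            f"missing TI sidecar for {path}: expected {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    tis = [_ti_from_json(v) for v in sidecar["inversion_times_ms"]]
    img = nib.load(path)
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    spacing = float(sidecar.get("pixel_spacing_mm",
                                abs(img.affine[0, 0]) or 2.1))
    images = np.stack([pad_or_crop(d, target_size) for d in data])
    return T1wStack(images=images, tis=tis,
                    pixel_spacing=spacing).sorted_by_ti()


def read_stack_dicom(directory: str, target_size: int = 256) -> T1wStack:
    """Read a DICOM series; TI from the InversionTime tag, any file order."""
    files = sorted(os.listdir(directory))
    images, tis, spacing = [], [], 2.1
    missing = []
    for f in files:
        p = os.path.join(directory, f)
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        ti = getattr(ds, "InversionTime", None)
        if ti is None:
            missing.append(f)
            continue
        ti = float(ti)
        # the effectively infinite TI is conventionally stored as a huge value
        if ti >= 1e5:
            ti = math.inf
        images.append(pad_or_crop(ds.pixel_array.astype(float), target_size))
        tis.append(ti)
        if getattr(ds, "PixelSpacing", None) is not None:
            spacing = float(ds.PixelSpacing[0])
    if missing:
        raise ValueError(f"files without InversionTime metadata: {missing}")
    if not images:
        raise ValueError(f"no readable DICOM images in {directory}")
    return T1wStack(images=np.stack(images), tis=tis,
                    pixel_spacing=spacing).sorted_by_ti()


def read_stack(path: str, fmt: str = "nifti", target_size: int = 256) -> T1wStack:
    """Dispatch on format: 'nifti' (file + sidecar) or 'dicom' (directory)."""
    if fmt == "nifti":
        return read_stack_nifti(path, target_size)
    if fmt == "dicom":
        return read_stack_dicom(path, target_size)
    raise ValueError(f"unknown stack format: {fmt!r}")


def write_mask_png(mask: np.ndarray, path: str) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint16(65535))
    Image.fromarray(arr, mode="I;16").save(path)


def read_mask_png(path: str) -> np.ndarray:
    return np.asarray(Image.open(path)) > 0


def write_t1_map_nifti(values: np.ndarray, path: str,
                       pixel_spacing: float = 2.1) -> None:
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(values.astype(np.float32), affine), path)
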