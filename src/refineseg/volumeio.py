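"""NIfTI volume reading/writing and run manifests.

NIfTI (.nii / .nii.gz) is the only on-disk volume format; users convert
DICOM series upstream.  The slice axis is the volume's third axis (the
axial axis); orientation metadata is carried through unchanged, never
reinterpreted.  Internally volumes are handled as (slices, H, W), i.e. the
NIfTI array transposed so the axial axis leads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np


class VolumeFormatError(ValueError):
    """Raised for unreadable or non-3-D volume files."""


@dataclass
class VolumeRecord:
    """Manifest entry tying an image file to its label file."""

    image_path: str
    label_path: str | None
    patient_id: str
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    """Read a NIfTI volume as (slices, H, W).

    Returns ``(array, spacing, affine)`` where ``spacing`` is ordered like
    the returned array axes (slice, row, column).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3-D volume, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    # axis 2 is axial in our convention; lead with it
    array = np.ascontiguousarray(np.moveaxis(data, 2, 0))
    spacing = (float(zooms[2]), float(zooms[0]), float(zooms[1]))
    return array, spacing, img.affine


def _to_disk_order(volume: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.moveaxis(volume, 0, 2))


def write_image(volume: np.ndarray, affine: np.ndarray, path,
                spacing: tuple[float, float, float] | None = None) -> None:
    """Write a float volume given in (slices, H, W) order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(_to_disk_order(np.asarray(volume,
                                                    dtype=np.float32)),
                          affine)
    if spacing is not None:
        img.header.set_zooms((spacing[1], spacing[2], spacing[0]))
    nib.save(img, str(path))


def write_labels(labels: np.ndarray, affine: np.ndarray, path,
                 reference_shape: tuple[int, int, int] | None = None,
                 spacing: tuple[float, float, float] | None = None) -> None:
    """Write an integer label volume aligned with its reference grid."""
    labels = np.asarray(labels)
    if reference_shape is not None and labels.shape != tuple(reference_shape):
        raise ValueError(f"label shape {labels.shape} does not match "
                         f"reference {tuple(reference_shape)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(_to_disk_order(labels.astype(np.int16)), affine)
    if spacing is not None:
        img.header.set_zooms((spacing[1], spacing[2], spacing[0]))
    nib.save(img, str(path))


def spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    """Diagonal affine for a (slice, row, col) spacing triple."""
    return np.diag([spacing[1], spacing[2], spacing[0], 1.0])


def write_manifest(records: list[VolumeRecord], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps([asdict(r) for r in records], indent=2))


def read_manifest(path) -> list[VolumeRecord]:
    entries = json.loads(Path(path).read_text())
    return [VolumeRecord(image_path=e["image_path"],
                         label_path=e.get("label_path"),
                         patient_id=e["patient_id"],
                         spacing=tuple(e["spacing"]),
                         shape=tuple(e["shape"])) for e in entries]
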