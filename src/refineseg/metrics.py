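"""Dice and Hausdorff evaluation of stacked 3-D label volumes.

Evaluation follows the usual organ-at-risk protocol: 2-D per-slice
predictions are mapped back to the original slice geometry, stacked into a
3-D volume in acquisition order, and compared with the ground-truth volume
per organ by the dice overlap coefficient and the (full, symmetric)
Hausdorff distance between boundary voxel sets.  Per-organ results are
aggregated over patients as mean and population variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)


def stack_slices(per_slice_labels: list[np.ndarray]) -> np.ndarray:
    """Stack ordered 2-D label masks into a (slices, H, W) volume."""
    if not per_slice_labels:
        raise ValueError("no slices to stack")
    shapes = {np.asarray(s).shape for s in per_slice_labels}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    return np.stack([np.asarray(s) for s in per_slice_labels], axis=0)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """``2 |A∩B| / (|A| + |B|)``; defined as 1.0 when both are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / size


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of boundary voxels (mask minus its erosion)."""
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(a: np.ndarray, b: np.ndarray,
              spacing: tuple[float, ...] | None = None) -> float:
    """Symmetric Hausdorff distance between the boundary voxel sets.

    Distances are Euclidean in voxel units unless ``spacing`` scales each
    axis.  Raises ``ValueError`` if either mask is empty (the distance is
    undefined); callers report such organs as missing.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance is undefined for empty masks")
    pa = _surface_voxels(a).astype(float)
    pb = _surface_voxels(b).astype(float)
    if spacing is not None:
        s = np.asarray(spacing, dtype=float)
        if s.shape != (a.ndim,) or np.any(s <= 0):
            raise ValueError("spacing must give one positive value per axis")
        pa = pa * s
        pb = pb * s
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def boundary_mass_fraction(uncertainty: np.ndarray, labels: np.ndarray,
                           radius: float = 3.0) -> float:
    """Fraction of uncertainty mass within ``radius`` pixels of a label
    boundary, computed slice-wise.

    A boundary pixel is one whose predicted label differs from a 4-connected
    neighbour.  Returns NaN when the volume has no boundary or no
    uncertainty mass.
    """
    uncertainty = np.asarray(uncertainty, dtype=float)
    labels = np.asarray(labels)
    if uncertainty.shape != labels.shape:
        raise ValueError("uncertainty / labels shape mismatch")
    if uncertainty.ndim == 2:
        uncertainty = uncertainty[None]
        labels = labels[None]
    total = float(uncertainty.sum())
    if total <= 0:
        return float("nan")
    near = 0.0
    any_boundary = False
    for unc_s, lab_s in zip(uncertainty, labels):
        boundary = np.zeros_like(lab_s, dtype=bool)
        boundary[:-1, :] |= lab_s[:-1, :] != lab_s[1:, :]
        boundary[1:, :] |= lab_s[1:, :] != lab_s[:-1, :]
        boundary[:, :-1] |= lab_s[:, :-1] != lab_s[:, 1:]
        boundary[:, 1:] |= lab_s[:, 1:] != lab_s[:, :-1]
        if not boundary.any():
            continue
        any_boundary = True
        dist = ndimage.distance_transform_edt(~boundary)
        near += float(unc_s[dist <= radius].sum())
    if not any_boundary:
        return float("nan")
    return near / total


@dataclass
class OrganScore:
    """Per-organ aggregate over patients (population variance)."""

    organ: int
    dice: float
    dice_variance: float
    hd: float | None
    hd_variance: float | None
    per_patient_dice: list[float] = field(default_factory=list)
    per_patient_hd: list[float] = field(default_factory=list)
    n_patients: int = 0


def score_patients(preds: list[np.ndarray], gts: list[np.ndarray],
                   organ_ids: list[int],
                   spacing: tuple[float, ...] | None = None
                   ) -> list[OrganScore]:
    """Per-organ mean dice/HD across patients, with variance.

    Patients whose ground truth lacks an organ are excluded from that
    organ's aggregate (logged).  Patients where the HD is undefined (empty
    prediction) contribute dice but no HD.
    """
    if len(preds) != len(gts):
        raise ValueError("prediction / ground-truth patient lists differ")
    scores = []
    for organ in organ_ids:
        dices: list[float] = []
        hds: list[float] = []
        for idx, (pred, gt) in enumerate(zip(preds, gts)):
            gt_bin = np.asarray(gt) == organ
            if not gt_bin.any():
                log.warning("organ %d absent from ground truth of patient %d;"
                            " excluded", organ, idx)
                continue
            pred_bin = np.asarray(pred) == organ
            dices.append(dice_coefficient(pred_bin, gt_bin))
            try:
                hds.append(hausdorff(pred_bin, gt_bin, spacing))
            except ValueError:
                log.warning("HD undefined for organ %d, patient %d "
                            "(empty prediction)", organ, idx)
        if not dices:
            scores.append(OrganScore(organ, float("nan"), float("nan"),
                                     None, None, [], [], 0))
            continue
        dice_arr = np.asarray(dices)
        hd_arr = np.asarray(hds) if hds else None
        scores.append(OrganScore(
            organ=organ,
            dice=float(dice_arr.mean()),
            dice_variance=float(dice_arr.var()),
            hd=float(hd_arr.mean()) if hd_arr is not None else None,
            hd_variance=float(hd_arr.var()) if hd_arr is not None else None,
            per_patient_dice=[float(d) for d in dices],
            per_patient_hd=[float(h) for h in hds],
            n_patients=len(dices),
        ))
    return scores


def scores_to_rows(scores: list[OrganScore]) -> list[dict]:
    """Flatten OrganScores for CSV writing (per-organ mean/variance rows)."""
    rows = []
    for s in scores:
        rows.append({
            "organ": s.organ,
            "dice": s.dice,
            "dice_variance": s.dice_variance,
            "hd": s.hd if s.hd is not None else "",
            "hd_variance": s.hd_variance if s.hd_variance is not None else "",
            "n_patients": s.n_patients,
        })
    return rows
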