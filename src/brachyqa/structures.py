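"""Voxelized structure sets for brachytherapy planning geometry.

A :class:`StructureSet` holds binary masks for the high-risk clinical
target volume (HR-CTV) and the organs at risk (OARs) on one shared voxel
lattice with physical spacing.  Masks round-trip through NIfTI label
volumes plus a JSON name-to-label map; an optional adapter rasterizes
DICOM RTSTRUCT planar contours onto a lattice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: canonical structure names used throughout the package
HRCTV = "hrctv"
OAR_NAMES = ("bladder", "rectum", "sigmoid_colon", "small_intestine")


class StructureError(ValueError):
    """Invalid structure geometry (empty target, overlap, lattice mismatch)."""


@dataclass
class StructureSet:
    """Named binary masks on a shared lattice.

    Parameters
    ----------
    masks
        Mapping of structure name to 3D boolean array.  Must contain
        ``"hrctv"``; OARs are optional but, when present, must be disjoint
        from the HR-CTV.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, all positive.
    origin
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise StructureError(f"spacing must be 3 positive values, got {self.spacing}")
        if HRCTV not in self.masks:
            raise StructureError("structure set must contain an 'hrctv' mask")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise StructureError(f"masks live on different lattices: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        hrctv = self.masks[HRCTV]
        if not hrctv.any():
            raise StructureError("empty structure: hrctv")
        for name, mask in self.masks.items():
            if name != HRCTV and np.logical_and(mask, hrctv).any():
                raise StructureError(f"structure '{name}' overlaps the HR-CTV")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.masks[HRCTV].shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def volume_cm3(self, name: str) -> float:
        """Total volume of a structure in cm^3."""
        if name not in self.masks:
            raise KeyError(f"unknown structure '{name}'")
        return float(self.masks[name].sum()) * self.voxel_volume_cm3

    def organ_names(self) -> list[str]:
        return [n for n in self.masks if n != HRCTV]


# ---------------------------------------------------------------------------
# NIfTI label-volume round trip


def save_structures(structures: StructureSet, nifti_path: str | Path) -> None:
    """Write masks as one NIfTI integer label volume plus a JSON label map.

    Overlapping structures cannot be represented in a single label volume;
    the ``StructureSet`` invariants guarantee the HR-CTV is disjoint from
    every OAR, and OAR/OAR overlaps are resolved in favor of the later name
    (the generator never produces them).
    """
    import nibabel as nib

    nifti_path = Path(nifti_path)
    labels = np.zeros(structures.shape, dtype=np.int16)
    label_map: dict[str, int] = {}
    for i, (name, mask) in enumerate(structures.masks.items(), start=1):
        labels[mask] = i
        label_map[name] = i
    affine = np.diag(list(structures.spacing) + [1.0])
    affine[:3, 3] = structures.origin
    nib.save(nib.Nifti1Image(labels, affine), nifti_path)
    json_path = nifti_path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    json_path = Path(str(json_path) + ".labels.json")
    json_path.write_text(json.dumps(label_map, indent=1))


def load_structures(nifti_path: str | Path) -> StructureSet:
    """Inverse of :func:`save_structures`."""
    import nibabel as nib

    nifti_path = Path(nifti_path)
    img = nib.load(nifti_path)
    labels = np.asarray(img.dataobj)
    json_path = Path(str(nifti_path.with_suffix("").with_suffix("")) + ".labels.json")
    label_map = json.loads(json_path.read_text())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    masks = {name: labels == lab for name, lab in label_map.items()}
    return StructureSet(masks=masks, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# Planar-contour rasterization (DICOM RTSTRUCT adapter)


def rasterize_contours(
    contours: Iterable[np.ndarray],
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Rasterize planar polygons (even-odd rule) into a boolean mask.

    Each contour is an (n, 3) array of physical points (mm) lying on one
    axial plane (constant z).  Points are assigned to the nearest slice;
    a voxel is inside if its center is inside the polygon.  Multiple
    polygons on one slice combine by the even-odd (XOR) rule, so holes
    and islands behave as in a treatment planning system.
    """
    from matplotlib.path import Path as MplPath

    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    for contour in contours:
        contour = np.asarray(contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 3 or len(contour) < 3:
            raise StructureError("contour must be an (n>=3, 3) array of points")
        z = contour[:, 2]
        if np.ptp(z) > 1e-6:
            raise StructureError("contour is not planar (z varies)")
        k = int(round((z[0] - origin[2]) / spacing[2]))
        if not 0 <= k < shape[2]:
            continue
        inside = MplPath(contour[:, :2]).contains_points(pts).reshape(shape[:2])
        mask[:, :, k] ^= inside
    return mask


def rtstruct_to_masks(
    rtstruct_path: str | Path,
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    name_map: Mapping[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Convert a DICOM RTSTRUCT file to boolean masks on the given lattice.

    ``name_map`` renames ROI names (e.g. ``{"Bladder": "bladder"}``);
    unmapped ROIs keep their RTSTRUCT name lower-cased with spaces as
    underscores.
    """
    import pydicom

    ds = pydicom.dcmread(str(rtstruct_path))
    roi_names = {
        roi.ROINumber: roi.ROIName for roi in ds.StructureSetROISequence
    }
    masks: dict[str, np.ndarray] = {}
    for roi_contour in ds.ROIContourSequence:
        raw = roi_names.get(roi_contour.ReferencedROINumber, "")
        name = (name_map or {}).get(raw, raw.lower().replace(" ", "_"))
        contours = []
        for c in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append(pts)
        masks[name] = rasterize_contours(contours, shape, spacing, origin)
    return masks
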