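"""Mean gray-matter volume per ROI from probability maps and label masks.

Inputs are voxelwise gray-matter probability images (values in [0, 1] after
segmentation and modulation — produced upstream, consumed here) plus an
integer atlas label image on the same grid.  A region's "volume" is the
mean of the voxel intensities that lie inside the region's labels and
exceed a cut-off (default 0.15), i.e. the average over surviving voxels
only.  An ``all_roi`` mode that averages sub-threshold voxels as zeros over
the whole region is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import RoiSpec

__all__ = ["GmImage", "RoiMask", "extract_mean_gm", "extract_cohort_volumes"]

DEFAULT_THRESHOLD = 0.15


@dataclass(frozen=True)
class GmImage:
    """A 3-D gray-matter probability map plus its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "data", arr)
        aff = (
            np.asarray(self.affine, dtype=float)
            if self.affine is not None
            else np.eye(4)
        )
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_file(cls, path) -> "GmImage":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine)

    def to_file(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


@dataclass(frozen=True)
class RoiMask:
    """Integer label image on the same grid as the data it masks."""

    labels: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            arr = np.rint(arr).astype(int)
        if arr.min() < 0:
            raise ValueError("mask labels must be >= 0")
        object.__setattr__(self, "labels", arr)
        aff = (
            np.asarray(self.affine, dtype=float)
            if self.affine is not None
            else np.eye(4)
        )
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_file(cls, path) -> "RoiMask":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), img.affine)

    def to_file(self, path) -> None:
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(self.labels.astype(np.int16), self.affine), str(path)
        )

    def roi_voxels(self, roi: RoiSpec) -> np.ndarray:
        """Boolean array selecting the ROI's voxels; warns if a declared
        atlas label is absent from the image."""
        present = set(np.unique(self.labels))
        missing = [v for v in roi.atlas_labels if v not in present]
        if missing:
            warnings.warn(
                f"ROI {roi.abbreviation!r}: atlas label(s) {missing} absent "
                "from the mask image",
                RuntimeWarning,
                stacklevel=2,
            )
        return np.isin(self.labels, roi.atlas_labels)


def extract_mean_gm(
    image: GmImage,
    mask: RoiMask,
    roi: RoiSpec,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "surviving",
) -> float:
    """Mean gray-matter probability of one ROI in one subject.

    Voxels inside the ROI's labels with intensity strictly above
    *threshold* survive; the default returns their mean, NaN if none
    survive (flagged missing, never silently 0).  ``mode="all_roi"``
    instead zeroes sub-threshold voxels and averages over every ROI voxel.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in ("surviving", "all_roi"):
        raise ValueError(f"unknown mode {mode!r}")
    if image.data.shape != mask.labels.shape:
        raise ValueError(
            f"grid mismatch: image {image.data.shape} vs mask {mask.labels.shape}"
        )
    inside = mask.roi_voxels(roi)
    vals = image.data[inside]
    surviving = vals[vals > threshold]
    if mode == "all_roi":
        if vals.size == 0:
            return float("nan")
        return float(surviving.sum() / vals.size)
    if surviving.size == 0:
        return float("nan")
    return float(surviving.mean())


def extract_cohort_volumes(
    images: Mapping[str, GmImage],
    mask: RoiMask,
    rois: Sequence[RoiSpec],
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "surviving",
    subjects: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-subject x per-ROI mean volumes.

    Returns a DataFrame indexed by subject id with one column per ROI
    abbreviation.  Subjects with any empty ROI get NaN in that cell and are
    listed in ``df.attrs["flagged_subjects"]`` rather than dropped.  When an
    expected *subjects* list is given, subjects without an image raise.
    """
    if subjects is not None:
        missing = [s for s in subjects if s not in images]
        if missing:
            raise ValueError(f"missing image(s) for subject(s): {missing}")
        images = {s: images[s] for s in subjects}
    rows = {}
    for sid, img in images.items():
        rows[sid] = {
            roi.abbreviation: extract_mean_gm(img, mask, roi, threshold, mode)
            for roi in rois
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=[r.abbreviation for r in rois])
    df.index.name = "subject_id"
    flagged = sorted(df.index[df.isna().any(axis=1)]) if len(df) else []
    df.attrs["flagged_subjects"] = flagged
    return df
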