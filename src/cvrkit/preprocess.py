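"""Minimal BOLD preprocessing: spatial smoothing, brain masking, mean time courses.

The pipeline consumes motion-corrected series; realignment itself is standard
upstream work and is not redone here. The brain mask is intensity-based
(threshold on the smoothed temporal mean, largest connected component, hole
filling) — for whole-brain averaging and relative normalization only the
brain/background split matters — and a user-supplied mask on the BOLD grid
always takes precedence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import MaskError
from .io_formats import ImageVolume4D

__all__ = ["BrainMask", "MeanTimecourse", "gaussian_smooth", "compute_brain_mask",
           "mean_timecourse"]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class BrainMask:
    """Boolean 3D mask on the BOLD grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise MaskError(f"mask must be 3D, got {self.mask.ndim}D")
        if not self.mask.any():
            raise MaskError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class MeanTimecourse:
    """Spatially averaged BOLD signal for one region (whole brain or an ROI)."""

    values: np.ndarray
    tr: float
    region: str = "whole-brain"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise MaskError("time course must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise MaskError(f"time course for {self.region} contains non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr


def gaussian_smooth(img: ImageVolume4D, fwhm_mm: float = 8.0) -> ImageVolume4D:
    """Per-frame 3D Gaussian smoothing with the kernel size given as FWHM in mm.

    sigma (voxels) = FWHM / sqrt(8 ln 2) / voxel size, per axis; reflective
    boundaries so the mean image is not darkened at the edges. ``fwhm_mm=0``
    returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return img
    sigma_vox = tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in img.voxel_size)
    smoothed = ndimage.gaussian_filter(img.data, sigma=(*sigma_vox, 0.0), mode="reflect")
    return ImageVolume4D(data=smoothed, voxel_size=img.voxel_size, tr=img.tr,
                         affine=img.affine)


def compute_brain_mask(img: ImageVolume4D, threshold_frac: float = 0.5) -> BrainMask:
    """Threshold-based brain mask from the temporal-mean image.

    Threshold at ``threshold_frac`` of the robust maximum (98th percentile),
    keep the largest connected component, fill holes. Raises if the result
    is empty or covers the full grid (no brain/background contrast).
    """
    mean_img = img.data.mean(axis=3)
    robust_max = np.percentile(mean_img, 98)
    if robust_max <= 0:
        raise MaskError("mean image has no positive signal; cannot build a mask")
    mask = mean_img >= threshold_frac * robust_max
    if not mask.any() or mask.all():
        raise MaskError("mask empty or full: no brain/background intensity contrast")
    labels, n_labels = ndimage.label(mask)
    if n_labels > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_labels + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    return BrainMask(mask=mask)


def mean_timecourse(img: ImageVolume4D, mask: BrainMask,
                    region: str = "whole-brain") -> MeanTimecourse:
    """Per-frame arithmetic mean of the series over the mask voxels."""
    if mask.mask.shape != img.shape3d:
        raise MaskError(f"mask grid {mask.mask.shape} != image grid {img.shape3d}")
    values = img.data[mask.mask].mean(axis=0)
    return MeanTimecourse(values=values, tr=img.tr, region=region)
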