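"""Resting-state relative CVR mapping.

Without a gas challenge, spontaneous CO2 fluctuations still modulate the
BOLD signal at low frequencies. The whole-brain BOLD time course — linearly
detrended, low-pass filtered to [0, 0.1164] Hz, and rescaled to zero mean
and 2-norm sqrt(N)/2 — serves as a surrogate "reference signal" replacing
the EtCO2 regressor. Each voxel is regressed on

    reference + 6 motion covariates + linear trend + intercept,

and RS-CVR = 100 * beta1 / beta0. Because no mmHg scaling exists, only the
map divided by its in-mask mean (relative CVR) is reported; the reference-
signal normalization makes beta1 comparable across runs of different
lengths, and beta0 carries the baseline signal level so the ratio is a
percent fluctuation amplitude.

The low-pass filter is an ideal frequency-domain projection (rFFT bins at
or below the cutoff kept, all higher bins zeroed), which is exactly
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import drift_regressor
from .exceptions import ModelError
from .io_formats import ImageVolume4D, MotionParams
from .preprocess import BrainMask, MeanTimecourse, mean_timecourse
from .cvr_co2 import relative_map

__all__ = ["ReferenceSignal", "RsGlmFit", "lowpass", "build_reference",
           "rs_glm_voxel", "rs_cvr_map", "CUTOFF_HZ"]

CUTOFF_HZ = 0.1164


@dataclass
class ReferenceSignal:
    """Surrogate CO2 regressor: zero mean, 2-norm sqrt(N)/2."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.size
        if abs(self.values.mean()) > 1e-10:
            raise ModelError("reference signal mean deviates from 0")
        if abs(np.linalg.norm(self.values) - np.sqrt(n) / 2.0) > 1e-10:
            raise ModelError("reference signal 2-norm deviates from sqrt(N)/2")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


@dataclass
class RsGlmFit:
    beta1: float
    beta2: np.ndarray | None  # 6 motion coefficients, when motion supplied
    beta3: float              # linear-trend coefficient
    beta0: float              # intercept (baseline signal level)
    rs_cvr: float             # 100 * beta1 / beta0


def lowpass(values: np.ndarray, tr: float, cutoff_hz: float = CUTOFF_HZ) -> np.ndarray:
    """Ideal low-pass: keep rFFT bins with frequency <= cutoff (inclusive)."""
    values = np.asarray(values, dtype=float)
    spectrum = np.fft.rfft(values)
    freqs = np.fft.rfftfreq(values.size, d=tr)
    spectrum[freqs > cutoff_hz] = 0.0
    return np.fft.irfft(spectrum, n=values.size)


def build_reference(bold_wb: MeanTimecourse, cutoff_hz: float = CUTOFF_HZ) -> ReferenceSignal:
    """Detrend, low-pass, and rescale the whole-brain time course.

    Raises when the filtered signal is (numerically) zero — e.g. a constant
    input, or a series with no power below the cutoff.
    """
    n = bold_wb.n_frames
    if n < 16:
        raise ModelError(f"need at least 16 frames to build a reference, got {n}")
    y = bold_wb.values
    X = np.column_stack([np.ones(n), drift_regressor(n)])
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    resid_norm = np.linalg.norm(resid)
    if resid_norm <= 1e-10 * max(np.abs(y).max(), 1.0):
        raise ModelError("whole-brain signal is constant after detrending; "
                         "cannot build a reference signal")
    filtered = lowpass(resid, bold_wb.tr, cutoff_hz)
    centered = filtered - filtered.mean()
    norm = np.linalg.norm(centered)
    # a real resting series keeps most of its variance below ~0.1 Hz; when
    # less than 0.01% survives the filter the band is effectively empty
    if norm <= 1e-2 * resid_norm:
        raise ModelError(
            "whole-brain signal has no power below the low-pass cutoff; "
            "cannot build a reference signal"
        )
    s0 = centered * (np.sqrt(n) / 2.0) / norm
    s0 = s0 - s0.mean()  # remove rounding residue so invariants hold to 1e-10
    return ReferenceSignal(values=s0, tr=bold_wb.tr)


def _rs_design(
    reference: ReferenceSignal, motion: MotionParams | None
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix plus the indices of the motion columns actually used.

    Motion columns are zero-meaned; all-constant columns (e.g. a run with no
    rotation about one axis) carry no information and are dropped to keep
    the design full rank.
    """
    n = reference.n_frames
    cols = [reference.values]
    kept = np.array([], dtype=int)
    if motion is not None:
        if motion.n_frames != n:
            raise ModelError(
                f"motion parameters have {motion.n_frames} rows but the series has "
                f"{n} frames"
            )
        centered = motion.values - motion.values.mean(axis=0)
        kept = np.flatnonzero(np.ptp(centered, axis=0) > 0)
        cols.extend(centered[:, j] for j in kept)
    cols.append(drift_regressor(n))
    cols.append(np.ones(n))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("rank-deficient design (collinear motion/trend covariates)")
    return X, kept


def rs_glm_voxel(
    voxel: np.ndarray, reference: ReferenceSignal, motion: MotionParams | None = None
) -> RsGlmFit:
    """Fit one voxel's series on [reference, motion, trend, intercept].

    Motion columns are zero-meaned so the intercept keeps its baseline-
    signal meaning; RS-CVR = 100*beta1/beta0, NaN when beta0 ~ 0.
    """
    y = np.asarray(voxel, dtype=float)
    if y.size != reference.n_frames:
        raise ModelError(f"voxel series length {y.size} != reference {reference.n_frames}")
    X, kept = _rs_design(reference, motion)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    beta1 = float(beta[0])
    if motion is not None:
        beta2 = np.zeros(6)
        beta2[kept] = beta[1:1 + kept.size]
    else:
        beta2 = None
    beta3 = float(beta[-2])
    beta0 = float(beta[-1])
    rs = 100.0 * beta1 / beta0 if abs(beta0) > 1e-9 * max(abs(y).max(), 1.0) else float("nan")
    return RsGlmFit(beta1=beta1, beta2=beta2, beta3=beta3, beta0=beta0, rs_cvr=rs)


def rs_cvr_map(
    img: ImageVolume4D,
    mask: BrainMask,
    motion: MotionParams | None = None,
    parcellation: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame | None, ReferenceSignal]:
    """Relative RS-CVR map (in-mask mean 1) and optional per-ROI means.

    The reference is built from the whole-brain mean of ``img`` (which
    should already be spatially smoothed), every in-mask voxel is fitted,
    and the RS-CVR map is divided by its in-mask mean.
    """
    wb = mean_timecourse(img, mask)
    reference = build_reference(wb)
    X, _ = _rs_design(reference, motion)
    Y = img.data[mask.mask].T  # (n_frames, n_voxels)
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    beta1 = beta[0]
    beta0 = beta[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = 100.0 * beta1 / beta0
    rs[np.abs(beta0) <= 1e-9 * np.maximum(np.abs(Y).max(axis=0), 1.0)] = np.nan
    raw = np.full(img.shape3d, np.nan)
    raw[mask.mask] = rs
    rel = relative_map(raw, mask)

    roi_table: pd.DataFrame | None = None
    if parcellation is not None:
        labels = np.asarray(np.rint(parcellation), dtype=int)
        if labels.shape != img.shape3d:
            raise ModelError(
                f"parcellation grid {labels.shape} != image grid {img.shape3d}"
            )
        rows = []
        for roi in np.unique(labels[labels > 0]):
            sel = labels == roi
            rows.append({
                "roi_id": int(roi),
                "n_voxels": int(sel.sum()),
                "relative_rscvr": float(np.nanmean(rel[sel])),
            })
        roi_table = pd.DataFrame(rows)
    return rel, roi_table, reference
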