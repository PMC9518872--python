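"""CO2-challenge CVR quantification: whole-brain, regional, voxel-wise.

CVR is expressed as percent BOLD signal change per mmHg of EtCO2 change,
referenced to the baseline (room-air) signal level. From the alignment GLM
coefficients,

    CVR = beta1 / (beta0 - beta1 * (mean(EtCO2) - baseline(EtCO2))) * 100,

where the denominator reconstructs the signal at baseline EtCO2 from the
fit of the zero-meaned regressor (beta0 is the signal at *mean* EtCO2).

Whole-brain CVR uses the globally aligned EtCO2; regional CVR re-runs the
full two-step alignment per ROI (white matter lags gray matter, so one
global shift would bias late regions); voxel-wise maps come in two
flavours — a global-shift map, and a voxel-shift map where each voxel's
regressor is additionally shifted within -5..+30 s of the global optimum,
which also yields a temporal shift map analogous to a bolus-arrival-time
map. Relative maps divide by the in-mask mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignmentResult, align, drift_regressor, glm_fit, resample_regressor
from .capnogram import EtCo2Curve
from .exceptions import ModelError
from .io_formats import ImageVolume4D
from .preprocess import BrainMask, MeanTimecourse, mean_timecourse

__all__ = ["CvrValue", "cvr_from_betas", "whole_brain_cvr", "regional_cvr",
           "voxelwise_cvr_global", "voxelwise_cvr_shifted", "relative_map",
           "VOXEL_SHIFT_WINDOW_S"]

VOXEL_SHIFT_WINDOW_S = (-5.0, 30.0)
VOXEL_SHIFT_STEP_S = 1.0
DENOM_GUARD_REL = 1e-9


@dataclass
class CvrValue:
    """CVR for one region, with the fit it came from."""

    cvr: float            # % BOLD change per mmHg
    beta1: float
    beta0: float
    shift_used: float     # seconds
    partial_cc: float


def cvr_from_betas(
    beta1: float | np.ndarray,
    beta0: float | np.ndarray,
    mean_etco2: float,
    baseline_etco2: float,
) -> float | np.ndarray:
    """Convert GLM coefficients to CVR in %/mmHg (scalar or elementwise).

    Non-positive or near-zero denominators (no meaningful baseline signal)
    yield NaN with a warning.
    """
    b1 = np.asarray(beta1, dtype=float)
    b0 = np.asarray(beta0, dtype=float)
    denom = b0 - b1 * (mean_etco2 - baseline_etco2)
    bad = (denom <= 0) | (np.abs(denom) < DENOM_GUARD_REL * np.abs(b0))
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} CVR value(s) undefined (non-positive baseline signal)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cvr = np.where(bad, np.nan, b1 / np.where(bad, 1.0, denom) * 100.0)
    if np.isscalar(beta1) or (cvr.ndim == 0):
        return float(cvr)
    return cvr


def whole_brain_cvr(
    etco2: EtCo2Curve, bold_wb: MeanTimecourse, allow_short_co2: bool = False
) -> tuple[CvrValue, AlignmentResult]:
    """Align globally, fit, and convert to %/mmHg."""
    result = align(etco2, bold_wb, allow_short_co2=allow_short_co2)
    fit = result.fit_at_opt
    reg = resample_regressor(etco2, bold_wb.frame_times, result.shift_opt)
    cvr = cvr_from_betas(fit.beta1, fit.beta0, float(reg.mean()), etco2.baseline_etco2)
    value = CvrValue(cvr=float(cvr), beta1=fit.beta1, beta0=fit.beta0,
                     shift_used=result.shift_opt, partial_cc=fit.partial_cc)
    return value, result


def regional_cvr(
    etco2: EtCo2Curve,
    img: ImageVolume4D,
    parcellation: np.ndarray,
    min_voxels: int = 10,
    allow_short_co2: bool = False,
) -> pd.DataFrame:
    """Per-ROI CVR with per-ROI temporal alignment.

    ``parcellation`` holds non-negative integer labels on the BOLD grid
    (0 = background). Rows below ``min_voxels`` are flagged ``low_n`` but
    still computed.
    """
    labels = np.asarray(np.rint(parcellation), dtype=int)
    if labels.shape != img.shape3d:
        raise ModelError(f"parcellation grid {labels.shape} != image grid {img.shape3d}")
    roi_ids = np.unique(labels)
    roi_ids = roi_ids[roi_ids > 0]
    if roi_ids.size == 0:
        raise ModelError("parcellation contains no nonzero labels")
    rows = []
    for roi in roi_ids:
        roi_mask = BrainMask(mask=labels == roi)
        tc = mean_timecourse(img, roi_mask, region=f"roi-{roi}")
        result = align(etco2, tc, allow_short_co2=allow_short_co2)
        fit = result.fit_at_opt
        reg = resample_regressor(etco2, tc.frame_times, result.shift_opt)
        cvr = cvr_from_betas(fit.beta1, fit.beta0, float(reg.mean()), etco2.baseline_etco2)
        rows.append({
            "roi_id": int(roi),
            "n_voxels": roi_mask.n_voxels,
            "shift_sec": result.shift_opt,
            "cvr_pct_per_mmHg": float(cvr),
            "partial_cc": fit.partial_cc,
            "low_n": roi_mask.n_voxels < min_voxels,
        })
    return pd.DataFrame(rows)


def _design(regressor: np.ndarray) -> np.ndarray:
    n = regressor.size
    return np.column_stack([regressor - regressor.mean(), drift_regressor(n), np.ones(n)])


def _fit_voxels(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Betas (3, nv) and rss (nv,) for all voxel columns of Y at once."""
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return beta, np.einsum("ij,ij->j", resid, resid)


def voxelwise_cvr_global(
    etco2: EtCo2Curve,
    img: ImageVolume4D,
    mask: BrainMask,
    shift_global: float,
) -> np.ndarray:
    """CVR map with every voxel regressed on the globally shifted EtCO2.

    Out-of-mask and zero-variance voxels are NaN.
    """
    reg = resample_regressor(etco2, img.frame_times, shift_global)
    X = _design(reg)
    Y = img.data[mask.mask].T  # (n_frames, n_voxels)
    beta, _ = _fit_voxels(X, Y)
    cvr = np.asarray(
        cvr_from_betas(beta[0], beta[2], float(reg.mean()), etco2.baseline_etco2)
    )
    cvr[np.ptp(Y, axis=0) == 0] = np.nan
    out = np.full(img.shape3d, np.nan)
    out[mask.mask] = cvr
    return out


def voxelwise_cvr_shifted(
    etco2: EtCo2Curve,
    img: ImageVolume4D,
    mask: BrainMask,
    shift_global: float,
    window_s: tuple[float, float] = VOXEL_SHIFT_WINDOW_S,
    step_s: float = VOXEL_SHIFT_STEP_S,
) -> dict[str, np.ndarray]:
    """Voxel-wise-shift CVR map plus temporal shift map.

    Starting from the global shift, each voxel's regressor is further
    shifted by delta in ``window_s`` (default -5..+30 s) at ``step_s``
    steps; the delta minimizing that voxel's residual sum of squares wins
    (ties -> smallest delta). Returns a dict with:

    - ``cvr``: %/mmHg at the per-voxel best shift
    - ``shift``: best delta in seconds, relative to the global shift
    - ``shift_absolute``: global shift + delta
    - ``boundary``: 1.0 where the best delta sits on a window edge (the
      true delay may lie outside the scanned window)
    """
    lo, hi = window_s
    if not hi > lo:
        raise ModelError(f"invalid voxel-shift window {window_s}")
    deltas = lo + np.arange(int(np.floor((hi - lo) / step_s)) + 1) * step_s
    ft = img.frame_times
    Y = img.data[mask.mask].T
    nv = Y.shape[1]
    yy = np.einsum("ij,ij->j", Y, Y)
    best_rss = np.full(nv, np.inf)
    best_delta = np.zeros(nv)
    for d in deltas:
        X = _design(resample_regressor(etco2, ft, shift_global + d))
        Q, _ = np.linalg.qr(X)
        proj = Q.T @ Y
        rss = yy - np.einsum("ij,ij->j", proj, proj)
        better = rss < best_rss - 1e-12  # strict: ties keep the earlier (smaller) delta
        best_rss[better] = rss[better]
        best_delta[better] = d
    cvr = np.full(nv, np.nan)
    for d in np.unique(best_delta):
        sel = best_delta == d
        reg_d = resample_regressor(etco2, ft, shift_global + d)
        beta, _ = _fit_voxels(_design(reg_d), Y[:, sel])
        cvr[sel] = np.asarray(
            cvr_from_betas(beta[0], beta[2], float(reg_d.mean()), etco2.baseline_etco2)
        )
    flat = np.ptp(Y, axis=0) == 0
    cvr[flat] = np.nan
    best_delta_out = best_delta.copy()
    best_delta_out[flat] = np.nan
    boundary = ((best_delta <= deltas[0] + 1e-12) | (best_delta >= deltas[-1] - 1e-12))

    def to_map(vec: np.ndarray) -> np.ndarray:
        out = np.full(img.shape3d, np.nan)
        out[mask.mask] = vec
        return out

    return {
        "cvr": to_map(cvr),
        "shift": to_map(best_delta_out),
        "shift_absolute": to_map(best_delta_out + shift_global),
        "boundary": to_map(boundary.astype(float)),
    }


def relative_map(map3d: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Divide a map by its in-mask mean (NaN voxels excluded from the mean)."""
    values = map3d[mask.mask]
    mean = np.nanmean(values)
    if not np.isfinite(mean) or mean == 0:
        raise ModelError("in-mask mean is zero or undefined; cannot normalize")
    out = np.full(map3d.shape, np.nan)
    out[mask.mask] = values / mean
    return out
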