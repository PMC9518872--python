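"""Temporal alignment of the EtCO2 curve to a BOLD time course.

EtCO2 is measured at the mouth, the BOLD response in the brain, so the two
signals are offset by ventilation-to-brain transit plus hemodynamic delay.
The alignment model is a GLM,

    BOLD_i = beta1 * etco2_i(s) + beta2 * ell_i + beta0,

where ``etco2_i(s)`` is the zero-meaned EtCO2 curve resampled (linear
interpolation) to recorder time ``s + i*TR``, and ``ell`` is a linearly
ascending drift term ``-(N-1)/2 ... (N-1)/2``. The optimal shift ``s`` is
found in two steps: a coarse scan at 1 s steps over every feasible shift
(0 to EtCO2 duration minus BOLD duration), then a fine scan at 100 ms steps
over +/-5 s around the coarse optimum, with the residual-vs-shift profile
fitted by a second-degree polynomial whose vertex (when convex) gives the
final shift at sub-grid resolution.

The partial correlation between BOLD and the shifted EtCO2 — after both are
residualized against intercept and drift — doubles as the dataset quality
index.

Because the gas paradigm is (nearly) periodic, an anti-phase shift fits the
data almost as well as the true one if the CO2 coefficient is allowed to go
negative (a half-period offset just flips the regressor's sign). Shift
*scoring* therefore constrains beta1 >= 0: when the unconstrained
coefficient is negative, the shift is scored with the CO2-free (drift +
intercept) residual. Hypercapnia raises the BOLD signal, so the constraint
only discards physiologically inverted fits; the final fit reported at the
optimum is unconstrained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .capnogram import EtCo2Curve
from .exceptions import AlignmentError
from .preprocess import MeanTimecourse

__all__ = ["GlmFit", "AlignmentResult", "glm_fit", "coarse_shift_search",
           "fine_shift_search", "align", "resample_regressor"]

FINE_HALF_WINDOW_S = 5.0
FINE_STEP_S = 0.1


@dataclass
class GlmFit:
    """Least-squares fit of a BOLD series on [regressor, drift, intercept]."""

    beta1: float   # signal units per mmHg
    beta2: float   # signal units per frame-index unit (drift)
    beta0: float   # intercept, signal units
    rss: float
    partial_cc: float


@dataclass
class AlignmentResult:
    shift_opt: float
    coarse_profile: np.ndarray   # (n, 2): shift_s, rss
    fine_profile: np.ndarray     # (m, 2): shift_s, rss
    poly_coeffs: tuple[float, float, float] | None  # a, b, c of a*s^2+b*s+c
    fit_at_opt: GlmFit
    warnings: list[str]


def drift_regressor(n: int) -> np.ndarray:
    """Linearly ascending term -(N-1)/2, ..., (N-1)/2."""
    return np.arange(n, dtype=float) - (n - 1) / 2.0


def glm_fit(bold: np.ndarray | MeanTimecourse, regressor: np.ndarray) -> GlmFit:
    """Fit the alignment GLM at one shift.

    The regressor is zero-meaned before fitting (the scaling of beta0 and
    beta1 downstream relies on this convention). ``partial_cc`` is the
    Pearson correlation between BOLD and regressor after residualizing both
    against intercept and drift.
    """
    y = bold.values if isinstance(bold, MeanTimecourse) else np.asarray(bold, dtype=float)
    r = np.asarray(regressor, dtype=float)
    n = y.size
    if n < 4:
        raise AlignmentError(f"need at least 4 time points, got {n}")
    if r.size != n:
        raise AlignmentError(f"length mismatch: BOLD {n}, regressor {r.size}")
    if np.ptp(r) == 0:
        raise AlignmentError("regressor is constant; cannot fit")
    rbar = r - r.mean()
    ell = drift_regressor(n)
    X = np.column_stack([rbar, ell, np.ones(n)])
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    # partial correlation: residualize both against [1, ell]
    Z = np.column_stack([np.ones(n), ell])
    Pz = Z @ np.linalg.lstsq(Z, np.column_stack([y, rbar]), rcond=None)[0]
    yr = y - Pz[:, 0]
    rr = rbar - Pz[:, 1]
    denom = np.linalg.norm(yr) * np.linalg.norm(rr)
    partial_cc = float((yr @ rr) / denom) if denom > 0 else 0.0
    return GlmFit(beta1=float(beta[0]), beta2=float(beta[1]), beta0=float(beta[2]),
                  rss=rss, partial_cc=partial_cc)


def _search_rss(bold: MeanTimecourse, regressor: np.ndarray) -> float:
    """Shift-scoring residual: rss of the GLM, with beta1 constrained >= 0.

    If the unconstrained CO2 coefficient is negative the constrained
    optimum has beta1 = 0, i.e. the residual of BOLD on drift + intercept
    alone (constant across shifts, so inverted fits can never win).
    """
    fit = glm_fit(bold, regressor)
    if fit.beta1 >= 0:
        return fit.rss
    y = bold.values
    n = y.size
    Z = np.column_stack([np.ones(n), drift_regressor(n)])
    resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return float(resid @ resid)


def resample_regressor(etco2: EtCo2Curve, frame_times: np.ndarray, shift: float,
                       warn_list: list[str] | None = None) -> np.ndarray:
    """EtCO2 values at recorder times ``shift + frame_times`` (linear interp).

    Times beyond the curve hold the terminal value; that only happens at
    extreme fine-search shifts and is reported as a warning.
    """
    times = shift + np.asarray(frame_times, dtype=float)
    if warn_list is not None and (times[-1] > etco2.t[-1] + 1e-9 or times[0] < etco2.t[0] - 1e-9):
        warn_list.append(
            f"shift {shift:.2f} s samples beyond the EtCO2 curve; terminal value held"
        )
    return np.interp(times, etco2.t, etco2.v)


def _feasible_max_shift(etco2: EtCo2Curve, bold: MeanTimecourse) -> float:
    d_bold = (bold.n_frames - 1) * bold.tr
    return float(etco2.t[-1] - etco2.t[0] - d_bold)


def coarse_shift_search(
    etco2: EtCo2Curve, bold: MeanTimecourse, allow_short_co2: bool = False
) -> tuple[float, np.ndarray]:
    """Scan integer-second shifts over [0, EtCO2 duration - BOLD duration].

    Returns the residual-minimizing shift (ties -> smallest) and the
    (shift, rss) profile. If the recording is shorter than the BOLD run the
    search is infeasible; with ``allow_short_co2`` a single zero-shift fit
    is performed with the curve end-padded by its last value.
    """
    s_max = _feasible_max_shift(etco2, bold)
    ft = bold.frame_times
    if s_max < 0:
        if not allow_short_co2:
            raise AlignmentError(
                "EtCO2 recording is shorter than the BOLD run; re-run with "
                "allow_short_co2 (--allow-short-co2) to force a zero-shift fit"
            )
        warnings.warn("EtCO2 shorter than BOLD: zero-shift fit with end-padded curve",
                      stacklevel=2)
        fit = glm_fit(bold, resample_regressor(etco2, ft, 0.0))
        return 0.0, np.array([[0.0, fit.rss]])
    shifts = np.arange(0.0, np.floor(s_max) + 1.0)
    rss = np.empty(shifts.size)
    for i, s in enumerate(shifts):
        rss[i] = _search_rss(bold, resample_regressor(etco2, ft, s))
    best = float(shifts[int(np.argmin(rss))])  # argmin returns the first minimum
    return best, np.column_stack([shifts, rss])


def fine_shift_search(
    etco2: EtCo2Curve, bold: MeanTimecourse, s_coarse: float,
    coarse_profile: np.ndarray | None = None,
) -> AlignmentResult:
    """100 ms-step scan over +/-5 s around the coarse optimum, with a
    quadratic fit of the residual profile for sub-grid shift resolution.

    The fine grid is clipped to the feasible shift range. If the quadratic
    is convex its vertex (clamped to the scanned window) is the final
    shift; otherwise the grid argmin is used with a warning.
    """
    warn_list: list[str] = []
    s_max = max(_feasible_max_shift(etco2, bold), 0.0)
    ft = bold.frame_times
    n_steps = int(round(FINE_HALF_WINDOW_S / FINE_STEP_S))
    shifts = s_coarse + np.arange(-n_steps, n_steps + 1) * FINE_STEP_S
    shifts = shifts[(shifts >= 0.0) & (shifts <= s_max + 1e-9)]
    if shifts.size < 5:
        warn_list.append("fewer than 5 feasible fine-grid shifts; keeping coarse optimum")
        fit = glm_fit(bold, resample_regressor(etco2, ft, s_coarse, warn_list))
        profile = np.array([[s_coarse, fit.rss]])
        return AlignmentResult(
            shift_opt=float(s_coarse),
            coarse_profile=coarse_profile if coarse_profile is not None else profile,
            fine_profile=profile, poly_coeffs=None, fit_at_opt=fit, warnings=warn_list)
    rss = np.empty(shifts.size)
    for i, s in enumerate(shifts):
        rss[i] = _search_rss(bold, resample_regressor(etco2, ft, s, warn_list))
    a, b, c = np.polyfit(shifts, rss, 2)
    # The full-window quadratic locates the basin and is reported for QC,
    # but its vertex is biased when the profile has piecewise kinks (the
    # regressor is piecewise linear in the shift). The final vertex comes
    # from a parabola over the points within +/-1 s of the grid argmin.
    i_min = int(np.argmin(rss))
    local = np.abs(shifts - shifts[i_min]) <= 1.0 + 1e-9
    a_loc, b_loc, _ = np.polyfit(shifts[local], rss[local], 2) if local.sum() >= 3 \
        else (0.0, 0.0, 0.0)
    if a_loc > 0:
        shift_opt = float(np.clip(-b_loc / (2 * a_loc),
                                  shifts[local][0], shifts[local][-1]))
    elif a > 0:
        shift_opt = float(np.clip(-b / (2 * a), shifts[0], shifts[-1]))
    else:
        shift_opt = float(shifts[i_min])
        warn_list.append("residual profile not convex; using fine-grid argmin")
    fit = glm_fit(bold, resample_regressor(etco2, ft, shift_opt, warn_list))
    return AlignmentResult(
        shift_opt=shift_opt,
        coarse_profile=coarse_profile if coarse_profile is not None else np.empty((0, 2)),
        fine_profile=np.column_stack([shifts, rss]),
        poly_coeffs=(float(a), float(b), float(c)),
        fit_at_opt=fit,
        warnings=warn_list,
    )


def align(etco2: EtCo2Curve, bold: MeanTimecourse,
          allow_short_co2: bool = False) -> AlignmentResult:
    """Two-step shift search: coarse 1 s scan, then fine 100 ms scan."""
    s_coarse, profile = coarse_shift_search(etco2, bold, allow_short_co2=allow_short_co2)
    return fine_shift_search(etco2, bold, s_coarse, coarse_profile=profile)
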