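"""Synthetic capnograms and BOLD phantoms with known ground truth.

Every pipeline stage is testable without any acquired data. The generators
emulate the study conditions the pipeline targets:

- capnograms: quasi-periodic breathing (period ~4.5 s, bounded to 3-8 s)
  with raised-cosine breath edges, exhalation plateaus at the block EtCO2
  level, and interleaved 60 s room-air / 60 s hypercapnia blocks (40 ->
  48 mmHg by default, the usual 5% CO2 challenge response); optional
  partial breaths at half amplitude; optional CO2-switching scenario where
  the inhaled gas exceeds a low exhaled EtCO2;
- CO2-task BOLD: each voxel is an affine function of the time-shifted true
  EtCO2 curve (gain = CVR in %/mmHg referenced to baseline) plus linear
  drift, motion-correlated nuisance, and white Gaussian noise;
- resting-state BOLD: a shared low-frequency latent signal (sinusoids below
  the 0.1164 Hz reference-signal cutoff) scaled per voxel by a gain field.

Block transitions in the true EtCO2 curve are instantaneous so recovery
targets stay analytically exact. All randomness flows through one
``numpy.random.Generator`` seeded from the spec, so a fixed seed gives
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .capnogram import EtCo2Curve
from .exceptions import ModelError
from .io_formats import Co2Trace, ImageVolume4D, MotionParams

__all__ = ["PhantomSpec", "simulate_capnogram", "simulate_co2_bold",
           "simulate_rest_bold", "simulate_parcellation", "brain_ellipsoid",
           "noise_sd_from_snr"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic study.

    Defaults mirror the standard acquisition the pipeline targets: a
    64x64x10 matrix at 3.44x3.44x3.5 mm voxels, TR 2 s, 60 s blocks
    alternating room air (EtCO2 40 mmHg) and 5% CO2 (48 mmHg), a 7 min CO2
    recording, and a global lung-to-brain shift of tens of seconds.
    ``noise_sd`` is the white-noise standard deviation as a fraction of the
    voxel baseline signal ``a_brain``.
    """

    shape: tuple[int, int, int] = (64, 64, 10)
    voxel_size: tuple[float, float, float] = (3.44, 3.44, 3.5)
    tr: float = 2.0
    n_frames: int = 210
    baseline_etco2: float = 40.0
    hyper_etco2: float = 48.0
    block_s: float = 60.0
    breath_period_mean: float = 4.5
    breath_period_sd: float = 0.5
    breath_period_bounds: tuple[float, float] = (3.0, 8.0)
    partial_breath_rate: float = 0.0
    inspired_room: float = 1.0    # mmHg, trough level breathing room air
    inspired_hyper: float = 36.0  # mmHg, trough level breathing 5% CO2
    capno_fs: float = 100.0
    capno_duration_s: float | None = None  # None: resolved (>= 420 s, covers BOLD+shift)
    capno_noise_sd: float = 0.0   # mmHg, additive white noise on the raw trace
    true_shift_s: float = 47.0
    true_cvr: float = 0.3         # %/mmHg
    drift_pct_per_frame: float = 0.0
    noise_sd: float = 0.0
    motion_amp_mm: float = 0.0
    rest_gain: float = 0.01       # fractional signal swing per unit latent
    a_brain: float = 1000.0
    a_background: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("breath_period_sd", "partial_breath_rate", "noise_sd",
                     "capno_noise_sd", "motion_amp_mm"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be non-negative")
        lo, hi = self.breath_period_bounds
        if not 0 < lo <= hi:
            raise ModelError("invalid breath period bounds")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def resolved_capno_duration(self) -> float:
        """Explicit duration, or the longer of 7 min and BOLD span + shift + margin.

        The margin (36 s) covers the +30 s voxel-wise shift window plus the
        fine-search half-window so shifted regressors never run off the
        recording.
        """
        if self.capno_duration_s is not None:
            return float(self.capno_duration_s)
        need = self.true_shift_s + (self.n_frames - 1) * self.tr + 36.0
        return float(max(420.0, need))

    def to_dict(self) -> dict:
        return asdict(self)


def noise_sd_from_snr(spec: PhantomSpec, snr: float) -> float:
    """Noise level (fraction of a_brain) giving plateau-contrast / sigma = snr."""
    contrast = spec.a_brain * (spec.true_cvr / 100.0) * (spec.hyper_etco2 - spec.baseline_etco2)
    return contrast / snr / spec.a_brain


def _block_level(t: float, spec: PhantomSpec) -> float:
    """True exhaled EtCO2 at time t: alternating blocks, room air first."""
    block = int(t // spec.block_s)
    return spec.hyper_etco2 if block % 2 == 1 else spec.baseline_etco2


def _raised_cosine(n: int, v0: float, v1: float) -> np.ndarray:
    """Smooth monotone transition from v0 to v1 over n samples."""
    u = (1.0 - np.cos(np.linspace(0.0, np.pi, n))) / 2.0
    return v0 + (v1 - v0) * u


def simulate_capnogram(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[Co2Trace, EtCo2Curve]:
    """Breath-by-breath capnogram plus the exact plateau-value truth curve.

    Each breath: trough at the inspired CO2 level (elevated during
    hypercapnic blocks), raised-cosine rise, flat exhalation plateau at the
    block's EtCO2 level, raised-cosine fall. Breath periods are drawn from
    a clipped normal distribution. Partial breaths (probability
    ``partial_breath_rate``) reach only half the trough-to-plateau
    amplitude. The truth curve is the block plateau value on a 1 Hz grid,
    unaffected by partial breaths.
    """
    rng = spec.rng() if rng is None else rng
    fs = spec.capno_fs
    duration = spec.resolved_capno_duration()
    lo, hi = spec.breath_period_bounds
    segments: list[np.ndarray] = []
    t = 0.0
    while t < duration:
        period = float(np.clip(rng.normal(spec.breath_period_mean, spec.breath_period_sd),
                               lo, hi)) if spec.breath_period_sd > 0 else spec.breath_period_mean
        n = max(8, int(round(period * fs)))
        plateau = _block_level(t, spec)
        trough = spec.inspired_hyper if plateau == spec.hyper_etco2 else spec.inspired_room
        if spec.partial_breath_rate > 0 and rng.random() < spec.partial_breath_rate:
            plateau = trough + 0.5 * (plateau - trough)
        n_trough = int(0.25 * n)
        n_rise = int(0.20 * n)
        n_fall = max(1, int(0.15 * n))
        n_plateau = n - n_trough - n_rise - n_fall
        breath = np.concatenate([
            np.full(n_trough, trough),
            _raised_cosine(n_rise, trough, plateau),
            np.full(n_plateau, plateau),
            _raised_cosine(n_fall, plateau, trough),
        ])
        segments.append(breath)
        t += n / fs
    p = np.concatenate(segments)
    n_total = int(round(duration * fs))
    p = p[:n_total]
    if spec.capno_noise_sd > 0:
        p = p + rng.normal(0.0, spec.capno_noise_sd, size=p.size)
    tt = np.arange(p.size) / fs
    trace = Co2Trace(t=tt, p=p, fs_native=fs)
    t_truth = np.arange(int(np.floor(tt[-1])) + 1, dtype=float)
    v_truth = np.array([_block_level(s, spec) for s in t_truth])
    return trace, EtCo2Curve(t=t_truth, v=v_truth)


def brain_ellipsoid(shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean ellipsoid 'brain' centered in the grid (semi-axes 0.4 * dims)."""
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ax, ay, az = 0.4 * nx, 0.4 * ny, 0.4 * nz
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _simulate_motion(spec: PhantomSpec, rng: np.random.Generator) -> MotionParams:
    n = spec.n_frames
    t = np.arange(n) * spec.tr
    cols = []
    for i in range(6):
        amp = spec.motion_amp_mm * (1.0 if i < 3 else 0.01)  # rotations in rad, small
        if amp > 0:
            freq = 0.005 + 0.004 * i
            cols.append(amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)))
        else:
            cols.append(np.zeros(n))
    return MotionParams(values=np.column_stack(cols))


def simulate_co2_bold(
    spec: PhantomSpec,
    etco2_truth: EtCo2Curve,
    cvr_field: np.ndarray | None = None,
    delay_field: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageVolume4D, MotionParams, dict]:
    """Forward model of the CO2-task BOLD series.

    Voxel v at frame i:

        S = a_v * (1 + (c_v/100) * (EtCO2(i*TR + s_global + delta_v) - baseline))
            + a_v * (drift/100) * ell_i + a_v * noise_sd * eps,

    with c_v the CVR field (%/mmHg, default uniform ``true_cvr``), delta_v
    the per-voxel delay field (s, default 0), and baseline the truth
    curve's bottom-25% average. Background voxels sit at ``a_background``.
    Returns the image, a motion-parameter table, and a truth dict holding
    the mask, fields and global shift.
    """
    rng = spec.rng() if rng is None else rng
    mask = brain_ellipsoid(spec.shape)
    c = np.full(spec.shape, spec.true_cvr) if cvr_field is None else np.asarray(cvr_field, float)
    d = np.zeros(spec.shape) if delay_field is None else np.asarray(delay_field, float)
    if c.shape != spec.shape or d.shape != spec.shape:
        raise ModelError("cvr/delay fields must match the phantom grid")
    ft = np.arange(spec.n_frames) * spec.tr
    t_max = spec.true_shift_s + float(np.max(d[mask])) + ft[-1]
    if t_max > etco2_truth.t[-1] + 1e-9 or spec.true_shift_s + float(np.min(d[mask])) < 0:
        raise ModelError(
            f"delay field needs EtCO2 coverage up to {t_max:.0f} s but the truth "
            f"curve ends at {etco2_truth.t[-1]:.0f} s"
        )
    baseline = etco2_truth.baseline_etco2
    data = np.full((*spec.shape, spec.n_frames), spec.a_background, dtype=float)
    delays = np.unique(d[mask])
    for delay in delays:
        e = np.interp(spec.true_shift_s + delay + ft, etco2_truth.t, etco2_truth.v)
        sel = mask & (d == delay)
        gain = c[sel][:, None] / 100.0
        data[sel] = spec.a_brain * (1.0 + gain * (e - baseline)[None, :])
    ell = np.arange(spec.n_frames) - (spec.n_frames - 1) / 2.0
    if spec.drift_pct_per_frame != 0:
        data[mask] += spec.a_brain * (spec.drift_pct_per_frame / 100.0) * ell[None, :]
    if spec.noise_sd > 0:
        data += spec.a_brain * spec.noise_sd * rng.standard_normal(data.shape)
    img = ImageVolume4D(data=data, voxel_size=spec.voxel_size, tr=spec.tr)
    motion = _simulate_motion(spec, rng)
    truth = {
        "mask": mask,
        "cvr_field": c,
        "delay_field": d,
        "s_global": spec.true_shift_s,
        "baseline_etco2": baseline,
        "mean_etco2": etco2_truth.mean_etco2,
    }
    return img, motion, truth


def _latent_signal(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Shared low-frequency fluctuation, unit standard deviation.

    Sum of sinusoids at fixed frequencies below the reference-signal cutoff
    with random phases; emulates spontaneous CO2/vasomotor drift.
    """
    t = np.arange(spec.n_frames) * spec.tr
    # snap target frequencies to FFT bins so the whole latent sits exactly
    # at or below the reference-signal cutoff (no spectral leakage)
    df = 1.0 / (spec.n_frames * spec.tr)
    targets = np.array([0.013, 0.027, 0.041, 0.062, 0.083, 0.101])
    k_max = int(np.floor(0.1164 / df))
    ks = np.unique(np.clip(np.rint(targets / df).astype(int), 1, max(k_max, 1)))
    amps = 1.0 / np.sqrt(1 + np.arange(ks.size))
    latent = np.zeros(spec.n_frames)
    for k, a in zip(ks, amps):
        latent += a * np.sin(2 * np.pi * (k * df) * t + rng.uniform(0, 2 * np.pi))
    sd = latent.std()
    if sd == 0:
        raise ModelError("degenerate latent signal")
    return latent / sd


def simulate_rest_bold(
    spec: PhantomSpec,
    gain_field: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageVolume4D, MotionParams, dict]:
    """Resting-state phantom: voxel = a_v * (1 + g_v * latent) + noise.

    ``gain_field`` defaults to a uniform ``rest_gain``. Motion leakage is
    added when ``motion_amp_mm`` > 0. Truth dict carries the gain field,
    the latent signal and the mask.
    """
    rng = spec.rng() if rng is None else rng
    mask = brain_ellipsoid(spec.shape)
    g = np.full(spec.shape, spec.rest_gain) if gain_field is None else np.asarray(gain_field, float)
    if g.shape != spec.shape:
        raise ModelError("gain field must match the phantom grid")
    latent = _latent_signal(spec, rng)
    motion = _simulate_motion(spec, rng)
    data = np.full((*spec.shape, spec.n_frames), spec.a_background, dtype=float)
    data[mask] = spec.a_brain * (1.0 + g[mask][:, None] * latent[None, :])
    if spec.motion_amp_mm > 0:
        leak = motion.values[:, 0] * spec.a_brain * 0.001
        data[mask] += leak[None, :]
    if spec.noise_sd > 0:
        data += spec.a_brain * spec.noise_sd * rng.standard_normal(data.shape)
    img = ImageVolume4D(data=data, voxel_size=spec.voxel_size, tr=spec.tr)
    truth = {"mask": mask, "gain_field": g, "latent": latent}
    return img, motion, truth


def simulate_parcellation(mask: np.ndarray, n_rois: int) -> np.ndarray:
    """Tile the in-mask voxels into ``n_rois`` contiguous slabs along x.

    Labels are 1..n_rois inside the mask, 0 outside.
    """
    mask = np.asarray(mask).astype(bool)
    n_in = int(mask.sum())
    if not 1 <= n_rois <= n_in:
        raise ModelError(f"n_rois must be in [1, {n_in}], got {n_rois}")
    labels = np.zeros(mask.shape, dtype=int)
    idx = np.argwhere(mask)  # sorted by x, then y, z
    bounds = np.linspace(0, n_in, n_rois + 1).astype(int)
    for roi in range(n_rois):
        sel = idx[bounds[roi]:bounds[roi + 1]]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = roi + 1
    return labels
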