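"""Readers and writers for the image and text formats the pipeline touches.

Images are ANALYZE 7.5 (``.hdr``/``.img``) or NIfTI-1 (``.nii``/``.nii.gz``),
handled by nibabel. CO2 traces and motion parameters are plain-text tables.
No science lives here: this module only moves arrays and metadata in and out
of files, preserving geometry unchanged. All images consumed by one run are
assumed to share the BOLD voxel grid (the pipeline never re-orients or
resamples in space), and all time is carried in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError

__all__ = [
    "ImageVolume4D",
    "Co2Trace",
    "MotionParams",
    "read_image_4d",
    "read_image_3d",
    "read_co2_trace",
    "read_motion_params",
    "write_image_4d",
    "write_map_3d",
    "write_outputs",
]


@dataclass
class ImageVolume4D:
    """A 4D BOLD series: (x, y, z, frame) data plus acquisition metadata.

    ``tr`` is the repetition time in seconds; frame ``i`` is assigned the
    acquisition time ``i * tr`` (frame onset, 0-based). ``affine`` is carried
    through unchanged so outputs land on the source grid.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4D series, got {self.data.ndim}D data")
        if self.data.shape[3] < 2:
            raise FormatError("4D series must have at least 2 frames")
        if not self.tr > 0:
            raise FormatError(f"tr must be positive, got {self.tr}")
        vx = tuple(float(v) for v in self.voxel_size)
        if len(vx) != 3 or any(v <= 0 for v in vx):
            raise FormatError(f"voxel sizes must be 3 positive numbers, got {self.voxel_size}")
        self.voxel_size = vx
        if self.affine is None:
            self.affine = np.diag([*vx, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise FormatError("image data contains non-finite values")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame-onset convention)."""
        return np.arange(self.n_frames) * self.tr


@dataclass
class Co2Trace:
    """Raw capnogram samples: time in seconds, CO2 partial pressure in mmHg."""

    t: np.ndarray
    p: np.ndarray
    fs_native: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.ndim != 1 or self.p.ndim != 1 or self.t.size != self.p.size:
            raise FormatError("trace time and pressure must be 1D arrays of equal length")
        if self.t.size < 2:
            raise FormatError("trace must contain at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise FormatError("trace time axis must be strictly increasing")
        if not np.all(np.isfinite(self.p)) or not np.all(np.isfinite(self.t)):
            raise FormatError("trace contains non-finite values")
        if not 1.0 <= self.fs_native <= 1000.0:
            raise FormatError(f"sampling frequency {self.fs_native} Hz outside [1, 1000] Hz")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class MotionParams:
    """Rigid-body realignment parameters: N frames x 6 columns.

    Columns are 3 translations (mm) followed by 3 rotations (rad), the usual
    realignment convention.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise FormatError(
                f"motion parameters must have 6 columns, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("motion parameters contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def read_image_4d(path: str | Path, tr: float) -> ImageVolume4D:
    """Load a 4D ANALYZE or NIfTI image as an :class:`ImageVolume4D`.

    ``tr`` must be supplied explicitly (ANALYZE headers carry no repetition
    time, and NIfTI ones are frequently wrong in the wild). Header scaling
    slopes, when present, are applied by nibabel's ``get_fdata``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    if not tr > 0:
        raise FormatError(f"tr must be positive, got {tr}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt header, unknown format
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected 4D series, got {data.ndim}D image at {path}")
    zooms = img.header.get_zooms()[:3]
    return ImageVolume4D(data=data, voxel_size=tuple(float(z) for z in zooms),
                         tr=float(tr), affine=np.asarray(img.affine))


def read_image_3d(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D label/mask image; returns ``(data, affine)``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"expected 3D image, got {data.ndim}D at {path}")
    return data, np.asarray(img.affine)


def read_co2_trace(path: str | Path, fs: float | None = None) -> Co2Trace:
    """Parse a CO2 recording from a text/CSV file.

    Accepts either two columns (time in seconds, pressure in mmHg) or a
    single pressure column, in which case ``fs`` (Hz) is required and sample
    ``i`` is assigned ``t = i / fs``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"CO2 trace file not found: {path}")
    try:
        table = pd.read_csv(path, sep=r"[,;\s]+", engine="python", header=None, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse CO2 trace {path}: {exc}") from exc
    table = table.apply(pd.to_numeric, errors="coerce").dropna(how="all")
    if table.isna().any().any():
        raise FormatError(f"non-numeric entries in CO2 trace {path}")
    if table.shape[0] < 2:
        raise FormatError("CO2 trace must contain at least 2 samples")
    if table.shape[1] == 1:
        if fs is None:
            raise FormatError("single-column CO2 trace requires an explicit sampling rate fs")
        p = table.iloc[:, 0].to_numpy(dtype=float)
        t = np.arange(p.size) / float(fs)
        return Co2Trace(t=t, p=p, fs_native=float(fs))
    if table.shape[1] == 2:
        t = table.iloc[:, 0].to_numpy(dtype=float)
        p = table.iloc[:, 1].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise FormatError("CO2 trace time axis must be strictly increasing")
        fs_native = float(fs) if fs is not None else (t.size - 1) / (t[-1] - t[0])
        return Co2Trace(t=t, p=p, fs_native=float(fs_native))
    raise FormatError(f"CO2 trace must have 1 or 2 columns, got {table.shape[1]}")


def read_motion_params(path: str | Path) -> MotionParams:
    """Read a 6-column rigid-body motion parameter text file."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"motion parameter file not found: {path}")
    try:
        table = pd.read_csv(path, sep=r"[,;\s]+", engine="python", header=None, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse motion parameters {path}: {exc}") from exc
    table = table.apply(pd.to_numeric, errors="coerce")
    if table.isna().any().any():
        raise FormatError(f"non-numeric entries in motion parameter file {path}")
    if table.shape[1] != 6:
        raise FormatError(f"motion parameter file must have 6 columns, got {table.shape[1]}")
    return MotionParams(values=table.to_numpy(dtype=float))


def _nib_image(data: np.ndarray, affine: np.ndarray, path: Path):
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".hdr", ".img")):
        return nib.AnalyzeImage(np.asarray(data), None, None), True
    return nib.Nifti1Image(np.asarray(data), affine), False


def write_image_4d(vol: ImageVolume4D, path: str | Path) -> Path:
    """Write a 4D series as NIfTI-1 or ANALYZE 7.5 depending on the suffix."""
    path = Path(path)
    img, is_analyze = _nib_image(vol.data, vol.affine, path)
    if is_analyze:
        img.header.set_zooms((*vol.voxel_size, vol.tr))
    nib.save(img, str(path))
    return path


def write_map_3d(data: np.ndarray, reference: ImageVolume4D, path: str | Path) -> Path:
    """Write a 3D map on the geometry of ``reference``."""
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if data.shape != reference.shape3d:
        raise FormatError(
            f"map shape {data.shape} does not match reference grid {reference.shape3d}"
        )
    img, is_analyze = _nib_image(data, reference.affine, path)
    if is_analyze:
        img.header.set_zooms(reference.voxel_size)
    nib.save(img, str(path))
    return path


def write_outputs(
    out_dir: str | Path,
    *,
    reference: ImageVolume4D | None = None,
    maps: dict[str, np.ndarray] | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
    json_blobs: dict[str, dict] | None = None,
    reports: dict[str, str] | None = None,
) -> dict:
    """Write maps (NIfTI), tables (CSV), JSON blobs and text reports.

    Returns the manifest (also written as ``manifest.json``) listing every
    file produced. Map geometry is taken from ``reference``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise FormatError(f"output directory {out_dir} is not writable: {exc}") from exc

    files: list[str] = []
    for name, data in (maps or {}).items():
        if reference is None:
            raise FormatError("writing maps requires a reference image for geometry")
        fname = name if name.endswith((".nii", ".nii.gz", ".hdr")) else f"{name}.nii.gz"
        write_map_3d(data, reference, out_dir / fname)
        files.append(fname)
    for name, table in (tables or {}).items():
        fname = name if name.endswith(".csv") else f"{name}.csv"
        table.to_csv(out_dir / fname, index=False, float_format="%.10g")
        files.append(fname)
    for name, blob in (json_blobs or {}).items():
        fname = name if name.endswith(".json") else f"{name}.json"
        (out_dir / fname).write_text(json.dumps(blob, indent=2, sort_keys=True) + "\n")
        files.append(fname)
    for name, text in (reports or {}).items():
        fname = name if name.endswith(".txt") else f"{name}.txt"
        (out_dir / fname).write_text(text)
        files.append(fname)

    manifest = {"out_dir": str(out_dir), "files": sorted(files)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
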