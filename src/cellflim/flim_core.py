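"""Core data model and file I/O for cell-encircled FLIM analysis.

The raw substrate of a FLIM acquisition is a TCSPC histogram cube: for every
pixel of the scanned field, a histogram of photon arrival delays relative to
the excitation pulse, accumulated over many pulses.  A segmentation mask
(a label image with single-pixel borders encoded as 0) assigns pixels to
cells.  This module defines the in-memory containers shared by the analysis
modules and the open on-disk formats used to exchange them:

* cubes — an HDF5 layout (``/counts``, ``/calibration/*``, ``/meta/*``) or a
  multi-frame TIFF (one frame per time bin) with a JSON calibration sidecar;
* masks — 16-bit single-channel label TIFF/PNG;
* per-cell results — plain CSV with fixed column names.

Conventions fixed here and relied on everywhere else: arrays are row-major,
0-based, indexed ``(row, col)``; the time coordinate of bin *i* is its
center, ``t_i = (i + 0.5) * bin_width``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FlimError",
    "FileFormatError",
    "TimingCalibration",
    "HistogramCube",
    "CellMask",
    "CellDecay",
    "AcquisitionMetadata",
    "Channel",
    "Meridian",
    "ScanDirection",
    "DecayFitResult",
    "PhasorPoint",
    "FitConfig",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]


class FlimError(Exception):
    """Base class for errors raised by this package."""


class FileFormatError(FlimError):
    """A file does not conform to the documented on-disk layout."""


# ---------------------------------------------------------------------------
# timing calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimingCalibration:
    """Timing geometry of a TCSPC acquisition.

    Parameters
    ----------
    rep_frequency_hz
        Laser repetition frequency.  Default 80 MHz, the pulsed
        supercontinuum rate typical of adaptive-optics FLIM ophthalmoscopes;
        one period is then 12.5 ns.
    n_bins
        Number of TCSPC time bins spanning one period.
    bin_width_s
        Duration of one bin in seconds.  ``n_bins * bin_width_s`` must not
        exceed the laser period.
    """

    rep_frequency_hz: float = 8.0e7
    n_bins: int = 256
    bin_width_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rep_frequency_hz <= 0:
            raise ValueError("rep_frequency_hz must be positive")
        if self.n_bins < 8:
            raise ValueError(f"n_bins must be >= 8, got {self.n_bins}")
        if self.bin_width_s is None:
            object.__setattr__(self, "bin_width_s", self.period_s / self.n_bins)
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be positive")
        if self.n_bins * self.bin_width_s > self.period_s * (1 + 1e-9):
            raise ValueError(
                "time axis exceeds the laser period: "
                f"{self.n_bins} * {self.bin_width_s} > {self.period_s}"
            )

    @property
    def period_s(self) -> float:
        return 1.0 / self.rep_frequency_hz

    @property
    def angular_frequency(self) -> float:
        """First-harmonic angular frequency, 2*pi*rep_frequency_hz."""
        return 2.0 * math.pi * self.rep_frequency_hz

    def bin_centers_s(self) -> np.ndarray:
        """Time coordinate of every bin center (seconds)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_s

    def bin_centers_ps(self) -> np.ndarray:
        return self.bin_centers_s() * 1e12

    @property
    def period_ps(self) -> float:
        return self.period_s * 1e12

    @property
    def bin_width_ps(self) -> float:
        return self.bin_width_s * 1e12


class ScanDirection(str, enum.Enum):
    forward = "forward"
    backward = "backward"
    combined = "combined"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class HistogramCube:
    """Per-pixel TCSPC histograms: ``counts[row, col, bin]`` photon counts."""

    counts: np.ndarray
    calibration: TimingCalibration
    scan_direction: ScanDirection = ScanDirection.combined

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError(f"counts must be 3-D, got ndim={self.counts.ndim}")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(np.isfinite(self.counts)):
                raise ValueError("counts contain non-finite values")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.shape[2] != self.calibration.n_bins:
            raise ValueError(
                f"cube has {self.counts.shape[2]} time bins but calibration "
                f"declares {self.calibration.n_bins}"
            )
        if isinstance(self.scan_direction, str):
            self.scan_direction = ScanDirection(self.scan_direction)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]


@dataclass
class CellMask:
    """Label image defining cell interiors.

    Label 0 encodes background and the single-pixel hand-drawn borders;
    label k > 0 marks the interior pixels of cell k.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def cell_labels(self) -> np.ndarray:
        """Sorted positive labels present in the mask."""
        u = np.unique(self.labels)
        return u[u > 0]

    def validate_connectivity(self) -> None:
        """Check that every positive label is one 4-connected component."""
        from skimage.measure import label as cc_label

        for k in self.cell_labels():
            ncomp = cc_label(self.labels == k, connectivity=1).max()
            if ncomp != 1:
                raise ValueError(
                    f"label {k} forms {ncomp} 4-connected components"
                )


@dataclass
class CellDecay:
    """One aggregated decay histogram per cell."""

    label: int
    histogram: np.ndarray
    pixel_count: int
    total_photons: int
    touches_edge: bool = False

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram)
        if self.histogram.ndim != 1:
            raise ValueError("histogram must be 1-D")
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")
        if int(self.histogram.sum()) != int(self.total_photons):
            raise ValueError("total_photons does not equal sum(histogram)")


class Channel(str, enum.Enum):
    """Excitation / emission-band imaging paradigms."""

    NIR_765 = "765/NIR"
    LSC_532 = "532/LSC"
    LSC_473 = "473/LSC"
    SSC_473 = "473/SSC"


class Meridian(str, enum.Enum):
    temporal = "temporal"
    inferior = "inferior"
    none = "none"


_VALID_ECC = (0.0, 2.0, 8.0, 12.0)


@dataclass
class AcquisitionMetadata:
    """Acquisition sidecar: who/where/how an image was taken."""

    subject_id: str
    age_years: float
    channel: Channel
    eccentricity_deg: float
    axial_length_mm: float
    image_px_per_side: int
    meridian: Meridian = Meridian.none
    visit_date: str = ""
    fov_deg: float = 1.4

    def __post_init__(self) -> None:
        if isinstance(self.channel, str):
            self.channel = Channel(self.channel)
        if isinstance(self.meridian, str):
            self.meridian = Meridian(self.meridian)
        if not (15.0 < self.axial_length_mm < 35.0):
            raise ValueError(
                f"axial_length_mm {self.axial_length_mm} outside plausible (15, 35) mm"
            )
        if self.fov_deg <= 0:
            raise ValueError("fov_deg must be positive")
        if self.eccentricity_deg not in _VALID_ECC:
            raise ValueError(
                f"eccentricity_deg must be one of {_VALID_ECC}, got {self.eccentricity_deg}"
            )
        if self.image_px_per_side <= 0:
            raise ValueError("image_px_per_side must be positive")


@dataclass
class DecayFitResult:
    """Bi-exponential fit of one decay histogram.

    Component lifetimes are canonically ordered ``tau1_ps <= tau2_ps`` and
    ``a1`` is the normalized amplitude weight of the short component, so the
    amplitude-weighted mean lifetime is ``tau_m_ps = a1*tau1 + a2*tau2`` with
    ``a1 + a2 = 1``.
    """

    tau1_ps: float
    tau2_ps: float
    a1: float
    a2: float
    tau_m_ps: float
    amplitude: float
    background: float
    shift_bins: float
    chi2_reduced: float
    n_photons: int
    converged: bool

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.a1 <= 1 + 1e-9):
            raise ValueError(f"a1 out of [0, 1]: {self.a1}")
        if abs(self.a1 + self.a2 - 1.0) > 1e-9:
            raise ValueError("a1 + a2 must equal 1")
        if self.tau1_ps > self.tau2_ps + 1e-9:
            raise ValueError("tau1_ps must not exceed tau2_ps")
        lo, hi = sorted((self.tau1_ps, self.tau2_ps))
        if not (lo - 1e-6 <= self.tau_m_ps <= hi + 1e-6):
            raise ValueError("tau_m_ps must lie between tau1_ps and tau2_ps")
        if self.chi2_reduced < 0:
            raise ValueError("chi2_reduced must be non-negative")


@dataclass
class PhasorPoint:
    """First-harmonic phasor coordinates of a decay histogram.

    ``g`` and ``s`` are the real and imaginary Fourier components of the
    photon-normalized histogram evaluated at ``harmonic`` times the laser
    repetition frequency.  Any physical (non-negative) decay satisfies
    ``g**2 + s**2 <= 1``.
    """

    g: float
    s: float
    harmonic: int = 1
    n_photons: int = 0

    def __post_init__(self) -> None:
        if self.g**2 + self.s**2 > 1.0 + 1e-9:
            raise ValueError(
                f"(g, s) = ({self.g}, {self.s}) lies outside the unit circle"
            )

    @property
    def modulation(self) -> float:
        return math.hypot(self.g, self.s)

    @property
    def phase(self) -> float:
        return math.atan2(self.s, self.g)


@dataclass
class FitConfig:
    """Settings for bi-exponential maximum-likelihood fitting.

    ``min_photons`` implements the photon-count inclusion threshold (default
    300 photons per histogram); histograms below it are rejected rather than
    fitted.  ``irf_fwhm_ps`` is the FWHM of the Gaussian instrument response
    convolved into the model (None disables IRF convolution; combined with
    ``fit_from_peak`` this gives a classic tail fit).
    """

    min_photons: int = 300
    tau_bounds_ps: tuple = (10.0, 12000.0)
    n_starts: int = 4
    max_iter: int = 300
    tolerance: float = 1e-9
    fit_background: bool = True
    irf_fwhm_ps: Optional[float] = 120.0
    shift_bins: float = 0.0
    fit_from_peak: bool = False

    def __post_init__(self) -> None:
        if self.min_photons < 1:
            raise ValueError("min_photons must be >= 1")
        lo, hi = self.tau_bounds_ps
        if not (0 < lo < hi):
            raise ValueError("tau_bounds_ps must be ordered and positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.irf_fwhm_ps is not None and self.irf_fwhm_ps <= 0:
            raise ValueError("irf_fwhm_ps must be positive or None")


# ---------------------------------------------------------------------------
# cube I/O
# ---------------------------------------------------------------------------

def write_cube(cube: HistogramCube, path: Union[str, Path]) -> None:
    """Write a cube to the open HDF5 layout (``/counts``, ``/calibration/*``)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=cube.counts, compression="gzip", compression_opts=1)
        cal = f.create_group("calibration")
        cal.attrs["rep_frequency_hz"] = cube.calibration.rep_frequency_hz
        cal.attrs["n_bins"] = cube.calibration.n_bins
        cal.attrs["bin_width_s"] = cube.calibration.bin_width_s
        f.create_group("meta").attrs["scan_direction"] = cube.scan_direction.value


def _read_cube_hdf5(path: Path) -> HistogramCube:
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise FileFormatError(f"{path}: missing /counts dataset")
        if "calibration" not in f:
            raise FileFormatError(f"{path}: missing /calibration group")
        cal = f["calibration"].attrs
        for key in ("rep_frequency_hz", "n_bins", "bin_width_s"):
            if key not in cal:
                raise FileFormatError(f"{path}: calibration attribute '{key}' missing")
        calibration = TimingCalibration(
            rep_frequency_hz=float(cal["rep_frequency_hz"]),
            n_bins=int(cal["n_bins"]),
            bin_width_s=float(cal["bin_width_s"]),
        )
        counts = f["counts"][...]
        direction = ScanDirection.combined
        if "meta" in f and "scan_direction" in f["meta"].attrs:
            direction = ScanDirection(str(f["meta"].attrs["scan_direction"]))
    return HistogramCube(counts=counts, calibration=calibration, scan_direction=direction)


def _read_cube_tiff(path: Path, calibration: Optional[TimingCalibration]) -> HistogramCube:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FileFormatError(f"{path}: expected a multi-frame TIFF stack")
    # frames are (bin, row, col); the cube is (row, col, bin)
    counts = np.moveaxis(frames, 0, -1)
    if calibration is None:
        sidecar = path.with_suffix(path.suffix + ".calib.json")
        alt = path.with_suffix(".calib.json")
        sidecar = sidecar if sidecar.exists() else alt
        if not sidecar.exists():
            raise FileFormatError(
                f"{path}: TIFF cubes need a calibration — pass calibration= or "
                f"provide a sidecar '{alt.name}'"
            )
        with open(sidecar) as fh:
            d = json.load(fh)
        calibration = TimingCalibration(
            rep_frequency_hz=float(d["rep_frequency_hz"]),
            n_bins=int(d.get("n_bins", counts.shape[2])),
            bin_width_s=float(d["bin_width_s"]) if "bin_width_s" in d else None,
        )
    return HistogramCube(counts=counts, calibration=calibration)


def read_cube(
    path: Union[str, Path],
    calibration: Optional[TimingCalibration] = None,
) -> HistogramCube:
    """Read a TCSPC cube from HDF5 or multi-frame TIFF.

    HDF5 files are self-describing.  TIFF stacks (one frame per time bin)
    need a calibration, either passed explicitly or found in a
    ``<name>.calib.json`` sidecar with keys ``rep_frequency_hz``,
    ``n_bins`` and optionally ``bin_width_s``.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        return _read_cube_hdf5(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_cube_tiff(path, calibration)
    raise FileFormatError(f"{path}: unrecognized cube format '{path.suffix}'")


# ---------------------------------------------------------------------------
# mask I/O
# ---------------------------------------------------------------------------

def write_mask(mask: CellMask, path: Union[str, Path]) -> None:
    """Write a label mask as a single-channel 16-bit TIFF or PNG."""
    path = Path(path)
    labels = mask.labels
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed 16-bit range")
    arr = labels.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, arr)
    else:
        raise FileFormatError(f"{path}: unsupported mask format '{path.suffix}'")


def read_mask(path: Union[str, Path]) -> CellMask:
    """Read an 8/16-bit single-channel label image (TIFF or PNG)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        arr = iio.imread(path)
    else:
        raise FileFormatError(f"{path}: unsupported mask format '{path.suffix}'")
    if arr.ndim != 2:
        raise FileFormatError(
            f"{path}: masks must be single-channel, got shape {arr.shape}"
        )
    return CellMask(labels=arr.astype(np.int64))


# ---------------------------------------------------------------------------
# per-cell result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "label", "pixel_count", "total_photons",
    "tau1_ps", "tau2_ps", "a1", "a2", "tau_m_ps",
    "amplitude", "background", "shift_bins", "chi2_reduced",
    "n_photons", "converged", "g", "s",
]

_META_COLUMNS = [
    "subject_id", "age_years", "channel", "eccentricity_deg", "meridian",
    "visit_date", "axial_length_mm", "fov_deg", "image_px_per_side",
]


def write_results(
    cells: Union[pd.DataFrame, Sequence[dict]],
    path: Union[str, Path],
    metadata: Optional[AcquisitionMetadata] = None,
) -> pd.DataFrame:
    """Write per-cell records to CSV, one row per cell.

    Missing result columns are emitted as empty; acquisition metadata, when
    given, is broadcast into per-row columns so downstream group statistics
    can concatenate tables from many images.
    """
    df = pd.DataFrame(cells).copy()
    if "label" not in df.columns:
        raise ValueError("cell records need a 'label' column")
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if metadata is not None:
        meta = asdict(metadata)
        meta["channel"] = metadata.channel.value
        meta["meridian"] = metadata.meridian.value
        for col in _META_COLUMNS:
            df[col] = meta[col]
    cols = RESULT_COLUMNS + [c for c in df.columns if c not in RESULT_COLUMNS]
    df = df[cols]
    df.to_csv(path, index=False)
    return df


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-cell result CSV written by :func:`write_results`."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise FileFormatError(f"{path}: not a per-cell result table (no 'label')")
    return df
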