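"""Core data model and I/O for full-scan LC-MS runs.

A run is an ordered list of MS1 scans, each scan a pair of parallel arrays
(m/z, intensity).  Profile and centroid acquisitions are both represented as
plain point lists; no centroiding is performed, because every downstream
quantity (TIC, EIC, mass bins) is a sum over points and is well defined for
either mode.

Supported input formats: mzML 1.1, mzXML 3.x and ANDI-MS netCDF (the
netCDF-3 "classic" dialect written by instrument software).  mzData is an
obsolete dialect and is rejected with an explicit error.  All tabular output
is plain CSV (comma separator, ``.`` decimal, header row, UTF-8).

Retention times are stored in seconds internally; every user-facing table
and plot reports minutes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .binning import BinMatrix

logger = logging.getLogger(__name__)

SECONDS_PER_MINUTE = 60.0


class MassbinError(Exception):
    """Base class for errors raised by this package."""


class FormatError(MassbinError):
    """The input file could not be parsed as the expected format."""


class UnsupportedFormatError(FormatError):
    """The input is a recognized but unsupported dialect (e.g. mzData)."""


class EmptyRunError(FormatError):
    """The input contained no MS1 scans."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scan:
    """One MS1 acquisition: retention time plus parallel m/z / intensity arrays.

    Parameters
    ----------
    rt : float
        Retention time in seconds (non-negative).
    mz : ndarray
        Strictly ascending m/z values (Thomson).
    intensity : ndarray
        Non-negative ion intensities, same length as ``mz``.
    ms_level : int
        MS level of the acquisition (1 for full scan).
    """

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1 or len(mz) != len(inten):
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z values must be strictly ascending within a scan")
        if len(inten) and inten.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        if self.ms_level < 1:
            raise ValueError("ms_level must be a positive integer")

    @property
    def n_points(self) -> int:
        return len(self.mz)


def _make_scan(rt: float, mz: np.ndarray, intensity: np.ndarray,
               ms_level: int = 1) -> Scan:
    """Build a Scan from possibly unsorted points, merging duplicate m/z."""
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(mz) and not np.all(np.diff(mz) > 0):
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        uniq, inverse = np.unique(mz, return_inverse=True)
        if len(uniq) < len(mz):
            summed = np.zeros(len(uniq))
            np.add.at(summed, inverse, intensity)
            mz, intensity = uniq, summed
    return Scan(rt=float(rt), mz=mz, intensity=intensity, ms_level=ms_level)


@dataclass
class Run:
    """An ordered sequence of MS1 scans with acquisition metadata."""

    scans: list[Scan]
    source_name: str = ""
    mz_min: float = field(default=np.nan)
    mz_max: float = field(default=np.nan)
    rt_min: float = field(default=np.nan)
    rt_max: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not self.scans:
            raise EmptyRunError("a Run must contain at least one scan")
        rts = np.array([s.rt for s in self.scans])
        if np.any(np.diff(rts) < 0):
            self.scans = sorted(self.scans, key=lambda s: s.rt)
            rts = np.array([s.rt for s in self.scans])
        self.rt_min, self.rt_max = float(rts[0]), float(rts[-1])
        nonempty = [s for s in self.scans if s.n_points]
        if nonempty:
            self.mz_min = float(min(s.mz[0] for s in nonempty))
            self.mz_max = float(max(s.mz[-1] for s in nonempty))
        else:
            self.mz_min = self.mz_max = float("nan")

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def rts(self) -> np.ndarray:
        """Scan retention times in seconds."""
        return np.array([s.rt for s in self.scans])

    def total_intensity(self) -> float:
        """Summed intensity over all points in all scans (the total ion current)."""
        return float(sum(s.intensity.sum() for s in self.scans))


@dataclass
class TimeSeries:
    """A chromatogram: (retention time, intensity) pairs.

    Times are stored in seconds; :attr:`times_min` gives minutes for
    presentation, matching how retention times are reported to users.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    @property
    def times_min(self) -> np.ndarray:
        return self.times / SECONDS_PER_MINUTE

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Spectrum:
    """A mass spectrum: ascending m/z with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity must have equal length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly ascending")

    def __len__(self) -> int:
        return len(self.mz)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_EXTENSION_FORMATS = {
    ".mzml": "mzml",
    ".mzxml": "mzxml",
    ".cdf": "netcdf",
    ".nc": "netcdf",
    ".mzdata": "mzdata",
}


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in _EXTENSION_FORMATS:
        return _EXTENSION_FORMATS[ext]
    with open(path, "rb") as fh:
        head = fh.read(4096)
    if head[:3] == b"CDF":
        return "netcdf"
    if b"mzML" in head:
        return "mzml"
    if b"mzXML" in head:
        return "mzxml"
    if b"mzData" in head:
        return "mzdata"
    raise FormatError(f"could not recognize the format of {path!r}")


def _rt_seconds(value) -> float:
    """Convert a pyteomics retention-time value to seconds."""
    unit = getattr(value, "unit_info", None)
    rt = float(value)
    if unit in ("minute", "min"):
        return rt * SECONDS_PER_MINUTE
    # mzML default (and our writer) is seconds; mzXML retentionTime carries
    # an explicit unit via pyteomics.
    return rt


def _read_mzml(path: str) -> list[Scan]:
    from . import _mzml_reader

    scans: list[Scan] = []
    dropped = 0
    index = 0
    try:
        for spec in _mzml_reader.iter_spectra(path):
            index += 1
            if spec["ms_level"] != 1:
                dropped += 1
                continue
            if spec["rt"] is None:
                raise FormatError(
                    f"scan {index} of {path!r} has no scan start time")
            scans.append(_make_scan(spec["rt"], spec["mz"],
                                    spec["intensity"], ms_level=1))
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(
            f"failed to parse {path!r} as mzML near scan {index + 1}: {exc}"
        ) from exc
    if dropped:
        logger.info("dropped %d non-MS1 scans from %s", dropped, path)
    return scans


def _read_mzxml(path: str) -> list[Scan]:
    from pyteomics import mzxml

    scans: list[Scan] = []
    dropped = 0
    index = 0
    try:
        with mzxml.read(path) as reader:
            for spec in reader:
                index += 1
                level = int(spec.get("msLevel", 1))
                if level != 1:
                    dropped += 1
                    continue
                rt = _rt_seconds(spec["retentionTime"])
                scans.append(_make_scan(rt, spec["m/z array"],
                                        spec["intensity array"], ms_level=1))
    except Exception as exc:
        raise FormatError(
            f"failed to parse {path!r} as mzXML near scan {index + 1}: {exc}"
        ) from exc
    if dropped:
        logger.info("dropped %d non-MS1 scans from %s", dropped, path)
    return scans


def _read_netcdf(path: str) -> list[Scan]:
    """Read an ANDI-MS netCDF file (netCDF-3 classic)."""
    from scipy.io import netcdf_file

    try:
        with netcdf_file(path, "r", mmap=False) as nc:
            mass = np.asarray(nc.variables["mass_values"][:], dtype=float)
            inten = np.asarray(nc.variables["intensity_values"][:], dtype=float)
            times = np.asarray(nc.variables["scan_acquisition_time"][:], dtype=float)
            if "scan_index" in nc.variables:
                starts = np.asarray(nc.variables["scan_index"][:], dtype=int)
            else:
                counts = np.asarray(nc.variables["point_count"][:], dtype=int)
                starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"failed to parse {path!r} as ANDI netCDF: {exc}") from exc
    ends = np.concatenate([starts[1:], [len(mass)]])
    scans = []
    for i, (rt, lo, hi) in enumerate(zip(times, starts, ends)):
        if lo > hi or hi > len(mass):
            raise FormatError(f"inconsistent scan_index at scan {i + 1} of {path!r}")
        scans.append(_make_scan(rt, mass[lo:hi], inten[lo:hi], ms_level=1))
    return scans


def read_run(path: str, format: str = "auto") -> Run:
    """Read a full-scan LC-MS run into a :class:`Run`.

    Parameters
    ----------
    path : str
        Input file path.
    format : {"auto", "mzml", "mzxml", "netcdf"}
        With ``"auto"`` the format is sniffed from the file extension and,
        failing that, from magic content.

    Only MS1 scans are loaded; MSn scans are dropped with a logged count.
    mzData input is rejected as unsupported.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = _sniff_format(path)
    if fmt == "mzdata":
        raise UnsupportedFormatError(
            "mzData is an obsolete dialect and is not supported; "
            "convert to mzML or mzXML")
    readers = {"mzml": _read_mzml, "mzxml": _read_mzxml, "netcdf": _read_netcdf}
    if fmt not in readers:
        raise FormatError(f"unknown format {format!r}")
    scans = readers[fmt](path)
    if not scans:
        raise EmptyRunError(f"{path!r} contains no MS1 scans")
    name = os.path.splitext(os.path.basename(path))[0]
    return Run(scans=scans, source_name=name)


# ---------------------------------------------------------------------------
# CSV writers / readers
# ---------------------------------------------------------------------------


def write_timeseries_csv(series: TimeSeries, path: str) -> str:
    """Write a chromatogram as ``time_min,intensity`` CSV (times in minutes)."""
    df = pd.DataFrame({"time_min": series.times_min, "intensity": series.values})
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_timeseries_csv(path: str) -> TimeSeries:
    df = pd.read_csv(path)
    return TimeSeries(times=df["time_min"].to_numpy() * SECONDS_PER_MINUTE,
                      values=df["intensity"].to_numpy())


def write_spectrum_csv(spec: Spectrum, path: str) -> str:
    """Write a mass spectrum as ``mz,intensity`` CSV."""
    df = pd.DataFrame({"mz": spec.mz, "intensity": spec.intensity})
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_spectrum_csv(path: str) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy())


def write_matrix_csv(matrix: "BinMatrix", path: str) -> str:
    """Write a samples x bins matrix: columns ``sample,group`` then one per bin.

    Bin columns are labeled ``lo_hi`` from the grid edges.
    """
    df = pd.DataFrame(matrix.values, columns=matrix.grid.labels())
    df.insert(0, "group", matrix.groups)
    df.insert(0, "sample", matrix.samples)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_matrix_csv(path: str) -> "BinMatrix":
    """Read a matrix written by :func:`write_matrix_csv`.

    The bin grid is reconstructed from the ``lo_hi`` column labels.
    """
    from .binning import BinGrid, BinMatrix

    df = pd.read_csv(path)
    bin_cols = [c for c in df.columns if c not in ("sample", "group")]
    if not bin_cols:
        raise FormatError(f"{path!r} contains no bin columns")
    los = [float(c.split("_")[0]) for c in bin_cols]
    his = [float(c.split("_")[1]) for c in bin_cols]
    grid = BinGrid(mass_lo=los[0], mass_hi=his[-1], bin_size=his[0] - los[0])
    if grid.n_bins != len(bin_cols):
        raise FormatError(
            f"bin labels in {path!r} do not form a uniform grid")
    return BinMatrix(grid=grid,
                     samples=df["sample"].astype(str).tolist(),
                     groups=df["group"].astype(str).tolist(),
                     values=df[bin_cols].to_numpy(dtype=float))
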