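"""Mass binning: the retention-time-free spectral fingerprint.

The mass dimension of a run is divided into N fixed-width bins,
``N = ceil(mass_range / bin_size)`` (exactly ``mass_range / bin_size`` when
the range divides evenly), and each bin's value is the total intensity of
all ions, in all scans, whose m/z falls inside it.  The resulting vector is
a "fingerprint" of the sample that needs no peak detection and no retention
time alignment, and can be compared across samples with standard
chemometric tools (see :mod:`massbin.diffprofile`).

Bins are half-open ``[lo, hi)`` with the last bin closed at ``mass_hi``, and
edges are anchored at the user-supplied ``mass_lo`` (the instrument scan
floor, m/z 100, is the usual choice), so a size-2 grid from 100 produces the
even-numbered bins 100_102, 102_104, ... 1498_1500.  No point is ever
counted in two bins; points outside the grid are dropped with a logged
count, never clipped into the end bins, so the conservation law

    sum(bin values) + discarded intensity == total ion current

is exactly auditable.
"""

from __future__ import annotations

import logging
import math
import os
import zipfile
from dataclasses import dataclass, field
from io import StringIO
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .msdata_io import Run, TimeSeries

logger = logging.getLogger(__name__)

#: Above this bin count, eics_for_all_bins logs a warning: a small bin size
#: results in a large number of EIC files.
MANY_EICS_WARNING_THRESHOLD = 1000


def _fmt_edge(x: float) -> str:
    """Format a bin edge at the grid's precision (no trailing zeros)."""
    return f"{x:g}"


@dataclass(frozen=True)
class BinGrid:
    """A uniform m/z bin definition.

    ``edges`` has ``n_bins + 1`` entries: ``mass_lo + k * bin_size`` for
    ``k = 0 .. n_bins - 1`` plus a final edge at ``mass_hi`` (the last bin
    may be narrower than ``bin_size`` when the range does not divide evenly).
    """

    mass_lo: float
    mass_hi: float
    bin_size: float
    edges: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mass_lo >= self.mass_hi:
            raise ValueError(
                f"mass_lo ({self.mass_lo}) must be less than mass_hi ({self.mass_hi})")
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        n = math.ceil((self.mass_hi - self.mass_lo) / self.bin_size - 1e-12)
        edges = self.mass_lo + self.bin_size * np.arange(n + 1)
        edges[-1] = self.mass_hi
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> list[str]:
        """Bin labels ``"lo_hi"`` from the grid edges."""
        return [f"{_fmt_edge(lo)}_{_fmt_edge(hi)}"
                for lo, hi in zip(self.edges[:-1], self.edges[1:])]

    def bin_of(self, mz: np.ndarray) -> np.ndarray:
        """Bin index per point; -1 for points outside [mass_lo, mass_hi].

        Membership is half-open [lo, hi) except the last bin, closed at
        ``mass_hi``.
        """
        mz = np.asarray(mz, dtype=float)
        idx = np.searchsorted(self.edges, mz, side="right") - 1
        idx[mz == self.mass_hi] = self.n_bins - 1  # last bin is closed
        idx[(mz < self.mass_lo) | (mz > self.mass_hi)] = -1
        return idx


def make_grid(mass_lo: float, mass_hi: float, bin_size: float) -> BinGrid:
    """Build a :class:`BinGrid`; ``N = ceil((mass_hi - mass_lo) / bin_size)``."""
    return BinGrid(mass_lo=mass_lo, mass_hi=mass_hi, bin_size=bin_size)


@dataclass
class BinVector:
    """One sample's bin fingerprint under a grid."""

    grid: BinGrid
    values: np.ndarray
    sample: str = ""
    group: Optional[str] = None
    discarded_intensity: float = 0.0
    discarded_points: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_bins:
            raise ValueError("values length must equal the grid's bin count")
        if len(self.values) and self.values.min() < 0:
            raise ValueError("bin values must be non-negative")


@dataclass
class BinMatrix:
    """Samples x bins matrix with per-sample group labels."""

    grid: BinGrid
    samples: list[str]
    groups: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x bins)")
        if not (len(self.samples) == len(self.groups) == self.values.shape[0]):
            raise ValueError("samples, groups and value rows must align")
        if self.values.shape[1] != self.grid.n_bins:
            raise ValueError("value columns must equal the grid's bin count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def bin_run(run: Run, grid: BinGrid, sample: Optional[str] = None,
            group: Optional[str] = None) -> BinVector:
    """Total intensity of all ions, in all scans, per bin of ``grid``.

    Points outside ``[mass_lo, mass_hi]`` are discarded; their count and
    summed intensity are recorded on the result and logged.
    """
    pts = [s for s in run.scans if s.n_points]
    if pts:
        mz = np.concatenate([s.mz for s in pts])
        inten = np.concatenate([s.intensity for s in pts])
    else:
        mz = np.empty(0)
        inten = np.empty(0)
    idx = grid.bin_of(mz)
    inside = idx >= 0
    values = np.bincount(idx[inside], weights=inten[inside],
                         minlength=grid.n_bins)
    n_out = int((~inside).sum())
    out_intensity = float(inten[~inside].sum())
    if n_out:
        logger.info("discarded %d points (total intensity %g) outside the "
                    "grid [%g, %g]", n_out, out_intensity,
                    grid.mass_lo, grid.mass_hi)
    return BinVector(grid=grid, values=values,
                     sample=sample if sample is not None else run.source_name,
                     group=group,
                     discarded_intensity=out_intensity, discarded_points=n_out)


def aggregate_bins(vector: BinVector, coarse: BinGrid,
                   atol_edges: float = 1e-9) -> BinVector:
    """Re-express a fine bin vector on a coarser grid whose edges align.

    Every edge of ``coarse`` must coincide (within ``atol_edges``) with an
    edge of the fine grid; fine bins are then summed within each coarse bin.
    """
    fine = vector.grid
    pos = np.searchsorted(fine.edges, coarse.edges)
    pos = np.clip(pos, 0, len(fine.edges) - 1)
    # snap to the nearest fine edge and verify alignment
    for k, e in enumerate(coarse.edges):
        cand = pos[k]
        if cand > 0 and abs(fine.edges[cand - 1] - e) < abs(fine.edges[cand] - e):
            pos[k] = cand - 1
        if abs(fine.edges[pos[k]] - e) > atol_edges:
            raise ValueError(
                f"coarse edge {e:g} does not align with the fine grid")
    values = np.array([vector.values[a:b].sum()
                       for a, b in zip(pos[:-1], pos[1:])])
    return BinVector(grid=coarse, values=values, sample=vector.sample,
                     group=vector.group,
                     discarded_intensity=vector.discarded_intensity,
                     discarded_points=vector.discarded_points)


def refine_check(fine: BinVector, coarse: BinVector, rtol: float = 1e-9) -> bool:
    """True when the fine vector aggregates to the coarse one within ``rtol``.

    Exact float equality is not required (summation order differs); the
    comparison is element-wise at relative tolerance.
    """
    agg = aggregate_bins(fine, coarse.grid)
    scale = max(coarse.values.max(), 1.0) if len(coarse.values) else 1.0
    return bool(np.allclose(agg.values, coarse.values, rtol=rtol,
                            atol=rtol * scale))


def group_bin(runs: Sequence[Run], grid: BinGrid,
              groups: Sequence[str]) -> BinMatrix:
    """Bin every run under a shared grid into a samples x bins matrix.

    Sample names come from each run's ``source_name``; duplicates are
    deduplicated with numeric suffixes.
    """
    if len(runs) == 0:
        raise ValueError("group_bin requires at least one run")
    if len(groups) != len(runs):
        raise ValueError(
            f"got {len(groups)} group labels for {len(runs)} runs")
    names: list[str] = []
    seen: dict[str, int] = {}
    for run in runs:
        base = run.source_name or "sample"
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base}_{seen[base]}")
    values = np.vstack([bin_run(r, grid).values for r in runs])
    return BinMatrix(grid=grid, samples=names, groups=list(map(str, groups)),
                     values=values)


def _eic_halfopen(run: Run, lo: float, hi: float, closed_right: bool) -> TimeSeries:
    """EIC using bin membership (half-open [lo, hi); closed for the last bin)."""
    side = "right" if closed_right else "left"
    values = np.empty(len(run.scans))
    for i, s in enumerate(run.scans):
        if s.n_points:
            a = np.searchsorted(s.mz, lo, side="left")
            b = np.searchsorted(s.mz, hi, side=side)
            values[i] = s.intensity[a:b].sum()
        else:
            values[i] = 0.0
    return TimeSeries(times=run.rts, values=values)


def eics_for_all_bins(run: Run, grid: BinGrid, out_dir: str,
                      zip_name: str = "bin_eics.zip") -> str:
    """Write one EIC CSV per bin, bundled into a zip; returns the zip path.

    Each EIC uses the bin's half-open membership so the per-bin series sum
    exactly to the bin totals (this deliberately differs from the
    closed-interval user EIC of :mod:`massbin.chromatograms`).
    """
    if grid.n_bins > MANY_EICS_WARNING_THRESHOLD:
        logger.warning("a small bin size results in a large number of EIC "
                       "files (%d bins)", grid.n_bins)
    os.makedirs(out_dir, exist_ok=True)
    zip_path = os.path.join(out_dir, zip_name)
    times_min = run.rts / 60.0
    last = grid.n_bins - 1
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, label in enumerate(grid.labels()):
            series = _eic_halfopen(run, grid.edges[i], grid.edges[i + 1],
                                   closed_right=(i == last))
            buf = StringIO()
            pd.DataFrame({"time_min": times_min,
                          "intensity": series.values}).to_csv(
                buf, index=False, lineterminator="\n")
            zf.writestr(f"eic_bin_{label}.csv", buf.getvalue())
    return zip_path
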