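"""Chromatogram and averaged-spectrum extraction.

TIC, BPC and EIC all produce one point per scan so every chromatogram from a
run shares the same time axis; scans with zero points contribute zeros rather
than being skipped.  EIC mass windows are CLOSED intervals [lo, hi]: a window
written "608-610" contains an ion at exactly m/z 610.  (Mass *bins* use
half-open intervals; see :mod:`massbin.binning`.)
"""

from __future__ import annotations

import logging

import numpy as np

from .msdata_io import Run, Spectrum, TimeSeries

logger = logging.getLogger(__name__)


def total_ion_chromatogram(run: Run) -> TimeSeries:
    """Per-scan sum of all ion intensities versus retention time."""
    values = np.array([s.intensity.sum() if s.n_points else 0.0 for s in run.scans])
    return TimeSeries(times=run.rts, values=values, label="TIC")


def base_peak_chromatogram(run: Run) -> TimeSeries:
    """Per-scan maximum ion intensity versus retention time.

    The BPC traces the most intense ion in each scan and therefore shows less
    baseline noise than the TIC.
    """
    values = np.array([s.intensity.max() if s.n_points else 0.0 for s in run.scans])
    return TimeSeries(times=run.rts, values=values, label="BPC")


def extracted_ion_chromatogram(run: Run, mz_lo: float, mz_hi: float) -> TimeSeries:
    """Per-scan summed intensity restricted to the closed window [mz_lo, mz_hi]."""
    if mz_lo >= mz_hi:
        raise ValueError(f"mz_lo ({mz_lo}) must be less than mz_hi ({mz_hi})")
    if np.isfinite(run.mz_min) and (mz_hi < run.mz_min or mz_lo > run.mz_max):
        logger.warning(
            "EIC window [%g, %g] is outside the run's m/z range [%g, %g]; "
            "the chromatogram is all zero", mz_lo, mz_hi, run.mz_min, run.mz_max)
    values = np.empty(len(run.scans))
    for i, s in enumerate(run.scans):
        if s.n_points:
            lo = np.searchsorted(s.mz, mz_lo, side="left")
            hi = np.searchsorted(s.mz, mz_hi, side="right")
            values[i] = s.intensity[lo:hi].sum()
        else:
            values[i] = 0.0
    return TimeSeries(times=run.rts, values=values,
                      label=f"EIC {mz_lo:g}-{mz_hi:g}")


def averaged_mass_spectrum(run: Run, rt_lo: float, rt_hi: float,
                           mz_decimals: int = 2) -> Spectrum:
    """Per-scan averaged mass spectrum over the RT window [rt_lo, rt_hi] seconds.

    All points of scans inside the window are pooled, grouped by m/z rounded
    to ``mz_decimals``, and each group's summed intensity is divided by the
    number of scans in the window.  Averaging per scan (rather than raw
    summation) makes spectra comparable between windows of different widths.
    """
    if rt_lo >= rt_hi:
        raise ValueError(f"rt_lo ({rt_lo}) must be less than rt_hi ({rt_hi})")
    window = [s for s in run.scans if rt_lo <= s.rt <= rt_hi]
    if not window:
        raise ValueError(
            f"no scans in the RT window [{rt_lo:g}, {rt_hi:g}] s "
            f"(run spans [{run.rt_min:g}, {run.rt_max:g}] s)")
    n_scans = len(window)
    mz_all = np.concatenate([s.mz for s in window if s.n_points] or [np.empty(0)])
    int_all = np.concatenate([s.intensity for s in window if s.n_points]
                             or [np.empty(0)])
    if len(mz_all) == 0:
        return Spectrum(mz=np.empty(0), intensity=np.empty(0))
    mz_rounded = np.round(mz_all, mz_decimals)
    uniq, inverse = np.unique(mz_rounded, return_inverse=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, int_all)
    return Spectrum(mz=uniq, intensity=summed / n_scans,
                    label=f"avg MS {rt_lo / 60:g}-{rt_hi / 60:g} min")
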