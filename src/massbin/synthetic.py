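"""Synthetic LC-MS runs and two-group studies with known ground truth.

The generator emulates the structure the binning method exploits: each
compound is a Gaussian chromatographic peak (amplitude x exp(-(t-t0)^2 /
(2 sigma^2))) carried by one or a few ions at fixed m/z, sitting on an
exponential baseline (heavier-tailed than Gaussian and non-negative, as
ion-trap baseline signal is) scattered uniformly in m/z.  The two-group
study mirrors a 12-vs-11 replicate design: a common set of shared peaks
with log-normal sample-to-sample amplitude variation, plus a handful of
"spiked" peaks whose amplitude is multiplied by a known fold in one group.
The returned :class:`StudyTruth` records exactly which bins carry the
effect, so recovery can be scored without instrument data.

Everything is deterministic under a seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .binning import BinGrid, make_grid
from .msdata_io import Run, _make_scan

DEFAULT_RT_SIGMA = 6.0       # s, typical HPLC peak width for a 10-40 min run
DEFAULT_RT_SPAN = 600.0      # s of simulated gradient
DEFAULT_SCAN_INTERVAL = 5.0  # s between scans
DEFAULT_SHARED_AMPLITUDE = 1.0e5
DEFAULT_SPIKED_AMPLITUDE = 2.0e4  # small vs total signal, so sum
                                  # normalization barely dilutes the fold
DEFAULT_NOISE_POINTS = 40
DEFAULT_CV = 0.15


@dataclass(frozen=True)
class PeakSpec:
    """One chromatographic peak carried by an ion at fixed m/z.

    ``mz_sigma > 0`` spreads the ion over five profile-mode points with
    Gaussian weights summing to one, so the total intensity is unchanged;
    ``mz_sigma = 0`` gives a single centroid point.  ``isotope_ratios`` adds
    satellite ions at (delta m/z, relative amplitude) sharing the peak's
    elution profile — e.g. a [2M-1] dimer species.
    """

    mz_center: float
    rt_center: float
    rt_sigma: float
    amplitude: float
    mz_sigma: float = 0.0
    isotope_ratios: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.rt_sigma < 0 or self.mz_sigma < 0:
            raise ValueError("sigmas must be non-negative")

    def ion_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(m/z, fractional amplitude) of every point this peak contributes."""
        if self.mz_sigma > 0:
            offsets = np.linspace(-2 * self.mz_sigma, 2 * self.mz_sigma, 5)
            w = np.exp(-offsets ** 2 / (2 * self.mz_sigma ** 2))
            w /= w.sum()
            mzs = self.mz_center + offsets
        else:
            mzs = np.array([self.mz_center])
            w = np.array([1.0])
        for delta, rel in self.isotope_ratios:
            mzs = np.concatenate([mzs, [self.mz_center + delta]])
            w = np.concatenate([w, [rel]])
        return mzs, w


@dataclass
class StudyTruth:
    """Ground truth of a simulated two-group study."""

    samples: list[str]
    groups: list[str]
    spiked_bins: list[int]
    spiked_mz: list[float]
    shared_mz: list[float]
    effect_fold: float
    cv: float
    noise_level: float
    seed: int
    grid_mass_lo: float
    grid_mass_hi: float
    grid_bin_size: float
    peaks_by_sample: dict[str, list[PeakSpec]] = field(default_factory=dict)

    def to_json(self, path: str) -> str:
        payload = asdict(self)
        payload["peaks_by_sample"] = {
            name: [asdict(p) for p in peaks]
            for name, peaks in self.peaks_by_sample.items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        return path


def simulate_run(peaks: Sequence[PeakSpec], rt_grid: Sequence[float],
                 noise_level: float = 0.0,
                 n_noise_points: int = DEFAULT_NOISE_POINTS,
                 noise_mz_range: tuple[float, float] = (100.0, 1500.0),
                 seed: int = 0, source_name: str = "synthetic") -> Run:
    """Simulate one full-scan run.

    Every scan contains, for every peak, its ion points scaled by the
    Gaussian elution profile at that scan's time, plus ``n_noise_points``
    baseline points with exponentially distributed intensities (mean
    ``noise_level``) at uniform m/z.  With ``noise_level = 0`` no baseline
    points are added and all totals have closed forms.
    """
    rt_grid = np.asarray(rt_grid, dtype=float)
    if len(rt_grid) == 0:
        raise ValueError("rt_grid must be non-empty")
    if np.any(np.diff(rt_grid) <= 0):
        raise ValueError("rt_grid must be strictly ascending")
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    rng = np.random.default_rng(seed)

    ion_mz: list[np.ndarray] = []
    ion_w: list[np.ndarray] = []
    profiles = np.empty((len(rt_grid), len(peaks)))
    for j, p in enumerate(peaks):
        mzs, w = p.ion_points()
        ion_mz.append(mzs)
        ion_w.append(w * p.amplitude)
        if p.rt_sigma > 0:
            profiles[:, j] = np.exp(-(rt_grid - p.rt_center) ** 2
                                    / (2 * p.rt_sigma ** 2))
        else:
            profiles[:, j] = (rt_grid == p.rt_center).astype(float)

    flat_mz = (np.concatenate(ion_mz) if peaks else np.empty(0))
    flat_w = (np.concatenate(ion_w) if peaks else np.empty(0))
    owner = (np.concatenate([np.full(len(m), j) for j, m in enumerate(ion_mz)])
             if peaks else np.empty(0, dtype=int))

    scans = []
    for i, t in enumerate(rt_grid):
        mz = flat_mz
        inten = flat_w * profiles[i, owner] if len(flat_mz) else np.empty(0)
        if noise_level > 0 and n_noise_points > 0:
            nmz = rng.uniform(*noise_mz_range, size=n_noise_points)
            nint = rng.exponential(noise_level, size=n_noise_points)
            mz = np.concatenate([mz, nmz])
            inten = np.concatenate([inten, nint])
        scans.append(_make_scan(t, mz, inten, ms_level=1))
    return Run(scans=scans, source_name=source_name)


def simulate_two_group_study(
        n_a: int = 12, n_b: int = 11,
        grid: Optional[BinGrid] = None,
        n_shared_peaks: int = 60, n_spiked: int = 10,
        effect_fold: float = 8.0, cv: float = DEFAULT_CV,
        noise_level: Optional[float] = None,
        seed: int = 0,
        rt_span: float = DEFAULT_RT_SPAN,
        scan_interval: float = DEFAULT_SCAN_INTERVAL,
        group_names: tuple[str, str] = ("HL", "LL"),
        n_noise_points: int = DEFAULT_NOISE_POINTS,
) -> tuple[list[Run], StudyTruth]:
    """Simulate a two-group study with known differential bins.

    Group A (``n_a`` samples) carries ``n_spiked`` peaks multiplied by
    ``effect_fold``; all peaks vary log-normally between samples with
    coefficient of variation ``cv``.  The spiked peaks sit at the centers of
    distinct bins that hold no shared peak, and are listed in the returned
    truth manifest.  ``noise_level`` defaults to 1% of the largest shared
    amplitude.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least two samples")
    if effect_fold <= 0:
        raise ValueError("effect_fold must be positive")
    if grid is None:
        grid = make_grid(100.0, 1500.0, 2.0)
    rng = np.random.default_rng(seed)

    mz_lo_margin = grid.mass_lo + 0.01 * (grid.mass_hi - grid.mass_lo)
    mz_hi_margin = grid.mass_hi - 0.05 * (grid.mass_hi - grid.mass_lo)
    shared_mz = rng.uniform(mz_lo_margin, mz_hi_margin, size=n_shared_peaks)
    shared_rt = rng.uniform(0.1 * rt_span, 0.9 * rt_span, size=n_shared_peaks)
    shared_amp = DEFAULT_SHARED_AMPLITUDE * rng.uniform(
        0.5, 2.0, size=n_shared_peaks)

    shared_bins = set(grid.bin_of(shared_mz).tolist())
    centers = (grid.edges[:-1] + grid.edges[1:]) / 2
    candidates = [i for i in range(grid.n_bins)
                  if i not in shared_bins
                  and mz_lo_margin <= centers[i] <= mz_hi_margin]
    if len(candidates) < n_spiked:
        raise ValueError("grid too small for the requested number of "
                         "spiked bins outside shared-peak bins")
    spiked_bins = sorted(rng.choice(candidates, size=n_spiked,
                                    replace=False).tolist())
    spiked_mz = centers[spiked_bins]
    if np.any(spiked_mz < grid.mass_lo) or np.any(spiked_mz > grid.mass_hi):
        raise ValueError("spiked peak m/z outside the grid")
    spiked_rt = rng.uniform(0.1 * rt_span, 0.9 * rt_span, size=n_spiked)
    spiked_amp = DEFAULT_SPIKED_AMPLITUDE * rng.uniform(0.75, 1.5,
                                                        size=n_spiked)

    if noise_level is None:
        noise_level = 0.01 * float(shared_amp.max())

    sigma_ln = float(np.sqrt(np.log1p(cv ** 2)))
    mu_ln = -0.5 * sigma_ln ** 2  # mean-1 log-normal

    rt_grid = np.arange(0.0, rt_span + scan_interval / 2, scan_interval)
    runs: list[Run] = []
    samples: list[str] = []
    groups: list[str] = []
    peaks_by_sample: dict[str, list[PeakSpec]] = {}
    max_seed = 2 ** 31 - 1
    for k in range(n_a + n_b):
        in_a = k < n_a
        gname = group_names[0] if in_a else group_names[1]
        idx = k + 1 if in_a else k - n_a + 1
        name = f"{gname}_{idx:02d}"
        factors_shared = rng.lognormal(mu_ln, sigma_ln, size=n_shared_peaks)
        factors_spiked = rng.lognormal(mu_ln, sigma_ln, size=n_spiked)
        fold = effect_fold if in_a else 1.0
        peaks = [PeakSpec(mz_center=float(m), rt_center=float(t),
                          rt_sigma=DEFAULT_RT_SIGMA,
                          amplitude=float(a * f))
                 for m, t, a, f in zip(shared_mz, shared_rt, shared_amp,
                                       factors_shared)]
        peaks += [PeakSpec(mz_center=float(m), rt_center=float(t),
                           rt_sigma=DEFAULT_RT_SIGMA,
                           amplitude=float(a * f * fold))
                  for m, t, a, f in zip(spiked_mz, spiked_rt, spiked_amp,
                                        factors_spiked)]
        run_seed = int(rng.integers(0, max_seed))
        runs.append(simulate_run(
            peaks, rt_grid, noise_level=noise_level,
            n_noise_points=n_noise_points,
            noise_mz_range=(grid.mass_lo, grid.mass_hi),
            seed=run_seed, source_name=name))
        samples.append(name)
        groups.append(gname)
        peaks_by_sample[name] = peaks

    truth = StudyTruth(samples=samples, groups=groups,
                       spiked_bins=list(spiked_bins),
                       spiked_mz=[float(m) for m in spiked_mz],
                       shared_mz=[float(m) for m in shared_mz],
                       effect_fold=effect_fold, cv=cv,
                       noise_level=float(noise_level), seed=seed,
                       grid_mass_lo=grid.mass_lo, grid_mass_hi=grid.mass_hi,
                       grid_bin_size=grid.bin_size,
                       peaks_by_sample=peaks_by_sample)
    return runs, truth


def write_study(runs: Sequence[Run], truth: StudyTruth, out_dir: str) -> dict:
    """Write a simulated study as mzML files plus a truth manifest JSON."""
    from ._writers import write_mzml

    os.makedirs(out_dir, exist_ok=True)
    manifest = {}
    for run in runs:
        path = os.path.join(out_dir, f"{run.source_name}.mzML")
        write_mzml(run, path)
        manifest[run.source_name] = path
    truth_path = os.path.join(out_dir, "truth.json")
    truth.to_json(truth_path)
    manifest["truth"] = truth_path
    return manifest
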