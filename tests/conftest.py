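import numpy as np
import pytest

import massbin as mb


@pytest.fixture
def fixture_run() -> mb.Run:
    """Two-scan toy run: scan1 rt=6 s mz=[100,200] int=[10,30]; scan2 rt=12 s
    mz=[150] int=[5]."""
    return mb.Run(scans=[
        mb.Scan(rt=6.0, mz=np.array([100.0, 200.0]),
                intensity=np.array([10.0, 30.0])),
        mb.Scan(rt=12.0, mz=np.array([150.0]), intensity=np.array([5.0])),
    ], source_name="fixture")


@pytest.fixture
def empty_scan_run() -> mb.Run:
    return mb.Run(scans=[mb.Scan(rt=t, mz=np.empty(0), intensity=np.empty(0))
                         for t in (0.0, 5.0, 10.0)], source_name="empty")


def random_run(seed: int, n_scans: int = 20, n_points: int = 50,
               mz_range=(100.0, 1500.0)) -> mb.Run:
    """A run of random points, for conservation/refinement properties."""
    rng = np.random.default_rng(seed)
    scans = []
    for i in range(n_scans):
        mz = np.sort(rng.uniform(*mz_range, size=n_points))
        mz = np.unique(mz)
        inten = rng.exponential(100.0, size=len(mz))
        scans.append(mb.Scan(rt=5.0 * i, mz=mz, intensity=inten))
    return mb.Run(scans=scans, source_name=f"random{seed}")


@pytest.fixture(scope="session")
def small_study():
    """A reduced two-group study shared by unit tests (fast to simulate)."""
    runs, truth = mb.simulate_two_group_study(
        n_a=6, n_b=5, n_shared_peaks=30, n_spiked=5, seed=7)
    grid = mb.make_grid(100.0, 1500.0, 2.0)
    matrix = mb.group_bin(runs, grid, truth.groups)
    return runs, truth, grid, matrix


@pytest.fixture(scope="session")
def full_study():
    """The full 12-vs-11 study at the default conditions, one seed."""
    runs, truth = mb.simulate_two_group_study(seed=0)
    grid = mb.make_grid(100.0, 1500.0, 2.0)
    matrix = mb.group_bin(runs, grid, truth.groups)
    return runs, truth, grid, matrix
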