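import io

import numpy as np
import pytest

from mzlod.model import MzmlDialect, PointSet
from mzlod.mzml import write_mzml
from mzlod.synth import GenConfig, gen_points, points_to_spectra


@pytest.fixture(scope="session")
def small_cloud():
    """~3k-point map: 5 envelopes + 500 noise points straddling the floor."""
    cfg = GenConfig.random(seed=11, n_envelopes=5, noise_count=500)
    points, labels = gen_points(cfg)
    return points, labels, cfg


@pytest.fixture(scope="session")
def small_spectra(small_cloud):
    points, _, _ = small_cloud
    return points_to_spectra(points)


@pytest.fixture(scope="session")
def dense_cloud():
    """>= 10k-point map for query-oracle property tests."""
    cfg = GenConfig.random(seed=23, n_envelopes=20, noise_count=9000,
                           noise_intensity_range=(0.05, 50.0))
    points, labels = gen_points(cfg)
    assert len(points) >= 10_000
    return points, labels


def mzml_bytes(spectra, dialect=None) -> bytes:
    buf = io.BytesIO()
    write_mzml(spectra, buf, dialect or MzmlDialect())
    return buf.getvalue()


@pytest.fixture(scope="session")
def small_mzml(small_spectra) -> bytes:
    return mzml_bytes(small_spectra)


def random_windows(rng, count, mz_range=(400.0, 1600.0), rt_range=(0.0, 600.0)):
    """Seeded random viewports spanning zoomed-in to map-wide extents."""
    from mzlod.model import ViewWindow

    windows = []
    for _ in range(count):
        mz0 = rng.uniform(*mz_range)
        mzw = rng.uniform(0.5, (mz_range[1] - mz_range[0]) * 0.6)
        rt0 = rng.uniform(*rt_range)
        rtw = rng.uniform(1.0, (rt_range[1] - rt_range[0]) * 0.6)
        windows.append(ViewWindow(mz0, mz0 + mzw, rt0, rt0 + rtw))
    return windows


def sort_oracle_top_n(points, n):
    """Independent selection oracle: full sort by the documented order."""
    ranked = sorted(points, key=lambda p: (-p.intensity, p.mz, p.rt, p.id))
    return ranked[:n]


def grid_points(nx=20, ny=20, intensity=None):
    """A deterministic lattice cloud for hand-checkable tree tests."""
    mz, rt = np.meshgrid(np.linspace(400, 500, nx), np.linspace(0, 100, ny))
    mz, rt = mz.ravel(), rt.ravel()
    if intensity is None:
        intensity = 1.0 + np.arange(mz.size, dtype=float)
    return PointSet(np.arange(mz.size), mz, rt, np.asarray(intensity, dtype=float))
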