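"""Seeded synthetic MS1 point clouds.

Emulates the signal structure of a centroided LC-MS survey map: each
analyte at one charge state produces an *isotopic envelope* — a comb of
isotope traces spaced 1.003355/z Th apart (the C13 neutron mass
difference over the charge), each trace a Gaussian elution profile over
retention time, with abundances decaying geometrically across isotopes.
Sub-threshold noise points are sprinkled uniformly over the map.  The
geometric decay and single-Gaussian elution are deliberate synthetic
conventions: simple, seed-reproducible, and sufficient to exercise
culling, indexing and viewport queries; they do not model averagine
isotope patterns or chromatographic tailing.

Points are rasterized onto a regular RT scan grid (one spectrum per
``scan_interval``), so generated clouds round-trip through mzML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import MzmlDialect, PointSet, SpectrumRecord
from .mzml import write_mzml

__all__ = [
    "NEUTRON_SPACING",
    "EnvelopeSpec",
    "GenConfig",
    "gen_points",
    "gen_mzml",
    "points_to_spectra",
]

NEUTRON_SPACING = 1.003355  # Da; C13-C12 mass difference

NOISE_LABEL = -1


@dataclass(frozen=True)
class EnvelopeSpec:
    """One isotopic envelope: an analyte at one charge state.

    Isotope ``k`` sits at ``monoisotopic_mz + k * NEUTRON_SPACING/charge``
    with peak height ``base_intensity * isotope_decay**k`` and a Gaussian
    elution profile ``exp(-(t - rt_center)^2 / (2 rt_sigma^2))``.
    """

    monoisotopic_mz: float
    charge: int = 1
    num_isotopes: int = 4
    base_intensity: float = 1000.0
    isotope_decay: float = 0.6
    rt_center: float = 300.0
    rt_sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.monoisotopic_mz <= 0:
            raise ValueError("monoisotopic_mz must be positive")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        if not (0 < self.isotope_decay <= 1):
            raise ValueError("isotope_decay must be in (0, 1]")
        if self.num_isotopes < 1 or self.rt_sigma <= 0 or self.base_intensity <= 0:
            raise ValueError("invalid envelope geometry")

    def isotope_mz(self, k: int) -> float:
        return self.monoisotopic_mz + k * NEUTRON_SPACING / self.charge

    def trace_intensity(self, k: int, t: np.ndarray) -> np.ndarray:
        peak = self.base_intensity * self.isotope_decay ** k
        return peak * np.exp(-((t - self.rt_center) ** 2) / (2 * self.rt_sigma ** 2))


@dataclass(frozen=True)
class GenConfig:
    """Seeded description of a synthetic map.

    Defaults describe a small but structured MS1 run: a 400-1600 Th mass
    range over a 10-minute gradient sampled every second, envelopes of a
    few isotopes eluting over ~10 s, and a noise carpet whose intensity
    range straddles the conventional culling floor of 1.
    """

    seed: int = 0
    envelopes: tuple[EnvelopeSpec, ...] = ()
    noise_count: int = 0
    noise_intensity_range: tuple[float, float] = (0.05, 5.0)
    mz_range: tuple[float, float] = (400.0, 1600.0)
    rt_range: tuple[float, float] = (0.0, 600.0)
    scan_interval: float = 1.0
    trace_floor: float = 0.01  # drop envelope points fainter than this

    def __post_init__(self) -> None:
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("mz_range must be a non-empty interval")
        if self.rt_range[0] > self.rt_range[1]:
            raise ValueError("rt_range must be a valid interval")
        if self.noise_intensity_range[0] > self.noise_intensity_range[1]:
            raise ValueError("noise_intensity_range must be a valid interval")
        if self.scan_interval <= 0:
            raise ValueError("scan_interval must be positive")
        if self.noise_count < 0:
            raise ValueError("noise_count must be >= 0")

    @staticmethod
    def random(seed: int, n_envelopes: int, noise_count: int = 0,
               mz_range: tuple[float, float] = (400.0, 1600.0),
               rt_range: tuple[float, float] = (0.0, 600.0),
               scan_interval: float = 1.0,
               noise_intensity_range: tuple[float, float] = (0.05, 5.0),
               base_intensity_range: tuple[float, float] = (50.0, 5000.0),
               ) -> "GenConfig":
        """Draw ``n_envelopes`` plausible envelopes from sampling ranges."""
        rng = np.random.default_rng(seed)
        margin = 0.05 * (mz_range[1] - mz_range[0])
        envs = []
        for _ in range(n_envelopes):
            charge = int(rng.integers(1, 4))
            envs.append(EnvelopeSpec(
                monoisotopic_mz=float(rng.uniform(mz_range[0] + margin,
                                                  mz_range[1] - margin)),
                charge=charge,
                num_isotopes=int(rng.integers(3, 7)),
                base_intensity=float(rng.uniform(*base_intensity_range)),
                isotope_decay=float(rng.uniform(0.45, 0.85)),
                rt_center=float(rng.uniform(rt_range[0], rt_range[1])),
                rt_sigma=float(rng.uniform(4.0, 15.0)),
            ))
        return GenConfig(
            seed=seed, envelopes=tuple(envs), noise_count=noise_count,
            noise_intensity_range=noise_intensity_range,
            mz_range=mz_range, rt_range=rt_range, scan_interval=scan_interval,
        )


def _scan_times(config: GenConfig) -> np.ndarray:
    lo, hi = config.rt_range
    n = int(math.floor((hi - lo) / config.scan_interval + 1e-9)) + 1
    return lo + config.scan_interval * np.arange(n)


def gen_points(config: GenConfig) -> tuple[PointSet, np.ndarray]:
    """Generate the point cloud plus per-point truth labels.

    Returns ``(points, labels)`` where ``labels[i]`` is the envelope
    index the point belongs to, or -1 for noise.  Identical configs give
    identical output.  Envelope points fainter than ``trace_floor`` are
    dropped (a real centroider would never report them).
    """
    rng = np.random.default_rng(config.seed)
    times = _scan_times(config)
    mz_parts, rt_parts, int_parts, lab_parts = [], [], [], []

    for ei, env in enumerate(config.envelopes):
        for k in range(env.num_isotopes):
            inten = env.trace_intensity(k, times)
            keep = inten >= config.trace_floor
            if not keep.any():
                continue
            m = int(keep.sum())
            mz_parts.append(np.full(m, env.isotope_mz(k)))
            rt_parts.append(times[keep])
            int_parts.append(inten[keep])
            lab_parts.append(np.full(m, ei, dtype=np.int64))

    if config.noise_count:
        # noise sits on the scan grid like every real centroid
        mz_parts.append(rng.uniform(*config.mz_range, size=config.noise_count))
        rt_parts.append(rng.choice(times, size=config.noise_count))
        int_parts.append(rng.uniform(*config.noise_intensity_range,
                                     size=config.noise_count))
        lab_parts.append(np.full(config.noise_count, NOISE_LABEL, dtype=np.int64))

    if not mz_parts:
        return PointSet(), np.empty(0, dtype=np.int64)

    mz = np.concatenate(mz_parts)
    rt = np.concatenate(rt_parts)
    inten = np.concatenate(int_parts)
    labels = np.concatenate(lab_parts)
    # deterministic scan order: by (rt, mz), then intensity for exact ties
    order = np.lexsort((inten, mz, rt))
    ids = np.arange(mz.size, dtype=np.int64)
    return (PointSet(ids, mz[order], rt[order], inten[order]), labels[order])


def points_to_spectra(points: PointSet, ms_level: int = 1) -> list[SpectrumRecord]:
    """Group a point cloud into per-scan spectra, m/z ascending within each."""
    if len(points) == 0:
        return []
    records = []
    rts = points.rt
    order = np.lexsort((points.mz, rts))
    rts_sorted = rts[order]
    boundaries = np.flatnonzero(np.diff(rts_sorted)) + 1
    for idx, chunk in enumerate(np.split(order, boundaries)):
        records.append(SpectrumRecord(
            index=idx,
            scan_start_time=float(rts[chunk[0]]),
            ms_level=ms_level,
            mz_values=points.mz[chunk],
            intensity_values=points.intensity[chunk],
        ))
    return records


def gen_mzml(config: GenConfig, destination,
             dialect: MzmlDialect | None = None) -> tuple[PointSet, np.ndarray]:
    """Generate a cloud and write it as an mzML fixture.

    Returns the generated ``(points, labels)`` so callers can keep the
    truth table.  Parsing the file back recovers the cloud exactly at
    float64, and within single precision at float32.
    """
    points, labels = gen_points(config)
    write_mzml(points_to_spectra(points), destination, dialect)
    return points, labels
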