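"""Core domain types shared across the package.

An LC-MS map is modelled as a cloud of centroided observations, each a
single ``(m/z, RT, intensity)`` triple.  Scans (spectra) are the unit the
mzML format stores; points are the unit the summarization index and the
viewport service work with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "MsPoint",
    "SpectrumRecord",
    "MzmlDialect",
    "PointSet",
    "ViewWindow",
]


class MsPoint(NamedTuple):
    """One centroided observation of an ion signal.

    ``id`` is unique within a dataset; ``mz`` is in Thomson, ``rt`` in
    seconds, ``intensity`` in arbitrary detector units.
    """

    id: int
    mz: float
    rt: float
    intensity: float


@dataclass
class SpectrumRecord:
    """One scan: retention time plus parallel m/z and intensity arrays.

    ``scan_start_time`` is always in seconds regardless of the unit the
    source file declared.
    """

    index: int
    scan_start_time: float
    ms_level: int
    mz_values: np.ndarray
    intensity_values: np.ndarray

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=np.float64)
        self.intensity_values = np.asarray(self.intensity_values, dtype=np.float64)
        if self.mz_values.shape != self.intensity_values.shape:
            raise ValueError(
                "mz_values and intensity_values must have equal length "
                f"({self.mz_values.size} != {self.intensity_values.size})"
            )
        if self.scan_start_time < 0:
            raise ValueError("scan_start_time must be >= 0")
        if self.ms_level < 1:
            raise ValueError("ms_level must be >= 1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectrumRecord):
            return NotImplemented
        return (
            self.index == other.index
            and self.scan_start_time == other.scan_start_time
            and self.ms_level == other.ms_level
            and np.array_equal(self.mz_values, other.mz_values)
            and np.array_equal(self.intensity_values, other.intensity_values)
        )


PRECISIONS = ("float32", "float64")
COMPRESSIONS = ("none", "zlib")
RT_UNITS = ("second", "minute")


@dataclass(frozen=True)
class MzmlDialect:
    """How binary arrays and metadata are encoded in an mzML file."""

    precision: str = "float64"
    compression: str = "none"
    indexed_wrapper: bool = False
    rt_unit_in_file: str = "second"

    def __post_init__(self) -> None:
        if self.precision not in PRECISIONS:
            raise ValueError(f"precision must be one of {PRECISIONS}")
        if self.compression not in COMPRESSIONS:
            raise ValueError(f"compression must be one of {COMPRESSIONS}")
        if self.rt_unit_in_file not in RT_UNITS:
            raise ValueError(f"rt_unit_in_file must be one of {RT_UNITS}")


@dataclass(frozen=True)
class ViewWindow:
    """A closed viewport rectangle in the (m/z, RT) plane."""

    mz_min: float
    mz_max: float
    rt_min: float
    rt_max: float

    def __post_init__(self) -> None:
        if self.mz_min > self.mz_max:
            raise ValueError("mz_min must be <= mz_max")
        if self.rt_min > self.rt_max:
            raise ValueError("rt_min must be <= rt_max")

    @property
    def mz_width(self) -> float:
        return self.mz_max - self.mz_min

    def contains(self, mz: float, rt: float) -> bool:
        return (
            self.mz_min <= mz <= self.mz_max and self.rt_min <= rt <= self.rt_max
        )

    def overlaps(self, other: "ViewWindow") -> bool:
        return not (
            other.mz_max < self.mz_min
            or other.mz_min > self.mz_max
            or other.rt_max < self.rt_min
            or other.rt_min > self.rt_max
        )


@dataclass
class PointSet:
    """Columnar container for a point cloud (struct-of-arrays).

    Columns are parallel: ``ids`` (int64), ``mz``, ``rt``, ``intensity``
    (float64).  Most numeric work in the package is vectorized over these
    columns; :class:`MsPoint` views are materialized only at API edges.
    """

    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    mz: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    rt: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        n = self.ids.size
        if not (self.mz.size == self.rt.size == self.intensity.size == n):
            raise ValueError("PointSet columns must have equal length")

    def __len__(self) -> int:
        return int(self.ids.size)

    def __iter__(self) -> Iterator[MsPoint]:
        for i in range(len(self)):
            yield self.point(i)

    def point(self, row: int) -> MsPoint:
        return MsPoint(
            int(self.ids[row]),
            float(self.mz[row]),
            float(self.rt[row]),
            float(self.intensity[row]),
        )

    def take(self, rows: np.ndarray) -> "PointSet":
        rows = np.asarray(rows)
        return PointSet(
            self.ids[rows], self.mz[rows], self.rt[rows], self.intensity[rows]
        )

    @classmethod
    def from_points(cls, points: Sequence[MsPoint] | Iterator[MsPoint]) -> "PointSet":
        pts = list(points)
        if not pts:
            return cls()
        arr = np.array(pts, dtype=np.float64)
        return cls(arr[:, 0].astype(np.int64), arr[:, 1], arr[:, 2], arr[:, 3])

    def to_points(self) -> list[MsPoint]:
        return list(self)
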