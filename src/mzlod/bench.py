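"""Parser-scaling experiment: parse time as a function of spectrum count.

Prefix subsets of one source file are generated (first k spectra, same
dialect), and each subset is parsed in full by both the streaming reader
and the whole-document reference reader, with wall time recorded
separately for constructing the parser and for the parse itself.
File reading is a linear algorithm, so over subsets of one file the
times regress linearly on spectrum count; the numbers are reported,
never asserted here — hardware decides them.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path

from . import mzml

__all__ = ["BenchRow", "bench", "rows_to_tsv", "linear_r2"]


@dataclass
class BenchRow:
    file: str
    spectrum_count: int
    file_bytes: int
    build_seconds: float
    parse_seconds: float
    reference_seconds: float


def _time_stream_parse(path) -> tuple[float, float, int]:
    """(build_seconds, parse_seconds, spectra) for a full streaming parse."""
    t0 = time.perf_counter()
    it = mzml.stream_spectra(path)
    t1 = time.perf_counter()
    count = sum(1 for _ in it)
    t2 = time.perf_counter()
    return t1 - t0, t2 - t1, count


def bench(source, num_subsets: int, workdir) -> list[BenchRow]:
    """Create ``num_subsets`` prefix subsets of ``source`` and time parses.

    Subset k (1-based) holds the first ``k * total // num_subsets``
    spectra; counts are strictly increasing.  Subset files are written
    under ``workdir``.
    """
    if num_subsets < 1:
        raise ValueError("num_subsets must be >= 1")
    total = sum(1 for _ in mzml.stream_spectra(source))
    if total < num_subsets:
        raise ValueError(
            f"source has {total} spectra, fewer than {num_subsets} subsets"
        )
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(1, num_subsets + 1):
        k = i * total // num_subsets
        dest = workdir / f"subset_{k:06d}.mzML"
        mzml.subset_spectra(source, k, dest)
        build_s, parse_s, parsed = _time_stream_parse(dest)
        assert parsed == k
        t0 = time.perf_counter()
        mzml.reference_parse(dest)
        ref_s = time.perf_counter() - t0
        rows.append(BenchRow(
            file=str(dest), spectrum_count=k,
            file_bytes=dest.stat().st_size,
            build_seconds=build_s, parse_seconds=parse_s,
            reference_seconds=ref_s,
        ))
    return rows


def rows_to_tsv(rows: list[BenchRow]) -> str:
    header = "file\tspectrum_count\tfile_bytes\tbuild_seconds\tparse_seconds\treference_seconds"
    lines = [header]
    for r in rows:
        lines.append(
            f"{r.file}\t{r.spectrum_count}\t{r.file_bytes}"
            f"\t{r.build_seconds:.6f}\t{r.parse_seconds:.6f}\t{r.reference_seconds:.6f}"
        )
    return "\n".join(lines) + "\n"


def linear_r2(x, y) -> float:
    """R-squared of an ordinary least-squares line through (x, y)."""
    import numpy as np

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.allclose(y, y[0]):
        return 1.0
    coeffs = np.polyfit(x, y, 1)
    resid = y - np.polyval(coeffs, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot
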