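"""The parser-scaling experiment: parse time versus spectrum count.

Prefix subsets of one file are generated and each is parsed in full;
because file reading is a linear algorithm, the times fall on a line.
"""

import tempfile
from pathlib import Path

from mzlod import GenConfig, gen_mzml
from mzlod.bench import bench, linear_r2, rows_to_tsv

workdir = Path(tempfile.mkdtemp())
source = workdir / "run.mzML"
gen_mzml(GenConfig.random(seed=11, n_envelopes=20, noise_count=60000,
                          rt_range=(0.0, 300.0)), source)

rows = bench(source, num_subsets=10, workdir=workdir / "subsets")
print(rows_to_tsv(rows), end="")

r2 = linear_r2([r.spectrum_count for r in rows],
               [r.build_seconds + r.parse_seconds for r in rows])
print(f"\nR^2 of parse time vs spectrum count: {r2:.4f}")
# These are single-shot wall times: at millisecond scale the R^2 moves
# around with scheduler noise.  The test suite measures the same
# linearity with repeated interleaved timings, where it is near 1.
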