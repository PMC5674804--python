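"""Generate a synthetic MS1 map and write it as an mzML fixture.

The generator emulates what one LC-MS survey run looks like as a point
cloud: isotopic envelopes (combs of isotope traces spaced 1.003355/z Th
apart, each with a Gaussian elution profile) over a carpet of
sub-threshold noise.
"""

import tempfile
from pathlib import Path

import numpy as np

from mzlod import GenConfig, gen_mzml
from mzlod.synth import NEUTRON_SPACING

config = GenConfig.random(seed=42, n_envelopes=20, noise_count=5000)
out = Path(tempfile.mkdtemp()) / "map.mzML"
points, labels = gen_mzml(config, out)

n_noise = int((labels == -1).sum())
print(f"wrote {out}")
print(f"points generated: {len(points)} "
      f"({len(points) - n_noise} envelope points, {n_noise} noise)")

# verify the isotope spacing of the first envelope directly from the data
env = config.envelopes[0]
trace_mzs = np.unique(points.mz[labels == 0])
print(f"envelope 0: charge {env.charge}, isotope spacing "
      f"{np.diff(trace_mzs)[0]:.7f} Th (expected "
      f"{NEUTRON_SPACING / env.charge:.7f})")
# The spacing is the C13 neutron mass difference divided by the charge:
# it is what lets a human (or an algorithm) read the charge state off the map.
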