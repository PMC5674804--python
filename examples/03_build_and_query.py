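"""Build a summarization index and run viewport queries with a point budget.

The index culls sub-threshold noise, partitions the map into a
hierarchy of bounding boxes, and keeps per-node top-intensity samples.
A query asks for a viewport plus a desired number of points n and gets
back exactly n real stored points (or the whole in-window supply when
it is smaller than n).
"""

from mzlod import (
    BuildConfig,
    GenConfig,
    SummaryQuery,
    ViewWindow,
    brute_force_query,
    build_tree,
    gen_points,
    jump_window,
)

points, _ = gen_points(GenConfig.random(seed=23, n_envelopes=20,
                                        noise_count=9000,
                                        noise_intensity_range=(0.05, 50.0)))
index = build_tree(points, BuildConfig(intensity_floor=1.0))
print(f"generated {len(points)} points; {len(index)} retained after "
      f"culling at intensity >= {index.config.intensity_floor}")

window = ViewWindow(500.0, 900.0, 100.0, 400.0)
supply = brute_force_query(index.points, window)
print(f"viewport {window.mz_min:.0f}-{window.mz_max:.0f} Th x "
      f"{window.rt_min:.0f}-{window.rt_max:.0f} s holds {len(supply)} points")

for budget in (50, 500, len(supply) + 1000):
    result = index.query(SummaryQuery(window, budget))
    print(f"  budget n={budget}: returned {len(result)} points "
          f"(weakest intensity {min(p.intensity for p in result):.2f})")
# With n below the supply the strongest n points come back (the detail
# level); with n above it, the entire in-window set — never aggregates.

# jump-to-m/z keeps the zoom level and RT position
jumped = jump_window(window, target_mz=1200.0)
print(f"after jump to 1200 Th: window {jumped.mz_min:.0f}-{jumped.mz_max:.0f} Th, "
      f"same width ({jumped.mz_width:.0f} Th) and RT bounds "
      f"({jumped.rt_min:.0f}-{jumped.rt_max:.0f} s)")
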