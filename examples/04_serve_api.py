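"""Serve an index over HTTP and query it like a viewer client would.

Two JSON GET endpoints: /api/v1/bounds for the dataset extents and
/api/v1/points for viewport queries with a point budget.
"""

import json
import urllib.request

from mzlod import BuildConfig, GenConfig, build_tree, gen_points, serve

points, _ = gen_points(GenConfig.random(seed=5, n_envelopes=12,
                                        noise_count=4000))
index = build_tree(points, BuildConfig())

with serve(index, "127.0.0.1", 0) as handle:
    print(f"serving on {handle.url}")

    with urllib.request.urlopen(f"{handle.url}/api/v1/bounds") as resp:
        bounds = json.loads(resp.read())
    print("bounds:", json.dumps(bounds))

    url = (f"{handle.url}/api/v1/points"
           f"?mzmin=600&mzmax=1000&rtmin=0&rtmax=300&n=5")
    with urllib.request.urlopen(url) as resp:
        body = json.loads(resp.read())
    print(f"requested 5 points, got {body['returned_count']} "
          f"(truncated={body['truncated']}):")
    for p in body["points"]:
        print(f"  id={p['id']} mz={p['mz']:.4f} rt={p['rt']:.1f} "
              f"intensity={p['intensity']:.1f}")
# truncated=true means the viewport held more points than the budget;
# a client can raise n (the detail level) to see more of them.
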