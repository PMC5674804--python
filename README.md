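# mzlod

A level-of-detail backend for interactive LC-MS maps.

## The problem

A single mass-spectrometry run produces a three-dimensional map — m/z
(Thomson) × retention time (seconds) × intensity — with far more
centroided points than any interactive viewer can draw. A viewer that
downsamples arbitrarily misleads the practitioner; a viewer that draws
everything is unusably slow. What an interactive client needs from its
backend is: *given a viewport and a point budget n, return exactly n
real data points — never aggregates — chosen so the picture still looks
like the full data.*

`mzlod` implements that backend for anyone building or scripting MS
visualization and processing tools: a streaming mzML reader, a
summarization index, a JSON HTTP point service, and a seeded synthetic
MS1 generator so the whole stack is testable with no instrument data.

## The method

**Static summarization** (build time). The point cloud is culled at an
intensity floor (default 1 — sub-threshold points are treated as
noise), then partitioned recursively into a balanced hierarchy of
bounding boxes (median splits alternating between the m/z and RT axes).
Leaves own disjoint subsets of the retained points; every internal node
stores a *sample* of at most S references into its subtree — the top-S
points by intensity, ties broken on ascending (mz, rt, id). Samples are
references, never copies, so each point is stored once and higher tree
levels hold progressively coarser sketches of the map.

**Dynamic summarization** (query time). A query (viewport W, budget n)
walks the tree breadth-first. Each level's in-view candidates come from
node samples (full leaf contents at the bottom). The walk stops at the
first level whose candidate set provably contains the true in-window
top-n — provable because any point still hidden below a node ranks
strictly worse than that node's weakest sample member — and whittles it
down to exactly n points by the same top-by-intensity rule. If W holds
fewer than n retained points, all of them are returned. Results are
deterministic, always real stored points, and equal to a brute-force
scan-and-sort of the window.

The mzML reader is single-pass and incremental: spectra are decoded
and yielded while the file is still being read (first spectrum after
~2% of the bytes on typical files), for plain and `indexedmzML` files,
32- and 64-bit float arrays, zlib-compressed or not.

## Worked example

```sh
python examples/03_build_and_query.py
```

prints (numbers from an actual run):

```
generated 16460 points; 14618 retained after culling at intensity >= 1.0
viewport 500-900 Th x 100-400 s holds 2235 points
  budget n=50: returned 50 points (weakest intensity 1885.18)
  budget n=500: returned 500 points (weakest intensity 49.02)
  budget n=3235: returned 2235 points (weakest intensity 1.01)
after jump to 1200 Th: window 1000-1400 Th, same width (400 Th) and RT bounds (100-400 s)
```

Reading it: culling dropped the 1842 sub-threshold noise points. The
400 Th × 300 s viewport holds 2235 retained points; at budget 50 the
backend returns the 50 most intense (weakest 1885), at budget 500 the
top 500 (weakest 49), and a budget above the supply returns the whole
window (weakest 1.01, just above the floor). The jump-to-m/z call
recenters the window at 1200 Th while preserving the zoom (width) and
RT position. The other scripts in `examples/` demonstrate generation
(`01`), streaming (`02`), the HTTP API (`04`) and parser scaling (`05`).

The same operations are available from the shell:

```sh
mzlod gen --out map.mzML --seed 42 --envelopes 20 --noise 5000
mzlod index --in map.mzML --out map.idx
mzlod query --index map.idx --mz-min 400 --mz-max 500 \
            --rt-min 0 --rt-max 600 -n 1000
mzlod serve --index map.idx --port 4567
mzlod subset --in map.mzML -k 20 --out head.mzML
mzlod bench --in map.mzML --subsets 10
```

## HTTP API

- `GET /api/v1/points?mzmin=&mzmax=&rtmin=&rtmax=&n=` →
  `{"points": [{"id","mz","rt","intensity"}...], "returned_count": k,
  "truncated": bool}`
- `GET /api/v1/bounds` →
  `{"mz_min","mz_max","rt_min","rt_max","intensity_max","point_count"}`

Errors come back as `{"error": "..."}` with 400/404/503 status codes.
The route shapes are this package's own design.

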