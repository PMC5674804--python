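# Methods

## Data model

A map is a cloud of centroided points `(id, mz, rt, intensity)` with
m/z in Thomson, RT in seconds, intensity in arbitrary detector units.
Scans (`SpectrumRecord`) are the storage unit of mzML; flattening scans
into points assigns ids sequentially in file order. Internally points
live in a columnar `PointSet` (numpy struct-of-arrays); `MsPoint`
tuples are materialized only at API edges.

## mzML reading and writing

`stream_spectra` feeds the XML to a pull parser in 16 KiB chunks and
yields each spectrum as soon as its closing tag arrives, deleting
exhausted subtrees so memory stays flat. It reads the source exactly
once, front to back; the trailing index of an `indexedmzML` wrapper is
deliberately ignored — exploiting it would require seeking, and the
reader is single-pass by design. `reference_parse` is the opposite
strategy on purpose: a whole-document DOM load followed by extraction.
It exists as a correctness oracle; the test suite asserts record-level
equality between the two paths on every dialect combination
(float32/float64 × zlib/none × plain/indexed).

Conventions and error policy:

- RT is normalized to seconds at parse time whatever unit the file
  declares (minute-unit files are converted); one internal unit
  prevents axis-scale bugs downstream. The original unit is part of
  the detected dialect.
- Only arrays carrying the m/z or intensity CV terms are decoded;
  other `binaryDataArray` entries are skipped silently (forward
  compatibility).
- A mismatch between `encodedLength`/`defaultArrayLength` and the
  actual payload is a hard `IntegrityError`, not a warning: silent
  truncation would corrupt the point cloud.
- An unrecognized precision/compression CV term on a consumed array is
  an `UnsupportedDialectError`.
- Malformed XML reports the byte offset the reader had consumed when
  the parser failed.
- Profile and centroid spectra are treated uniformly: every array
  entry becomes one point.

The writer emits a fixed mzML 1.1 template with the standard CV
accessions; floats are serialized with shortest round-trip `repr`, so
identical inputs give byte-identical files and a float64
write→parse→write cycle is byte-stable. For `indexedmzML` output the
spectrum byte offsets are computed from the serialized body.

## Static summarization

`BuildConfig` defaults: `intensity_floor=1.0` (the conventional noise
floor for centroided MS1 maps; the boundary is inclusive — intensity
exactly 1 survives, strictly below is noise), `leaf_capacity=512`,
`branching=4`, `sample_size=256`.

The tree is built by recursive median splits alternating between the
m/z and RT axes into `branching` nearly equal children (stable sort on
(axis value, id)), stopping at `leaf_capacity`. This gives a balanced,
deterministic partition without tuning. Each node's sample is the
top-S of its subtree under the total selection order **intensity
descending, then ascending (mz, rt, id)**. The rank of every point
under this order is computed once per build (`lexsort`), so sampling is
an `argpartition` per node.

Top-by-intensity sampling (rather than random sampling) is a design
choice: it is deterministic, it keeps the visually dominant signal at
every zoom level, and it gives the selection a nesting property — a
point in a node's top-S is in its child's top-S — that makes
coarse-level results subsets of fine-level results. `BuildConfig.seed`
is accepted and stored in the index header for provenance, but the
sampling rule draws no random numbers, so the seed influences nothing;
determinism comes from the rule itself.

## Dynamic summarization

A query is a closed-interval viewport (closed on both axes, because a
viewer must draw boundary points; the brute-force oracle uses the same
convention) plus a budget `n`. The walk is breadth-first by level:
every frontier node overlapping the window contributes its in-window
sample (leaves contribute their full in-window contents), and leaves
stay on the frontier as deeper levels are processed.

The stopping rule is the one subtlety. A node's sample is the top-S of
its *whole* subtree, so a window clipping the node can miss strong
in-window points crowded out of the sample by out-of-window ones.
Stopping at the first level with ≥ n in-view candidates could therefore
return a set that differs from the true in-window intensity top-n. The
walk instead stops at the first level whose candidate set is
*certified*: for every unresolved internal node, the node's weakest
sample member ranks no better than the current n-th candidate. Since
any point still hidden below that node ranks strictly worse than the
weakest sample member, no hidden point can displace the selection, and
the returned set equals a brute-force scan-and-sort of the window.
When the certificate fails the walk descends one more level; in the
worst case it reaches the leaves, where the result is exact by
construction. Whittling uses the same total order as sampling, so
static and dynamic summarization agree and the budget-`n` result is a
subset of the budget-`n'` result for `n' > n`.

If the window's supply is below `n` the full supply is returned —
never padding. `n=0` returns an empty list.

## Index persistence

An index file is `MZLODIDX1\n`, one JSON header line (build config,
point count, column spec), then the four raw little-endian columns of
the culled point table. The tree is rebuilt deterministically on load
rather than serialized: rebuild cost is a sort-dominated pass over the
table, and the format guarantees both byte-identical files for
identical inputs and identical query results after a round trip.

## HTTP service

Stdlib `ThreadingHTTPServer` with the two GET routes; the index is
immutable after load, so concurrent reads need no locking. JSON is
serialized with sorted keys and no whitespace, making identical
requests byte-identical. `truncated` reports whether the window's true
supply exceeded the budget; the supply is counted with a vectorized
scan of the point table (microseconds at the scales served) rather
than threaded through the tree walk. The route and field names are
this package's design; no wire compatibility with any particular
viewer client is claimed.

## Synthetic maps

The generator emulates centroided MS1 data: each `EnvelopeSpec` is one
analyte at one charge state, producing `num_isotopes` traces at
`monoisotopic_mz + k·1.003355/charge` (1.003355 Da is the C13−C12 mass
difference — a generator convention, fixed), with peak heights decaying
geometrically (`isotope_decay^k`) and Gaussian elution
`exp(−(t−rt_center)²/2σ²)` sampled on a regular scan grid
(`scan_interval`, default 1 s over a 600 s gradient). Envelope points
fainter than `trace_floor` (default 0.01) are dropped, as a real
centroider would. Noise is uniform over the map, on the scan grid,
with an intensity range straddling the culling floor (default
0.05–5.0) so culling has real work to do. `GenConfig.random(seed, ...)`
draws envelope parameters from ranges typical of tryptic-peptide MS1
data (charges 1–3, 3–6 isotopes, σ of 4–15 s).

What the generator does *not* model — averagine isotope patterns,
chromatographic tailing, mass-accuracy jitter, co-eluting overlaps,
intensity-dependent noise — bounds what the tests show: they verify
the parsing, indexing and query machinery exactly, not robustness to
instrument artifacts. Nothing in the stack depends on the signal
model, only on points.

## Measurement choices

The parser-scaling check generates one ~160k-point file (~4 MB, ~400
spectra), cuts 10 prefix subsets, and regresses streaming parse time
on spectrum count. Timings are interleaved min-of-7 with the garbage
collector paused and a warm-up pass, because GC pauses and cold caches
are measurement artifacts, not parser behaviour; the observed R² is
≥ 0.98. Bench numbers from the CLI are single-shot and reported only,
never asserted — wall time belongs to the hardware.

Test problem sizes (≈10⁴-point clouds for query oracles, 50 random
windows, 25 HTTP round trips) were chosen so the full suite exercises
every contract in seconds; all the properties checked are
size-independent.

## Known limitations

- The index is in-RAM; out-of-core paging and incremental insertion
  are out of scope.
- No mzXML/vendor formats, chromatogram lists, ion mobility, or
  random access by scan id.
- `subset_spectra` re-streams the source to count spectra; it is a
  fixture utility, not an indexed extractor.
- Float32 files round-trip within single precision only, by nature of
  the encoding.
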