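"""Level-of-detail summarization index over an MS1 point cloud.

Static summarization happens at build time: the point cloud is culled at
an intensity floor (sub-threshold points are treated as noise), then
partitioned recursively into a balanced hierarchy of bounding boxes.
Leaves own disjoint subsets of the retained points; every internal node
carries a *sample* of at most ``S`` references into its subtree — the
top-``S`` points by intensity, ties broken on ascending ``(mz, rt, id)``.
Samples hold row references, never copies, so each retained point is
stored exactly once.

Dynamic summarization happens per query: given a viewport and a point
budget ``n``, the tree is walked breadth-first level by level.  Each
level's in-view candidates are gathered from node samples (or full leaf
contents); as soon as a level can *prove* that it already holds the
true in-window top-``n`` — every unresolved node's weakest sample member
ranks no better than the current n-th candidate, so nothing stronger can
be hiding deeper — the candidate set is whittled down to exactly ``n``
points and returned.  If the window holds fewer than ``n`` retained
points the walk reaches the leaves and returns them all.  Returned
points are always real stored points, never aggregates.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import MsPoint, PointSet, ViewWindow

__all__ = [
    "BuildConfig",
    "SummaryQuery",
    "SummaryNode",
    "MzTreeIndex",
    "cull_points",
    "build_tree",
    "sample_node",
    "whittle",
    "brute_force_query",
    "jump_window",
    "save_index",
    "load_index",
]


@dataclass(frozen=True)
class BuildConfig:
    """Knobs for static summarization.

    intensity_floor: points with intensity strictly below this are noise
        and dropped before indexing (default 1.0, the conventional floor
        for centroided MS1 maps).
    leaf_capacity: maximum points stored in one leaf.
    branching: children per internal node.
    sample_size: S, the per-node sample budget.
    seed: recorded in the index header for provenance; the sampling rule
        itself is deterministic and draws no random numbers.
    """

    intensity_floor: float = 1.0
    leaf_capacity: int = 512
    branching: int = 4
    sample_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_floor < 0:
            raise ValueError("intensity_floor must be >= 0")
        if self.leaf_capacity < 1:
            raise ValueError("leaf_capacity must be >= 1")
        if self.branching < 2:
            raise ValueError("branching must be >= 2")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


@dataclass(frozen=True)
class SummaryQuery:
    """A viewport plus the exact number of points the client wants."""

    window: ViewWindow
    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")


@dataclass
class SummaryNode:
    """One box in the hierarchy.

    ``sample`` and ``leaf_rows`` hold row indices into the index's culled
    point table (references, not copies).  ``sample`` is sorted by the
    selection order (intensity desc, then ascending mz, rt, id).
    """

    bounds: ViewWindow | None
    sample: np.ndarray
    children: list["SummaryNode"] = field(default_factory=list)
    leaf_rows: np.ndarray | None = None
    subtree_size: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.leaf_rows is not None

    @property
    def sample_covers_subtree(self) -> bool:
        return self.sample.size == self.subtree_size


# ---------------------------------------------------------------------------
# primitive operations


def cull_points(points: PointSet | Iterable[MsPoint],
                floor: float = 1.0) -> PointSet:
    """Drop sub-threshold noise: keep points with intensity >= floor.

    Order is preserved.  The boundary is inclusive — a point exactly at
    the floor survives; strictly-below is noise.
    """
    ps = points if isinstance(points, PointSet) else PointSet.from_points(points)
    return ps.take(np.flatnonzero(ps.intensity >= floor))


def _selection_ranks(ps: PointSet) -> np.ndarray:
    """Total selection order: intensity desc, then ascending (mz, rt, id).

    Returns rank[row] = position in that order (0 = strongest point).
    """
    order = np.lexsort((ps.ids, ps.rt, ps.mz, -ps.intensity))
    ranks = np.empty(len(ps), dtype=np.int64)
    ranks[order] = np.arange(len(ps), dtype=np.int64)
    return ranks


def _top_rows(rows: np.ndarray, ranks: np.ndarray, k: int) -> np.ndarray:
    """The k best rows by selection rank, returned in rank order."""
    if rows.size <= k:
        sel = rows
    else:
        part = np.argpartition(ranks[rows], k - 1)[:k]
        sel = rows[part]
    return sel[np.argsort(ranks[sel])]


def sample_node(child_point_sets: Sequence[PointSet], S: int,
                seed: int = 0) -> list[int]:
    """Select a node's sample from its children's points.

    If the children hold at most ``S`` points all are referenced;
    otherwise the top-``S`` by intensity with ties broken on ascending
    (mz, rt, id).  Returns point ids in selection order.  ``seed`` is
    accepted for interface stability; the rule is deterministic.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    merged = PointSet(
        np.concatenate([ps.ids for ps in child_point_sets]) if child_point_sets else [],
        np.concatenate([ps.mz for ps in child_point_sets]) if child_point_sets else [],
        np.concatenate([ps.rt for ps in child_point_sets]) if child_point_sets else [],
        np.concatenate([ps.intensity for ps in child_point_sets]) if child_point_sets else [],
    )
    ranks = _selection_ranks(merged)
    rows = _top_rows(np.arange(len(merged), dtype=np.int64), ranks, S)
    return [int(i) for i in merged.ids[rows]]


def whittle(candidates: Sequence[MsPoint] | PointSet, n: int) -> list[MsPoint]:
    """Dynamic summarization: reduce a candidate set to exactly n points.

    Selection is top-n by intensity with the same deterministic
    tie-break used by static sampling, so static and dynamic
    summarization agree on which points are the strongest.
    """
    ps = candidates if isinstance(candidates, PointSet) else PointSet.from_points(candidates)
    if n > len(ps):
        raise ValueError(f"cannot whittle {len(ps)} candidates down to {n}")
    ranks = _selection_ranks(ps)
    rows = _top_rows(np.arange(len(ps), dtype=np.int64), ranks, n)
    return ps.take(rows).to_points()


def brute_force_query(points: PointSet | Iterable[MsPoint],
                      window: ViewWindow) -> list[MsPoint]:
    """Linear-scan oracle: every point inside the closed window."""
    ps = points if isinstance(points, PointSet) else PointSet.from_points(points)
    mask = (
        (ps.mz >= window.mz_min) & (ps.mz <= window.mz_max)
        & (ps.rt >= window.rt_min) & (ps.rt <= window.rt_max)
    )
    return ps.take(np.flatnonzero(mask)).to_points()


def jump_window(window: ViewWindow, target_mz: float) -> ViewWindow:
    """Re-center the viewport at ``target_mz``.

    The m/z width and the RT bounds are preserved exactly, so zoom level
    and chromatographic position survive the jump.
    """
    if target_mz <= 0:
        raise ValueError("target_mz must be positive")
    half = window.mz_width / 2.0
    return ViewWindow(target_mz - half, target_mz + half,
                      window.rt_min, window.rt_max)


# ---------------------------------------------------------------------------
# the index


class MzTreeIndex:
    """A built level-of-detail index over a culled point table."""

    def __init__(self, points: PointSet, config: BuildConfig,
                 *, _pre_culled: bool = False):
        self.config = config
        self.points = points if _pre_culled else cull_points(points, config.intensity_floor)
        self._ranks = _selection_ranks(self.points)
        self.root = self._build(np.arange(len(self.points), dtype=np.int64), depth=0)

    # -- construction -----------------------------------------------------

    def _bounds_of(self, rows: np.ndarray) -> ViewWindow | None:
        if rows.size == 0:
            return None
        return ViewWindow(
            float(self.points.mz[rows].min()), float(self.points.mz[rows].max()),
            float(self.points.rt[rows].min()), float(self.points.rt[rows].max()),
        )

    def _build(self, rows: np.ndarray, depth: int) -> SummaryNode:
        cfg = self.config
        bounds = self._bounds_of(rows)
        if rows.size <= cfg.leaf_capacity:
            sample = _top_rows(rows, self._ranks, cfg.sample_size)
            return SummaryNode(bounds, sample, leaf_rows=np.sort(rows),
                               subtree_size=int(rows.size))
        axis = self.points.mz if depth % 2 == 0 else self.points.rt
        # stable sort on (axis value, id) keeps splits deterministic
        order = rows[np.lexsort((self.points.ids[rows], axis[rows]))]
        chunks = np.array_split(order, cfg.branching)
        children = [self._build(chunk, depth + 1) for chunk in chunks if chunk.size]
        sample = _top_rows(rows, self._ranks, cfg.sample_size)
        return SummaryNode(bounds, sample, children=children,
                           subtree_size=int(rows.size))

    # -- querying ---------------------------------------------------------

    def _in_window_mask(self, rows: np.ndarray, w: ViewWindow) -> np.ndarray:
        mz, rt = self.points.mz[rows], self.points.rt[rows]
        return ((mz >= w.mz_min) & (mz <= w.mz_max)
                & (rt >= w.rt_min) & (rt <= w.rt_max))

    def query(self, q: SummaryQuery) -> list[MsPoint]:
        rows, _ = self._query_rows(q.window, q.n)
        return self.points.take(rows).to_points()

    def query_points(self, window: ViewWindow, n: int) -> tuple[list[MsPoint], bool]:
        """Query returning (points, truncated) for the service layer."""
        rows, truncated = self._query_rows(window, n)
        return self.points.take(rows).to_points(), truncated

    def _query_rows(self, window: ViewWindow, n: int) -> tuple[np.ndarray, bool]:
        empty = np.empty(0, dtype=np.int64)
        if self.root.bounds is None or not window.overlaps(self.root.bounds):
            return empty, False
        supply = int(np.count_nonzero(self._in_window_mask(
            np.arange(len(self.points), dtype=np.int64), window)))
        if n == 0:
            return empty, supply > 0

        frontier: deque[SummaryNode] = deque([self.root])
        while True:
            candidates: list[np.ndarray] = []
            unresolved: list[SummaryNode] = []  # internal nodes with hidden points
            for node in frontier:
                if node.bounds is None or not window.overlaps(node.bounds):
                    continue
                src = node.leaf_rows if node.is_leaf else node.sample
                inview = src[self._in_window_mask(src, window)]
                if inview.size:
                    candidates.append(inview)
                if not node.is_leaf and not node.sample_covers_subtree:
                    unresolved.append(node)

            cand = np.concatenate(candidates) if candidates else empty
            if cand.size >= n and self._certified(cand, n, unresolved):
                top = _top_rows(cand, self._ranks, n)
                return top, supply > n
            if not unresolved:
                # leaves exhausted: return the full in-window supply
                top = _top_rows(cand, self._ranks, cand.size)
                return top, False
            # descend one level: expand internal nodes, keep leaves
            nxt: deque[SummaryNode] = deque()
            for node in frontier:
                if node.bounds is None or not window.overlaps(node.bounds):
                    continue
                if node.is_leaf or node.sample_covers_subtree:
                    nxt.append(node)
                else:
                    nxt.extend(node.children)
            frontier = nxt

    def _certified(self, cand: np.ndarray, n: int,
                   unresolved: list[SummaryNode]) -> bool:
        """True when the candidate set provably contains the in-window top-n.

        Any in-window point still hidden below an unresolved node ranks
        strictly worse than that node's weakest sample member; if every
        such weakest member ranks no better than our n-th candidate, no
        hidden point can displace the selection.
        """
        if not unresolved:
            return True
        nth_rank = np.partition(self._ranks[cand], n - 1)[n - 1]
        for node in unresolved:
            if self._ranks[node.sample].max() < nth_rank:
                return False
        return True

    # -- bounds -----------------------------------------------------------

    @property
    def bounds(self) -> ViewWindow | None:
        return self.root.bounds

    @property
    def intensity_max(self) -> float:
        return float(self.points.intensity.max()) if len(self.points) else 0.0

    def __len__(self) -> int:
        return len(self.points)


def build_tree(points: PointSet | Iterable[MsPoint],
               config: BuildConfig | None = None) -> MzTreeIndex:
    """Cull, partition and sample a point cloud into a queryable index."""
    config = config or BuildConfig()
    ps = points if isinstance(points, PointSet) else PointSet.from_points(points)
    return MzTreeIndex(ps, config)


# ---------------------------------------------------------------------------
# persistence: JSON header line + raw little-endian columns.
# The tree is rebuilt deterministically on load, so identical inputs give
# byte-identical files and identical query behaviour after a round trip.

_MAGIC = b"MZLODIDX1\n"


def save_index(index: MzTreeIndex, path) -> None:
    ps = index.points
    cfg = index.config
    header = {
        "config": {
            "intensity_floor": cfg.intensity_floor,
            "leaf_capacity": cfg.leaf_capacity,
            "branching": cfg.branching,
            "sample_size": cfg.sample_size,
            "seed": cfg.seed,
        },
        "point_count": len(ps),
        "columns": ["ids:int64", "mz:float64", "rt:float64", "intensity:float64"],
    }
    blob = json.dumps(header, sort_keys=True, separators=(",", ":")).encode() + b"\n"
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(blob)
        fh.write(ps.ids.astype("<i8").tobytes())
        fh.write(ps.mz.astype("<f8").tobytes())
        fh.write(ps.rt.astype("<f8").tobytes())
        fh.write(ps.intensity.astype("<f8").tobytes())


def load_index(path) -> MzTreeIndex:
    with open(Path(path), "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path} is not an index file")
        header = json.loads(fh.readline().decode())
        n = header["point_count"]
        ids = np.frombuffer(fh.read(8 * n), dtype="<i8").astype(np.int64)
        mz = np.frombuffer(fh.read(8 * n), dtype="<f8").astype(np.float64)
        rt = np.frombuffer(fh.read(8 * n), dtype="<f8").astype(np.float64)
        inten = np.frombuffer(fh.read(8 * n), dtype="<f8").astype(np.float64)
    cfg = BuildConfig(**header["config"])
    return MzTreeIndex(PointSet(ids, mz, rt, inten), cfg, _pre_culled=True)
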