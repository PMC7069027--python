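"""Spike counting from a binary recognition mask.

The count is assembled in two parts.  ``n_region`` is the number of
connected components that survive morphological cleaning (opening plus
small-fragment removal).  Components whose area or length-to-width ratio is
anomalously large are screened as overlap candidates — several spikes fused
into one region.  For each candidate the region's skeleton backbone (longest
skeleton path after spur pruning) is traced and its sharp direction changes
("inflection points") are counted: a chain of k fused spikes bends k - 1
times, so the candidate holds ``n_point + 1`` spikes.  The image total is

    total = n_region + n_point

with ``n_point`` summed over candidates only.  Evaluation against manual
counts uses the per-image accuracy A = (1 - |N_c - N_a| / N_a) x 100% plus
Pearson correlation and ordinary least-squares regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats
from skimage import measure, morphology

__all__ = [
    "CountParams",
    "RegionStats",
    "Backbone",
    "CountResult",
    "EvalResult",
    "clean_mask",
    "region_statistics",
    "flag_overlap_candidates",
    "extract_backbone",
    "count_inflections",
    "count_spikes",
    "accuracy",
    "evaluate",
]

# second-moment minor axis of a 1-pixel-wide line is zero; floor it at the
# value of a 1-px-wide continuous strip so elongation stays finite
_MIN_AXIS = 4.0 * np.sqrt(1.0 / 12.0)


@dataclass(frozen=True)
class CountParams:
    """Tunable parameters of the counting stage (pixels / degrees).

    Defaults are stated at the reference image scale (2592 x 1944); use
    :meth:`scaled` to adapt the area-like parameters to other frame sizes.
    """

    open_radius: int = 2
    min_area: int = 100
    area_factor: float = 1.25
    elongation_limit: float = 4.5
    spur_length: int | None = None  # default: 4 x open_radius
    window: int = 7
    angle_threshold: float = 35.0
    min_separation: int = 10

    def resolved_spur_length(self) -> int:
        return self.spur_length if self.spur_length is not None else 4 * self.open_radius

    def scaled(self, height: int, width: int) -> "CountParams":
        """Scale min_area by image area relative to the reference frame."""
        factor = (height * width) / (2592 * 1944)
        return replace(self, min_area=max(int(round(self.min_area * factor)), 4))


@dataclass(frozen=True)
class RegionStats:
    """Shape summary of one connected component."""

    region_id: int
    area: int
    centroid: tuple[float, float]
    major_axis: float
    minor_axis: float
    elongation: float
    is_overlap_candidate: bool = False
    n_inflections: int = 0


@dataclass(frozen=True)
class Backbone:
    """Longest pruned-skeleton path of a region, as an ordered pixel chain."""

    pixels: np.ndarray  # (L, 2) array of (row, col), 8-connected simple chain
    branch_count: int  # skeleton branch points before pruning

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class CountResult:
    n_region: int
    n_point: int
    per_region: tuple[RegionStats, ...] = field(default_factory=tuple)

    @property
    def total(self) -> int:
        return self.n_region + self.n_point


@dataclass(frozen=True)
class EvalResult:
    per_image_accuracy: tuple[float, ...]
    mean_accuracy: float
    pearson_r: float  # NaN when undefined (zero variance)
    r_squared: float
    slope: float
    intercept: float


# ---------------------------------------------------------------------------
# mask cleaning and region statistics


def clean_mask(mask: np.ndarray, open_radius: int = 2, min_area: int = 100) -> np.ndarray:
    """Morphological opening (disk) then removal of small components.

    Opening severs thin bridges and awn strokes between spikes; the area
    filter drops speckle left by misclassified superpixel fragments.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return mask.copy()
    if open_radius > 0:
        mask = morphology.opening(mask, morphology.disk(open_radius))
    if min_area > 1:
        # drop components with area < min_area (max_size removes area <= value)
        mask = morphology.remove_small_objects(
            mask, max_size=min_area - 1, connectivity=2
        )
    return mask


def region_statistics(mask: np.ndarray) -> list[RegionStats]:
    """Area, centroid and moment-based axes of each 8-connected component.

    Axis lengths are 4 x sqrt(eigenvalue) of the second central moment
    tensor, matching the normalization for which a solid ellipse recovers
    its own axes.
    """
    mask = np.asarray(mask).astype(bool)
    labels = measure.label(mask, connectivity=2)
    out = []
    for prop in measure.regionprops(labels):
        major = max(float(prop.axis_major_length), _MIN_AXIS)
        minor = max(float(prop.axis_minor_length), _MIN_AXIS)
        out.append(
            RegionStats(
                region_id=int(prop.label),
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                major_axis=major,
                minor_axis=minor,
                elongation=major / minor,
            )
        )
    return out


def flag_overlap_candidates(
    stats: list[RegionStats],
    area_factor: float = 1.75,
    elongation_limit: float = 4.5,
) -> list[RegionStats]:
    """Flag regions plausibly containing several fused spikes.

    A region is a candidate when its area exceeds ``area_factor`` times the
    median region area, or its length-to-width ratio exceeds
    ``elongation_limit``.  With a single region the median equals its own
    area, so only the elongation rule can fire.

    The screen is deliberately permissive: a large single spike flagged by
    mistake has a straight backbone and contributes zero inflections, while
    a fused pair that escapes the screen is an uncorrectable undercount.
    """
    if not stats:
        return []
    median_area = float(np.median([s.area for s in stats]))
    return [
        replace(
            s,
            is_overlap_candidate=(
                s.area > area_factor * median_area or s.elongation > elongation_limit
            ),
        )
        for s in stats
    ]


# ---------------------------------------------------------------------------
# backbone extraction

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    pts = set(map(tuple, np.argwhere(skel)))
    graph = {}
    for p in pts:
        graph[p] = [
            (p[0] + dy, p[1] + dx) for dy, dx in _NBRS if (p[0] + dy, p[1] + dx) in pts
        ]
    return graph


def _prune_spurs(
    graph: dict[tuple[int, int], list[tuple[int, int]]], spur_length: int
) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Iteratively delete endpoint chains shorter than spur_length that hang
    off a branch point."""
    graph = {p: list(nb) for p, nb in graph.items()}
    changed = True
    while changed:
        changed = False
        endpoints = sorted(p for p, nb in graph.items() if len(nb) <= 1)
        for ep in endpoints:
            if ep not in graph or len(graph[ep]) > 1:
                continue
            chain = [ep]
            prev, cur = None, ep
            while True:
                nxt = [q for q in graph[cur] if q != prev]
                if len(nxt) != 1:
                    break
                prev, cur = cur, nxt[0]
                if len(graph[cur]) > 2:
                    break
                chain.append(cur)
            # cur is the attachment point (branch) or the chain ran out
            if len(graph[cur]) > 2 and len(chain) < spur_length:
                for p in chain:
                    for q in graph.get(p, []):
                        if q in graph and p in graph[q]:
                            graph[q].remove(p)
                    graph.pop(p, None)
                changed = True
    return graph


def _bfs_farthest(
    graph: dict[tuple[int, int], list[tuple[int, int]]], start: tuple[int, int]
) -> tuple[tuple[int, int], dict[tuple[int, int], tuple[int, int] | None]]:
    from collections import deque

    dist = {start: 0}
    parent: dict[tuple[int, int], tuple[int, int] | None] = {start: None}
    far, far_d = start, 0
    q = deque([start])
    while q:
        u = q.popleft()
        for v in sorted(graph[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                q.append(v)
                if dist[v] > far_d or (dist[v] == far_d and v < far):
                    far, far_d = v, dist[v]
    return far, parent


def extract_backbone(region_mask: np.ndarray, spur_length: int = 8) -> Backbone:
    """Skeletonize a region, prune short spurs, return the longest path.

    The skeleton is reduced to a pixel graph; endpoint chains shorter than
    ``spur_length`` hanging off branch points are deleted iteratively, and
    the backbone is the geodesic between the two most distant remaining
    pixels (double breadth-first search, lexicographic tie-breaks for
    determinism).
    """
    region_mask = np.asarray(region_mask).astype(bool)
    if not region_mask.any():
        return Backbone(pixels=np.empty((0, 2), dtype=int), branch_count=0)
    skel = morphology.skeletonize(region_mask)
    if not skel.any():  # degenerate thin region: skeleton vanished
        pts = np.argwhere(region_mask)
        return Backbone(pixels=pts[:1], branch_count=0)
    graph = _skeleton_graph(skel)
    branch_count = sum(1 for nb in graph.values() if len(nb) > 2)
    pruned = _prune_spurs(graph, spur_length)
    if not pruned:
        pruned = {min(graph): []}
    start = min(pruned)
    a, _ = _bfs_farthest(pruned, start)
    b, parent = _bfs_farthest(pruned, a)
    path = []
    cur: tuple[int, int] | None = b
    while cur is not None:
        path.append(cur)
        cur = parent[cur]
    path.reverse()
    return Backbone(pixels=np.asarray(path, dtype=int), branch_count=branch_count)


# ---------------------------------------------------------------------------
# inflection counting


def count_inflections(
    backbone: Backbone,
    window: int = 7,
    angle_threshold: float = 35.0,
    min_separation: int = 10,
) -> int:
    """Count sharp direction changes along a backbone chain.

    At each interior position the incoming and outgoing tangents are
    estimated from the chain points ``window`` steps away; the turning angle
    is the absolute angle between them.  To reject pixel/segmentation
    jitter the turning angle is also measured with chords of twice the
    window (where the chain is long enough) and the smaller of the two is
    used: a genuine bend persists at the coarser scale, boundary wiggle
    collapses.  Inflection points are local maxima of this scale-stable
    turning angle above ``angle_threshold`` degrees, kept greedily in
    descending angle order subject to a pairwise chain distance of at least
    ``min_separation``.
    """
    pts = np.asarray(backbone.pixels, dtype=np.float64)
    n = len(pts)
    if n < 2 * window + 1:
        return 0
    # light pre-smoothing removes single-pixel staircase only; broader
    # jitter is handled by the two-scale minimum below, so genuine bends
    # keep almost their full turning angle
    size = 3
    pts = np.column_stack(
        [
            ndimage.uniform_filter1d(pts[:, 0], size, mode="nearest"),
            ndimage.uniform_filter1d(pts[:, 1], size, mode="nearest"),
        ]
    )

    def turning(w: int) -> np.ndarray:
        i = np.arange(w, n - w)
        before = pts[i] - pts[i - w]
        after = pts[i + w] - pts[i]
        dot = (before * after).sum(axis=1)
        cross = before[:, 0] * after[:, 1] - before[:, 1] * after[:, 0]
        return np.degrees(np.abs(np.arctan2(cross, dot)))

    coarse_w = 2 * window
    if n >= 2 * coarse_w + 1:
        # only positions where both scales are measurable count: a bend
        # closer than 2 x window to a chain end cannot be scale-validated,
        # and such terminal hooks are segmentation artifacts, not fusions
        idx = np.arange(coarse_w, n - coarse_w)
        fine = np.full(n, np.inf)
        fine[window : n - window] = turning(window)
        angles = np.minimum(fine[idx], turning(coarse_w))
    else:
        idx = np.arange(window, n - window)
        angles = turning(window)
    # local maxima above threshold (plateau-tolerant: >= neighbors)
    candidates = []
    for k in range(len(angles)):
        if angles[k] <= angle_threshold:
            continue
        left = angles[k - 1] if k > 0 else -np.inf
        right = angles[k + 1] if k < len(angles) - 1 else -np.inf
        if angles[k] >= left and angles[k] > right:
            candidates.append((angles[k], int(idx[k])))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    kept: list[int] = []
    for _, pos in candidates:
        if all(abs(pos - other) >= min_separation for other in kept):
            kept.append(pos)
    return len(kept)


# ---------------------------------------------------------------------------
# the count


def count_spikes(mask: np.ndarray, params: CountParams = CountParams()) -> CountResult:
    """Count spikes in a cleaned binary mask.

    ``n_region`` counts connected components; every overlap candidate
    contributes its backbone inflection count to ``n_point``; the total is
    their sum (a fused pair bends once, adding one to the two-spike count
    its single region would otherwise miss).
    """
    mask = np.asarray(mask).astype(bool)
    labels = measure.label(mask, connectivity=2)
    stats = flag_overlap_candidates(
        region_statistics(mask),
        area_factor=params.area_factor,
        elongation_limit=params.elongation_limit,
    )
    per_region = []
    n_point = 0
    for s in stats:
        if s.is_overlap_candidate:
            region = labels == s.region_id
            bb = extract_backbone(region, spur_length=params.resolved_spur_length())
            k = count_inflections(
                bb,
                window=params.window,
                angle_threshold=params.angle_threshold,
                min_separation=params.min_separation,
            )
            s = replace(s, n_inflections=k)
            n_point += k
        per_region.append(s)
    return CountResult(
        n_region=len(stats), n_point=n_point, per_region=tuple(per_region)
    )


def count_image(mask: np.ndarray, params: CountParams = CountParams()) -> CountResult:
    """clean_mask followed by count_spikes — the full counting stage."""
    cleaned = clean_mask(mask, open_radius=params.open_radius, min_area=params.min_area)
    return count_spikes(cleaned, params)


# ---------------------------------------------------------------------------
# evaluation


def accuracy(automatic: float, manual: float) -> float:
    """Per-image accuracy A = (1 - |N_c - N_a| / N_a) x 100 (percent).

    Negative when the automatic count is off by more than the manual count
    itself; reported as-is.
    """
    if manual < 1:
        raise ValueError("manual benchmark count must be >= 1")
    return (1.0 - abs(automatic - manual) / manual) * 100.0


def evaluate(pairs: list[tuple[float, float]]) -> EvalResult:
    """Accuracy, correlation and regression of automatic on manual counts.

    Pearson r (and hence R^2, slope) are NaN when either coordinate has zero
    variance; the accuracies are still reported.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (automatic, manual) pairs")
    nc = np.asarray([p[0] for p in pairs], dtype=np.float64)
    na = np.asarray([p[1] for p in pairs], dtype=np.float64)
    accs = tuple(accuracy(c, a) for c, a in zip(nc, na))
    if np.ptp(nc) == 0 or np.ptp(na) == 0:
        r = slope = intercept = r2 = float("nan")
    else:
        res = stats.linregress(na, nc)
        r, slope, intercept = float(res.rvalue), float(res.slope), float(res.intercept)
        r2 = r * r
    return EvalResult(
        per_image_accuracy=accs,
        mean_accuracy=float(np.mean(accs)),
        pearson_r=r,
        r_squared=r2,
        slope=slope,
        intercept=intercept,
    )
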