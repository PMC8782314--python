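"""Medial axis of the white space between contours.

The axis is detected on the exact Euclidean distance transform of the
contour mask: axis pixels are sinks of the normalized distance-gradient
field, found by thresholding the average outward flux through the
8-neighborhood. Each axis point carries the radius R (its distance value)
and a generating pair — the nearest contour pixel on each side, reached by
steepest descent of the distance map in two opposed directions.

The image border is not a contour: points whose descent walk exits the
canvas are dropped as border-generated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import heapq

import numpy as np
from scipy import ndimage

from ribbonsym.contour_model import RasterDrawing

__all__ = [
    "DistanceMap",
    "MedialAxis",
    "distance_transform",
    "extract_medial_axis",
    "trace_branches",
    "average_outward_flux",
]

DEFAULT_FLUX_THRESHOLD = -0.25

# 8-neighborhood offsets (dy, dx) and their unit outward directions
_N8 = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)], dtype=int)
_N8_UNIT = _N8 / np.linalg.norm(_N8, axis=1, keepdims=True)


@dataclass
class DistanceMap:
    """Exact Euclidean distance to the nearest contour pixel.

    dist    : (H, W) float distances in px, 0 exactly on contour pixels.
    nearest : (2, H, W) int (row, col) of one nearest contour pixel.
    mask    : the contour mask the map was computed from.
    """

    dist: np.ndarray
    nearest: np.ndarray
    mask: np.ndarray


@dataclass
class MedialAxis:
    """Axis pixels with radius function and branch structure.

    points     : (n, 2) int (row, col) axis pixel coordinates.
    radius     : (n,) float, distance-map value at each axis pixel (> 0).
    flux       : (n,) float, average outward flux at each axis pixel.
    generators : (n, 2, 2) int; [i, side] = (row, col) of the contour pixel
                 reached on each side. Both sides equal when only one
                 generator resolves.
    branch_id  : (n,) int, filled by :func:`trace_branches` (-1 before).
    arc_index  : (n,) int, position along the branch (-1 before).
    """

    points: np.ndarray
    radius: np.ndarray
    flux: np.ndarray
    generators: np.ndarray
    branch_id: np.ndarray = field(default=None)
    arc_index: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.points)
        if self.branch_id is None:
            self.branch_id = np.full(n, -1, dtype=int)
        if self.arc_index is None:
            self.arc_index = np.full(n, -1, dtype=int)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_branches(self) -> int:
        return int(self.branch_id.max()) + 1 if len(self) else 0

    def branch_order(self, bid: int) -> np.ndarray:
        """Indices of branch `bid` points sorted by arc index."""
        idx = np.flatnonzero(self.branch_id == bid)
        return idx[np.argsort(self.arc_index[idx])]


def distance_transform(raster: RasterDrawing) -> DistanceMap:
    """Exact Euclidean distance transform of the contour mask.

    Also returns, per pixel, the coordinates of one nearest contour pixel
    (consistent with the distances).
    """
    mask = raster.mask
    if not mask.any():
        raise ValueError("cannot compute distance transform of an empty raster")
    dist, indices = ndimage.distance_transform_edt(~mask, return_indices=True)
    return DistanceMap(dist=dist, nearest=indices, mask=mask)


def average_outward_flux(dist: np.ndarray) -> np.ndarray:
    """Average outward flux of the normalized distance gradient.

    For each pixel p: mean over 8-neighbors q of
    <grad D(q) / |grad D(q)|, (q - p) / |q - p|>. Out-of-canvas neighbors
    are skipped. Strongly negative values mark gradient sinks, i.e. the
    medial axis.
    """
    gy, gx = np.gradient(dist)
    norm = np.hypot(gy, gx)
    with np.errstate(invalid="ignore", divide="ignore"):
        ny = np.where(norm > 1e-12, gy / norm, 0.0)
        nx = np.where(norm > 1e-12, gx / norm, 0.0)
    h, w = dist.shape
    total = np.zeros((h, w))
    count = np.zeros((h, w))
    for (dy, dx), (uy, ux) in zip(_N8, _N8_UNIT):
        sl_dst = (slice(max(0, -dy), h - max(0, dy)),
                  slice(max(0, -dx), w - max(0, dx)))
        sl_src = (slice(max(0, dy), h - max(0, -dy)),
                  slice(max(0, dx), w - max(0, -dx)))
        total[sl_dst] += ny[sl_src] * uy + nx[sl_src] * ux
        count[sl_dst] += 1
    return total / count


def _is_simple(on: np.ndarray, y: int, x: int) -> bool:
    """Yokoi connectivity test: removing (y, x) preserves topology of the
    8-connected foreground iff its connectivity number is 1."""
    h, w = on.shape

    def val(dy, dx):
        yy, xx = y + dy, x + dx
        return bool(on[yy, xx]) if 0 <= yy < h and 0 <= xx < w else False

    # neighbors counter-clockwise starting east; 4-neighbors at even slots
    n = [val(0, 1), val(-1, 1), val(-1, 0), val(-1, -1),
         val(0, -1), val(1, -1), val(1, 0), val(1, 1)]
    if not any(n):
        return False  # isolated point: removal destroys the component
    c = 0
    for k in (0, 2, 4, 6):  # 8-connectivity: count on the complement
        a = 1 - int(n[k])
        b = 1 - int(n[(k + 1) % 8])
        d = 1 - int(n[(k + 2) % 8])
        c += a - a * b * d
    return c == 1


def _thin_candidates(candidate: np.ndarray, dist: np.ndarray,
                     flux: np.ndarray) -> np.ndarray:
    """Homotopic thinning of the sink set, guided by distance and flux.

    Simple points are removed in increasing (distance, flux) order — weaker
    sinks and smaller radii go first — so the surviving 1-px skeleton sits
    on the local distance ridge. Endpoints (a single remaining neighbor)
    are preserved: every candidate already passed the flux threshold."""
    on = candidate.copy()
    heap = [(dist[y, x], flux[y, x], int(y), int(x))
            for y, x in zip(*np.nonzero(candidate))]
    heapq.heapify(heap)
    while heap:
        _, _, y, x = heapq.heappop(heap)
        if not on[y, x]:
            continue
        nb = [(y + dy, x + dx) for dy, dx in _N8
              if 0 <= y + dy < on.shape[0] and 0 <= x + dx < on.shape[1]
              and on[y + dy, x + dx]]
        if len(nb) <= 1:
            continue  # endpoint (or isolated): keep
        if not _is_simple(on, y, x):
            continue
        on[y, x] = False
        for yy, xx in nb:  # neighbors may have become removable
            heapq.heappush(heap, (dist[yy, xx], flux[yy, xx], yy, xx))
    return on


def _descend_to_contour(dmap: DistanceMap, start: tuple[int, int],
                        first_step: np.ndarray) -> tuple[int, int] | None:
    """Greedy steepest-descent walk from `start`, forced through `first_step`,
    until a contour pixel (dist == 0) is reached. Returns None if the walk
    leaves the canvas or stalls."""
    h, w = dmap.dist.shape
    y, x = start[0] + first_step[0], start[1] + first_step[1]
    if not (0 <= y < h and 0 <= x < w):
        return None
    for _ in range(h + w):  # descent strictly decreases; this bounds the walk
        if dmap.dist[y, x] == 0:
            return (y, x)
        # jump straight to the recorded nearest contour pixel: it is the
        # steepest-descent endpoint from here
        return (int(dmap.nearest[0, y, x]), int(dmap.nearest[1, y, x]))
    return None


def _generating_pair(dmap: DistanceMap, y: int, x: int) -> np.ndarray | None:
    """Nearest contour pixel on each side of an axis point.

    Side one is the globally nearest contour pixel from the EDT. Side two
    follows the most opposed descent direction among the 8 neighbors. If no
    opposed descent resolves to a distinct pixel, both sides are the single
    generator."""
    g1 = np.array([dmap.nearest[0, y, x], dmap.nearest[1, y, x]], dtype=int)
    d1 = np.array([g1[0] - y, g1[1] - x], dtype=float)
    n1 = np.linalg.norm(d1)
    if n1 == 0:
        return None
    d1 /= n1
    h, w = dmap.dist.shape
    best = None
    best_key = None
    for dy, dx in _N8:
        yy, xx = y + dy, x + dx
        if not (0 <= yy < h and 0 <= xx < w):
            continue
        step = np.array([dy, dx], dtype=float)
        step /= np.linalg.norm(step)
        opp = d1 @ step
        if opp >= 0.0:  # only directions pointing away from side one
            continue
        drop = dmap.dist[y, x] - dmap.dist[yy, xx]
        if drop <= -0.5:  # ascending; not a descent direction
            continue
        key = (drop, -opp)
        if best_key is None or key > best_key:
            best_key = key
            best = (yy, xx)
    if best is None:
        return np.stack([g1, g1])
    g2 = _descend_to_contour(dmap, (y, x), np.array(best) - np.array([y, x]))
    if g2 is None:
        return None
    g2 = np.asarray(g2, dtype=int)
    return np.stack([g1, g2])


def extract_medial_axis(dmap: DistanceMap,
                        flux_threshold: float = DEFAULT_FLUX_THRESHOLD) -> MedialAxis:
    """Extract the medial axis as pixels of strongly negative outward flux.

    Axis pixels are non-contour pixels whose average outward flux falls
    below `flux_threshold`. Each stores its radius (distance value) and
    generating contour-pixel pair. Points whose generator lookup fails
    (border-generated) are discarded.
    """
    flux = average_outward_flux(dmap.dist)
    candidate = (flux < flux_threshold) & ~dmap.mask & (dmap.dist > 0)
    # one-sided gradients make flux unreliable on the outermost ring, and
    # the canvas border is not a contour: drop the ring
    candidate[0, :] = candidate[-1, :] = False
    candidate[:, 0] = candidate[:, -1] = False
    # the thresholded sink set can be 2-3 px wide where wavefronts collide
    # mid-pixel; thin it to a 1-px skeleton guided by distance and flux
    candidate = _thin_candidates(candidate, dmap.dist, flux)
    ys, xs = np.nonzero(candidate)
    if len(ys) == 0:
        warnings.warn("no medial axis points found (degenerate raster?)",
                      stacklevel=2)
        return MedialAxis(points=np.empty((0, 2), dtype=int),
                          radius=np.empty(0), flux=np.empty(0),
                          generators=np.empty((0, 2, 2), dtype=int))
    points, radius, fvals, gens = [], [], [], []
    for y, x in zip(ys, xs):
        pair = _generating_pair(dmap, int(y), int(x))
        if pair is None:
            continue
        points.append((y, x))
        radius.append(dmap.dist[y, x])
        fvals.append(flux[y, x])
        gens.append(pair)
    return MedialAxis(points=np.asarray(points, dtype=int).reshape(-1, 2),
                      radius=np.asarray(radius, dtype=float),
                      flux=np.asarray(fvals, dtype=float),
                      generators=np.asarray(gens, dtype=int).reshape(-1, 2, 2))


def trace_branches(axis: MedialAxis) -> MedialAxis:
    """Group 8-connected axis pixels into simple branches.

    Junction pixels (>= 3 axis neighbors) split the axis into simple arcs;
    each junction pixel is appended to one incident arc (the lowest branch
    id) so that every axis pixel belongs to exactly one branch. Arc indices
    increase consecutively along each branch. Isolated pixels become
    length-1 branches.
    """
    n = len(axis)
    if n == 0:
        return axis
    index_of = {(int(y), int(x)): i for i, (y, x) in enumerate(axis.points)}

    def neighbors(i):
        y, x = axis.points[i]
        out = []
        for dy, dx in _N8:
            j = index_of.get((int(y) + int(dy), int(x) + int(dx)))
            if j is not None:
                out.append(j)
        return out

    nbrs = [neighbors(i) for i in range(n)]
    degree = np.array([len(v) for v in nbrs])
    is_junction = degree >= 3

    branch_id = np.full(n, -1, dtype=int)
    arc_index = np.full(n, -1, dtype=int)
    visited = np.zeros(n, dtype=bool)
    next_bid = 0

    def simple_neighbors(i):
        return [j for j in nbrs[i] if not is_junction[j]]

    # walk each simple arc from an endpoint (or any point, for cycles)
    order = sorted(
        (i for i in range(n) if not is_junction[i]),
        key=lambda i: (len(simple_neighbors(i)), i),
    )
    for start in order:
        if visited[start]:
            continue
        chain = [start]
        visited[start] = True
        prev, cur = None, start
        while True:
            nxt = [j for j in simple_neighbors(cur)
                   if not visited[j] and j != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            visited[cur] = True
            chain.append(cur)
        for k, i in enumerate(chain):
            branch_id[i] = next_bid
            arc_index[i] = k
        next_bid += 1

    # attach each junction pixel to its lowest-id incident branch,
    # at whichever end of that branch it touches; junctions with no
    # non-junction neighbor become their own branches
    for i in np.flatnonzero(is_junction):
        incident = sorted({branch_id[j] for j in nbrs[i] if branch_id[j] >= 0})
        if not incident:
            branch_id[i] = next_bid
            arc_index[i] = 0
            next_bid += 1
            continue
        bid = incident[0]
        members = np.flatnonzero(branch_id == bid)
        touching = [j for j in nbrs[i] if branch_id[j] == bid]
        end_arcs = [arc_index[j] for j in touching]
        branch_id[i] = bid
        if min(end_arcs) == 0 and arc_index[members].min() == 0:
            arc_index[members] += 1  # prepend
            arc_index[i] = 0
        else:
            arc_index[i] = arc_index[members].max() + 1  # append

    axis.branch_id = branch_id
    axis.arc_index = arc_index
    return axis
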