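"""Vector line drawings, binary rasters, and their I/O.

A drawing is a list of open or closed polyline contours on a pixel canvas.
Coordinates are 0-based with x growing rightward and y growing downward;
pixel centers sit on integer coordinates. Rasterization uses integer
Bresenham lines (8-connected, one pixel wide, no anti-aliasing), which is
what the medial-axis scoring consumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "Contour",
    "LineDrawing",
    "RasterDrawing",
    "rasterize",
    "bresenham_line",
    "read_drawing",
    "write_drawing",
    "read_raster_png",
    "write_raster_png",
]


@dataclass(frozen=True)
class Contour:
    """An ordered polyline in pixel units.

    Parameters
    ----------
    points : (n, 2) float array of (x, y) positions, n >= 2.
    closed : if True the last point connects back to the first implicitly
        (the closing point must not be duplicated).
    """

    points: np.ndarray
    closed: bool = False

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"contour points must be (n, 2), got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError("a contour needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour coordinates must be finite")
        if self.closed and np.array_equal(pts[0], pts[-1]):
            raise ValueError("closed contour must not duplicate its endpoint")
        object.__setattr__(self, "points", pts)

    def segments(self):
        """Yield (p0, p1) vertex pairs, including the closing edge if closed."""
        pts = self.points
        for i in range(len(pts) - 1):
            yield pts[i], pts[i + 1]
        if self.closed:
            yield pts[-1], pts[0]


@dataclass(frozen=True)
class LineDrawing:
    """A set of contours on a (height, width) pixel canvas."""

    contours: list[Contour]
    canvas: tuple[int, int]
    category: str | None = None

    def __post_init__(self):
        h, w = self.canvas
        if h < 1 or w < 1:
            raise ValueError("canvas must be at least 1x1")
        for i, c in enumerate(self.contours):
            x, y = c.points[:, 0], c.points[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() >= w or y.max() >= h:
                raise ValueError(
                    f"contour {i} leaves the canvas "
                    f"(x in [{x.min()}, {x.max()}], y in [{y.min()}, {y.max()}], "
                    f"canvas {h}x{w})"
                )


@dataclass
class RasterDrawing:
    """Binary raster of a drawing.

    mask        : (H, W) bool, True on contour pixels.
    provenance  : (H, W) int, contour index per contour pixel, -1 elsewhere.
                  Where two contours share a pixel the lower index wins.
    """

    mask: np.ndarray
    provenance: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=int)
            if self.provenance.shape != self.mask.shape:
                raise ValueError("provenance shape must match mask")
            bad = (self.provenance >= 0) & ~self.mask
            if bad.any():
                raise ValueError("provenance set on non-contour pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def bresenham_line(x0: int, y0: int, x1: int, y1: int) -> np.ndarray:
    """Integer Bresenham line from (x0, y0) to (x1, y1), inclusive.

    Returns (n, 2) int array of (x, y); n == max(|dx|, |dy|) + 1.
    """
    dx, dy = abs(x1 - x0), abs(y1 - y0)
    sx = 1 if x1 >= x0 else -1
    sy = 1 if y1 >= y0 else -1
    pts = []
    x, y = x0, y0
    err = dx - dy
    while True:
        pts.append((x, y))
        if x == x1 and y == y1:
            break
        e2 = 2 * err
        if e2 > -dy:
            err -= dy
            x += sx
        if e2 < dx:
            err += dx
            y += sy
    return np.asarray(pts, dtype=int)


def rasterize(drawing: LineDrawing) -> RasterDrawing:
    """Render a drawing as an 8-connected 1-px-wide binary raster.

    Vertices are rounded to the nearest pixel; each polyline segment is a
    Bresenham line. Provenance records the contour index of each pixel,
    ties going to the lower contour index.
    """
    h, w = drawing.canvas
    mask = np.zeros((h, w), dtype=bool)
    prov = np.full((h, w), -1, dtype=int)
    if not drawing.contours:
        warnings.warn("rasterizing an empty drawing", stacklevel=2)
        return RasterDrawing(mask, prov)
    # higher indices first so lower indices overwrite on ties
    for ci in range(len(drawing.contours) - 1, -1, -1):
        for p0, p1 in drawing.contours[ci].segments():
            x0, y0 = int(round(p0[0])), int(round(p0[1]))
            x1, y1 = int(round(p1[0])), int(round(p1[1]))
            pts = bresenham_line(x0, y0, x1, y1)
            mask[pts[:, 1], pts[:, 0]] = True
            prov[pts[:, 1], pts[:, 0]] = ci
    return RasterDrawing(mask, prov)


# ---------------------------------------------------------------------------
# I/O: JSON vector format, 1-bit PNG rasters


def write_drawing(path, drawing: LineDrawing) -> None:
    """Serialize a drawing to JSON (lossless float round-trip)."""
    doc = {
        "canvas": list(drawing.canvas),
        "category": drawing.category,
        "contours": [
            {"points": c.points.tolist(), "closed": bool(c.closed)}
            for c in drawing.contours
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_drawing(path) -> LineDrawing:
    """Read a drawing from the JSON format written by :func:`write_drawing`."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"{path}: not valid JSON at line {e.lineno}: {e.msg}") from e
    for key in ("canvas", "contours"):
        if key not in doc:
            raise ValueError(f"{path}: missing required field '{key}'")
    contours = []
    for i, c in enumerate(doc["contours"]):
        if "points" not in c:
            raise ValueError(f"{path}: contour {i} missing 'points'")
        try:
            contours.append(Contour(np.asarray(c["points"], dtype=float),
                                    closed=bool(c.get("closed", False))))
        except ValueError as e:
            raise ValueError(f"{path}: contour {i}: {e}") from e
    return LineDrawing(contours, tuple(doc["canvas"]), category=doc.get("category"))


def write_raster_png(path, raster: RasterDrawing) -> None:
    """Export the mask as a 1-bit PNG (white contour on black)."""
    Image.fromarray(raster.mask).convert("1").save(path, format="PNG")


def read_raster_png(path) -> RasterDrawing:
    """Read a 1-bit (or grayscale) PNG back into a RasterDrawing."""
    img = Image.open(path).convert("L")
    mask = np.asarray(img) > 127
    return RasterDrawing(mask)
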