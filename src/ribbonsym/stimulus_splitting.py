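"""Split a scored drawing into most- and least-parallel half-images.

Contour pixels are rank-ordered by score (descending); the top half forms
the "most parallel" image, the bottom half the "least parallel" image. The
two halves are disjoint, union to the intact raster, and contain equal
pixel counts (within one pixel for odd totals, the extra pixel going to
"most"). Ties in score are broken by a seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ribbonsym.contour_model import RasterDrawing
from ribbonsym.ribbon_scoring import ContourScoreMap

__all__ = ["SplitPair", "split_half"]


@dataclass
class SplitPair:
    most: RasterDrawing
    least: RasterDrawing
    intact: RasterDrawing
    threshold_rank: int


def split_half(score_map: ContourScoreMap, seed: int = 0) -> SplitPair:
    """Rank contour pixels by score and split them into equal halves."""
    raster = score_map.raster
    ys, xs = np.nonzero(raster.mask)
    n = len(ys)
    if n == 0:
        raise ValueError("cannot split an empty score map")
    scores = score_map.score[ys, xs]
    if np.isnan(scores).any():
        raise ValueError("all contour pixels must have assigned scores")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)  # seeded tie-break, then stable sort
    order = perm[np.argsort(-scores[perm], kind="stable")]
    k = (n + 1) // 2  # odd N: extra pixel goes to "most"
    most_mask = np.zeros_like(raster.mask)
    least_mask = np.zeros_like(raster.mask)
    top = order[:k]
    bot = order[k:]
    most_mask[ys[top], xs[top]] = True
    least_mask[ys[bot], xs[bot]] = True

    def _sub(mask):
        prov = None
        if raster.provenance is not None:
            prov = np.where(mask, raster.provenance, -1)
        return RasterDrawing(mask, prov)

    return SplitPair(most=_sub(most_mask), least=_sub(least_mask),
                     intact=raster, threshold_rank=k)
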