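"""Ribbon-symmetry (local parallelism) scoring.

An axis point's score counts changes of the radius function across a local
window of its branch: with n supra-threshold changes in a window of
realized length W_eff, sigma = 1 - n / (W_eff - 1). Constant radius
(parallel flanking contours) gives sigma = 1; a change at every step gives
sigma = 0. Scores flow back to the contour pixels each axis point was
generated by; a contour pixel flanked by axes on both sides keeps the
maximum of the scores it receives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ribbonsym.contour_model import RasterDrawing
from ribbonsym.medial_axis import MedialAxis

__all__ = [
    "AxisScore",
    "ContourScoreMap",
    "score_axis",
    "project_to_contours",
    "average_parallelism",
    "DEFAULT_WINDOW",
    "DEFAULT_EPSILON",
]

DEFAULT_WINDOW = 11
DEFAULT_EPSILON = 0.5


@dataclass
class AxisScore:
    """Per-axis-point change counts and scores.

    n_changes : (n,) int, radius changes > epsilon within the window
    w_eff     : (n,) int, realized window length (truncated at branch ends)
    sigma     : (n,) float in [0, 1]
    """

    n_changes: np.ndarray
    w_eff: np.ndarray
    sigma: np.ndarray
    window: int
    epsilon: float


@dataclass
class ContourScoreMap:
    """Per-contour-pixel parallelism scores.

    score    : (H, W) float, in [0, 1] on contour pixels, NaN elsewhere
    raster   : the scored raster (mask + provenance)
    """

    score: np.ndarray
    raster: RasterDrawing

    def contour_scores(self) -> np.ndarray:
        """Scores of all contour pixels (1-D, raster order)."""
        return self.score[self.raster.mask]


def score_axis(axis: MedialAxis, window: int = DEFAULT_WINDOW,
               epsilon: float = DEFAULT_EPSILON) -> AxisScore:
    """Score every axis point by radius changes in a centered branch window.

    For each point, the window is the `window`-point run of its branch
    centered on it (truncated at branch ends); n counts consecutive pairs
    whose radius differs by more than `epsilon`. Length-1 windows score 1.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    n = len(axis)
    n_changes = np.zeros(n, dtype=int)
    w_eff = np.ones(n, dtype=int)
    sigma = np.ones(n)
    half = window // 2
    for bid in range(axis.n_branches):
        order = axis.branch_order(bid)
        radii = axis.radius[order]
        m = len(order)
        changed = np.abs(np.diff(radii)) > epsilon if m > 1 else np.empty(0, bool)
        for k, i in enumerate(order):
            lo, hi = max(0, k - half), min(m, k + half + 1)
            we = hi - lo
            nc = int(changed[lo:hi - 1].sum()) if we > 1 else 0
            n_changes[i] = nc
            w_eff[i] = we
            sigma[i] = 1.0 - nc / (we - 1) if we > 1 else 1.0
    return AxisScore(n_changes=n_changes, w_eff=w_eff, sigma=sigma,
                     window=window, epsilon=epsilon)


def project_to_contours(axis_score: AxisScore, axis: MedialAxis,
                        raster: RasterDrawing) -> ContourScoreMap:
    """Assign axis scores to the contour pixels they were generated by.

    Each contour pixel takes the maximum score over all axis points whose
    generating pair contains it (a contour is typically flanked by a
    skeleton on each side). Contour pixels reached by no axis point are
    filled from the nearest assigned pixel of the same contour (ties take
    the maximum score); contours with no assigned pixel at all score 0.
    """
    h, w = raster.mask.shape
    score = np.full((h, w), np.nan)
    assigned = np.zeros((h, w), dtype=bool)
    for i in range(len(axis)):
        s = axis_score.sigma[i]
        for side in range(2):
            y, x = axis.generators[i, side]
            if not raster.mask[y, x]:
                continue  # stale generator (raster edited); skip
            if not assigned[y, x] or s > score[y, x]:
                score[y, x] = s
                assigned[y, x] = True

    prov = raster.provenance
    if prov is None:
        prov = np.where(raster.mask, 0, -1)
    ys, xs = np.nonzero(raster.mask & ~assigned)
    if len(ys):
        for ci in np.unique(prov[ys, xs]):
            miss = (prov == ci) & raster.mask & ~assigned
            have = (prov == ci) & assigned
            mys, mxs = np.nonzero(miss)
            if not have.any():
                score[mys, mxs] = 0.0
                continue
            hys, hxs = np.nonzero(have)
            d = cdist(np.column_stack([mys, mxs]), np.column_stack([hys, hxs]))
            vals = score[hys, hxs]
            dmin = d.min(axis=1)
            for r in range(len(mys)):
                tied = d[r] <= dmin[r] + 1e-9
                score[mys[r], mxs[r]] = vals[tied].max()
    return ContourScoreMap(score=score, raster=raster)


def average_parallelism(score_map: ContourScoreMap) -> float:
    """Unweighted mean score over all contour pixels of the image."""
    vals = score_map.contour_scores()
    if vals.size == 0:
        raise ValueError("empty score map")
    return float(np.mean(vals))
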