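import numpy as np
import pytest

from ribbonsym.contour_model import Contour, LineDrawing, rasterize
from ribbonsym.medial_axis import distance_transform, extract_medial_axis, trace_branches
from ribbonsym.ribbon_scoring import project_to_contours, score_axis


@pytest.fixture
def parallel_pair():
    """Two full-width horizontal lines 12 px apart on a 64x64 canvas."""
    c1 = Contour(np.array([[0.0, 24.0], [63.0, 24.0]]))
    c2 = Contour(np.array([[0.0, 36.0], [63.0, 36.0]]))
    return LineDrawing([c1, c2], (64, 64))


@pytest.fixture
def wedge_pair():
    """Two segments meeting at a 60 degree opening angle."""
    half = np.deg2rad(30.0)
    length = 70.0
    apex = np.array([10.0, 48.0])
    up = apex + length * np.array([np.cos(half), -np.sin(half)])
    dn = apex + length * np.array([np.cos(half), np.sin(half)])
    return LineDrawing([Contour(np.vstack([apex, up])),
                        Contour(np.vstack([apex, dn]))], (96, 96))


def score_pipeline(drawing_or_raster, window=11, epsilon=0.5):
    """Full scoring chain; accepts a LineDrawing or RasterDrawing."""
    raster = (rasterize(drawing_or_raster)
              if isinstance(drawing_or_raster, LineDrawing)
              else drawing_or_raster)
    dmap = distance_transform(raster)
    axis = trace_branches(extract_medial_axis(dmap))
    ascore = score_axis(axis, window=window, epsilon=epsilon)
    return project_to_contours(ascore, axis, raster)


@pytest.fixture
def scorer():
    return score_pipeline
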