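"""Synthetic line drawings and BOLD datasets with known ground truth.

Drawings are composed of primitives with controllable local parallelism:
straight ribbon pairs (exactly parallel), wavy ribbons (separation jitter),
wedge pairs (separation grows linearly), and random open curves. Shapes are
placed on disjoint grid cells so primitives do not interfere with each
other's medial axes.

BOLD simulators produce voxels x volumes matrices with category-specific
multivoxel patterns (block design) or parametric parallelism modulation
through ROI-specific gamma HRFs (slow event design), plus polynomial drift
and AR(1) noise. Every generator is deterministic under its seed and
returns its ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ribbonsym.contour_model import Contour, LineDrawing, rasterize, write_raster_png
from ribbonsym.decoding_pipeline import RoiDataset
from ribbonsym.experiment_design import (
    BlockDesign,
    DesignMatrix,
    EventDesign,
    N_TENTS,
    TENT_SPACING,
    build_tent_design_matrix,
)
from ribbonsym.medial_axis import distance_transform, extract_medial_axis, trace_branches
from ribbonsym.ribbon_scoring import (
    average_parallelism,
    project_to_contours,
    score_axis,
)
from ribbonsym.stimulus_splitting import split_half

__all__ = [
    "DrawingSpec",
    "generate_drawing",
    "score_drawing",
    "generate_stimulus_set",
    "gamma_hrf",
    "RoiTruth",
    "BlockBoldTruth",
    "EventBoldTruth",
    "make_block_truth",
    "make_event_truth",
    "simulate_block_bold",
    "simulate_event_bold",
    "EventBoldData",
]


# ---------------------------------------------------------------------------
# Line drawings


@dataclass(frozen=True)
class DrawingSpec:
    """Counts and parameters of drawing primitives.

    n_ribbons : straight parallel pairs (jitter 0 -> exactly parallel)
    n_wavy    : ribbon pairs whose separation oscillates by +- jitter px
    n_wedges  : line pairs meeting at `wedge_angle` degrees
    n_curves  : random open polylines
    """

    n_ribbons: int = 1
    n_wavy: int = 0
    n_wedges: int = 1
    n_curves: int = 0
    jitter: float = 2.0
    wedge_angle: float = 60.0
    canvas: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ribbons, self.n_wavy, self.n_wedges, self.n_curves) < 0:
            raise ValueError("primitive counts must be >= 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if not 0.0 < self.wedge_angle <= 90.0:
            raise ValueError("wedge angle must be in (0, 90] degrees")

    @property
    def n_shapes(self) -> int:
        return self.n_ribbons + self.n_wavy + self.n_wedges + self.n_curves


def _bands(canvas, n_shapes, rng):
    """Disjoint full-width horizontal bands (y0, height), shuffled.

    Band placement keeps each primitive's medial-axis neighborhood free of
    other primitives; ribbons span the full canvas width so perfectly
    parallel pairs have no in-canvas endpoints (whose point-point skeleton
    would legitimately score below 1)."""
    h, w = canvas
    bh = h // n_shapes
    if bh < 24 or w < 24:
        raise ValueError(
            f"canvas {canvas} too small for {n_shapes} shapes "
            f"(bands {bh}x{w} < 24x24)")
    bands = [(i * bh, bh) for i in range(n_shapes)]
    rng.shuffle(bands)
    return bands


def _ribbon(band, width, rng, jitter=0.0):
    """A pair of congruent polylines offset by a constant normal distance
    (+- sinusoidal jitter). Jitter-0 ribbons are straight horizontal
    full-width lines at integer rows, so the rasterized radius function is
    exactly constant."""
    y0, bh = band
    margin = 4
    sep = int(rng.integers(8, max(9, bh // 2 - margin)))
    base = int(rng.integers(margin, bh - margin - sep))
    if jitter > 0:
        xs = np.arange(0, width, 4, dtype=float)
        if xs[-1] != width - 1:
            xs = np.append(xs, width - 1)
        phase = rng.uniform(0, 2 * np.pi)
        wavelength = rng.uniform(24, 64)
        y_a = np.full_like(xs, float(base))
        y_b = base + sep + jitter * np.sin(2 * np.pi * xs / wavelength + phase)
        y_b = np.clip(y_b, base + 2, bh - 2)
    else:
        xs = np.array([0.0, width - 1.0])
        y_a = np.full(2, float(base))
        y_b = np.full(2, float(base + sep))
    a = np.column_stack([xs, y_a + y0])
    b = np.column_stack([xs, y_b + y0])
    return [Contour(a), Contour(b)]


def _wedge(band, width, rng, angle_deg):
    """Two segments from a common apex with the given opening angle."""
    y0, bh = band
    margin = 3
    half = math.radians(angle_deg) / 2.0
    x_start = float(rng.integers(0, max(1, width // 4)))
    apex = np.array([x_start + margin, bh / 2.0])
    leg_len = min((width - margin - apex[0]) / math.cos(half),
                  (bh / 2.0 - margin) / max(math.sin(half), 1e-9))
    p_up = apex + leg_len * np.array([math.cos(half), -math.sin(half)])
    p_dn = apex + leg_len * np.array([math.cos(half), math.sin(half)])
    pts = [np.vstack([apex, p_up]), np.vstack([apex, p_dn])]
    return [Contour(p + (0, y0)) for p in pts]


def _curve(band, width, rng):
    """A random open polyline (smooth random walk)."""
    y0, bh = band
    ch, cw = bh, width
    x0 = 0
    margin = 3
    n_pts = int(rng.integers(4, 8))
    pts = np.empty((n_pts, 2))
    pts[0] = rng.uniform([margin, margin], [cw - margin, ch - margin])
    heading = rng.uniform(0, 2 * np.pi)
    step = min(ch, cw) / (n_pts - 1) * 0.8
    for i in range(1, n_pts):
        heading += rng.uniform(-0.9, 0.9)
        cand = pts[i - 1] + step * np.array([np.cos(heading), np.sin(heading)])
        pts[i] = np.clip(cand, margin, [cw - margin - 1, ch - margin - 1])
    pts = np.unique(pts.round(2), axis=0) if len(np.unique(pts.round(2), axis=0)) >= 2 else pts
    return [Contour(pts + (x0, y0))]


def generate_drawing(spec: DrawingSpec) -> tuple[LineDrawing, list[str]]:
    """Generate a drawing from the spec; returns the drawing and a
    per-contour ground-truth label ('parallel' | 'non-parallel')."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    bands = _bands(spec.canvas, spec.n_shapes, rng)
    transpose = h == w and bool(rng.integers(2))  # orientation variety
    contours: list[Contour] = []
    labels: list[str] = []
    ci = 0
    for _ in range(spec.n_ribbons):
        cs = _ribbon(bands[ci], w, rng, jitter=0.0)
        contours += cs
        labels += ["parallel"] * len(cs)
        ci += 1
    for _ in range(spec.n_wavy):
        cs = _ribbon(bands[ci], w, rng, jitter=spec.jitter)
        contours += cs
        labels += ["parallel"] * len(cs)
        ci += 1
    for _ in range(spec.n_wedges):
        cs = _wedge(bands[ci], w, rng, spec.wedge_angle)
        contours += cs
        labels += ["non-parallel"] * len(cs)
        ci += 1
    for _ in range(spec.n_curves):
        cs = _curve(bands[ci], w, rng)
        contours += cs
        labels += ["non-parallel"] * len(cs)
        ci += 1
    if transpose:
        contours = [Contour(c.points[:, ::-1], closed=c.closed) for c in contours]
    return LineDrawing(contours, spec.canvas), labels


def score_drawing(drawing: LineDrawing, window: int = 11, epsilon: float = 0.5,
                  flux_threshold: float = -0.25):
    """Run the full scoring chain on a drawing; returns the score map."""
    raster = rasterize(drawing)
    dmap = distance_transform(raster)
    axis = trace_branches(extract_medial_axis(dmap, flux_threshold))
    ascore = score_axis(axis, window=window, epsilon=epsilon)
    return project_to_contours(ascore, axis, raster)


def generate_stimulus_set(n_drawings: int, out_dir, seed: int = 0,
                          canvas: tuple[int, int] = (256, 256),
                          write_images: bool = True) -> pd.DataFrame:
    """Generate drawings, score them, split each into most/least halves,
    and write intact + most + least PNGs with a CSV manifest.

    Returns the manifest (one row per emitted image: 3 per drawing)."""
    if n_drawings < 1:
        raise ValueError("need at least one drawing")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    categories = ("beach", "city", "forest", "highway", "mountain", "office")
    for di in range(n_drawings):
        sub = int(master.integers(0, 2**31 - 1))
        srng = np.random.default_rng(sub)
        counts = dict(n_ribbons=int(srng.integers(1, 3)),
                      n_wavy=int(srng.integers(0, 2)),
                      n_wedges=int(srng.integers(1, 3)),
                      n_curves=int(srng.integers(0, 2)))
        capacity = max(2, min(canvas) // 26)  # bands need >= 24 px height
        for key in ("n_curves", "n_wavy", "n_wedges", "n_ribbons"):
            while sum(counts.values()) > capacity and counts[key] > (
                    1 if key in ("n_ribbons", "n_wedges") else 0):
                counts[key] -= 1
        spec = DrawingSpec(
            **counts,
            jitter=float(srng.uniform(1.5, 3.0)),
            wedge_angle=float(srng.uniform(45.0, 90.0)),
            canvas=canvas, seed=sub)
        drawing, _ = generate_drawing(spec)
        drawing = LineDrawing(drawing.contours, drawing.canvas,
                              category=categories[di % len(categories)])
        smap = score_drawing(drawing)
        pair = split_half(smap, seed=sub)
        versions = {
            "intact": (pair.intact, float(average_parallelism(smap))),
            "most": (pair.most,
                     float(np.nanmean(smap.score[pair.most.mask]))),
            "least": (pair.least,
                      float(np.nanmean(smap.score[pair.least.mask]))),
        }
        for version, (raster, mean_score) in versions.items():
            fname = f"stim_{di:04d}_{version}.png"
            if write_images:
                write_raster_png(out_dir / fname, raster)
            rows.append(dict(drawing_id=di, category=drawing.category,
                             version=version, path=fname,
                             n_pixels=raster.n_pixels, mean_score=mean_score))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# BOLD simulators


def gamma_hrf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Gamma-shaped HRF A*t^(k-1)*exp(-t/theta), peak-normalized to 1.

    The mode sits at (shape - 1) * scale seconds."""
    if shape <= 1 or scale <= 0:
        raise ValueError("need shape > 1 and scale > 0 for a unimodal HRF")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = t[pos] ** (shape - 1) * np.exp(-t[pos] / scale)
    mode = (shape - 1) * scale
    peak = mode ** (shape - 1) * np.exp(-mode / scale)
    return out / peak


@dataclass
class RoiTruth:
    """Ground truth for one simulated ROI."""

    name: str
    n_voxels: int
    hrf_shape: float = 6.0
    hrf_scale: float = 0.9
    # block design: 6 category pattern vectors and per-condition separability
    category_patterns: np.ndarray | None = None  # (6, n_voxels)
    separability: dict[str, float] = field(default_factory=dict)
    # event design: per-voxel parametric couplings
    beta_parallelism: np.ndarray | None = None
    beta_luminance: np.ndarray | None = None
    beta_contrast: np.ndarray | None = None
    unmod_amplitude: np.ndarray | None = None

    @property
    def hrf_mode(self) -> float:
        return (self.hrf_shape - 1) * self.hrf_scale


@dataclass
class BlockBoldTruth:
    rois: dict[str, RoiTruth]
    noise_sigma: float
    ar_phi: float
    drift_amplitude: float
    baseline: float
    seed: int


@dataclass
class EventBoldTruth:
    rois: dict[str, RoiTruth]
    noise_sigma: float
    ar_phi: float
    drift_amplitude: float
    seed: int


@dataclass
class EventBoldData:
    data: np.ndarray  # (V, T)
    roi_labels: np.ndarray
    design: EventDesign
    design_matrix: DesignMatrix
    truth: EventBoldTruth


def make_block_truth(roi_specs: dict[str, dict], seed: int = 0,
                     noise_sigma: float = 0.5, ar_phi: float = 0.3,
                     drift_amplitude: float = 0.5,
                     baseline: float = 100.0,
                     pattern_scale: float = 1.0) -> BlockBoldTruth:
    """Sample category patterns per ROI.

    roi_specs: name -> dict(n_voxels, separability={cond: mult},
    hrf_shape?, hrf_scale?)."""
    rng = np.random.default_rng(seed)
    rois = {}
    for name, cfg in roi_specs.items():
        nv = cfg["n_voxels"]
        rois[name] = RoiTruth(
            name=name, n_voxels=nv,
            hrf_shape=cfg.get("hrf_shape", 6.0),
            hrf_scale=cfg.get("hrf_scale", 0.9),
            category_patterns=pattern_scale * rng.standard_normal((6, nv)),
            separability=dict(cfg.get("separability",
                                      {"intact": 1.0, "most": 1.0, "least": 1.0})))
    return BlockBoldTruth(rois=rois, noise_sigma=noise_sigma, ar_phi=ar_phi,
                          drift_amplitude=drift_amplitude, baseline=baseline,
                          seed=seed)


def make_event_truth(roi_specs: dict[str, dict], seed: int = 0,
                     noise_sigma: float = 0.5, ar_phi: float = 0.3,
                     drift_amplitude: float = 0.5) -> EventBoldTruth:
    """Sample per-voxel parametric couplings per ROI.

    roi_specs: name -> dict(n_voxels, hrf_shape, hrf_scale, beta_mean,
    beta_sd?, lum_sd?, con_sd?, unmod_mean?)."""
    rng = np.random.default_rng(seed)
    rois = {}
    for name, cfg in roi_specs.items():
        nv = cfg["n_voxels"]
        rois[name] = RoiTruth(
            name=name, n_voxels=nv,
            hrf_shape=cfg.get("hrf_shape", 6.0),
            hrf_scale=cfg.get("hrf_scale", 0.9),
            beta_parallelism=cfg.get("beta_mean", 1.0)
            + cfg.get("beta_sd", 0.0) * rng.standard_normal(nv),
            beta_luminance=cfg.get("lum_sd", 0.0) * rng.standard_normal(nv),
            beta_contrast=cfg.get("con_sd", 0.0) * rng.standard_normal(nv),
            unmod_amplitude=cfg.get("unmod_mean", 1.0) * np.ones(nv))
    return EventBoldTruth(rois=rois, noise_sigma=noise_sigma, ar_phi=ar_phi,
                          drift_amplitude=drift_amplitude, seed=seed)


def _ar1_noise(rng, shape, sigma, phi):
    white = rng.standard_normal(shape)
    if phi == 0:
        return sigma * white
    out = np.empty_like(white)
    out[..., 0] = white[..., 0]
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + math.sqrt(1 - phi**2) * white[..., t]
    return sigma * out


def simulate_block_bold(design: BlockDesign, truth: BlockBoldTruth,
                        hrf_length: float = 20.0,
                        motion_coupling: float = 0.0) -> RoiDataset:
    """Simulate a block-design dataset for all ROIs in the truth.

    Voxel signal = baseline + sum over blocks of
    (category pattern x condition separability) convolved with the ROI HRF,
    plus Legendre drift and AR(1) noise. Motion series are returned (and
    optionally coupled into the data)."""
    rng = np.random.default_rng(truth.seed + 1)
    tr = design.tr
    n_per_run = design.volumes_per_run
    n_runs = len(design.runs)
    n_total = n_per_run * n_runs
    dt = 0.1
    t_hi = np.arange(0, design.run_duration, dt)
    vol_idx = (np.arange(n_per_run) * tr / dt).astype(int)

    roi_labels = np.concatenate([[name] * roi.n_voxels
                                 for name, roi in truth.rois.items()])
    n_vox = len(roi_labels)
    data = np.full((n_vox, n_total), truth.baseline, dtype=float)
    run_ids = np.repeat(np.arange(n_runs), n_per_run)
    cat_index = {c: i for i, c in enumerate(
        sorted({b.category for run in design.runs for b in run}))}

    kernels = {}
    for name, roi in truth.rois.items():
        k = gamma_hrf(np.arange(0, hrf_length, dt), roi.hrf_shape, roi.hrf_scale)
        kernels[name] = k

    motion = np.cumsum(0.05 * rng.standard_normal((n_total, 6)), axis=0)

    for ri, run in enumerate(design.runs):
        cols = slice(ri * n_per_run, (ri + 1) * n_per_run)
        for b in run:
            box = ((t_hi >= b.onset) & (t_hi < b.offset)).astype(float)
            v0 = 0
            for name, roi in truth.rois.items():
                reg = np.convolve(box, kernels[name])[:len(t_hi)][vol_idx]
                sep = roi.separability.get(b.condition, 1.0)
                vec = sep * roi.category_patterns[cat_index[b.category]]
                data[v0:v0 + roi.n_voxels, cols] += np.outer(vec, reg)
                v0 += roi.n_voxels
        # per-run quadratic drift
        x = np.linspace(-1, 1, n_per_run)
        for d in (1, 2):
            coef = truth.drift_amplitude * rng.standard_normal(n_vox)
            data[:, cols] += np.outer(coef,
                                      np.polynomial.legendre.Legendre.basis(d)(x))
    if truth.noise_sigma > 0:
        data += _ar1_noise(rng, (n_vox, n_total), truth.noise_sigma, truth.ar_phi)
    if motion_coupling:
        w = motion_coupling * rng.standard_normal((n_vox, 6))
        data += w @ motion.T
    return RoiDataset(data=data, roi_labels=roi_labels, run_ids=run_ids,
                      design=design, motion=motion, tr=tr)


def simulate_event_bold(design: EventDesign, truth: EventBoldTruth,
                        center: bool = True) -> EventBoldData:
    """Simulate a slow event-related dataset for all ROIs in the truth.

    The signal is generated through the same tent basis used for
    deconvolution (each ROI's injected lag profile is its gamma HRF sampled
    at lags 0..12 s), so noise-free recovery is exact."""
    dm = build_tent_design_matrix(design, center=center)
    lags = TENT_SPACING * np.arange(N_TENTS)
    rng = np.random.default_rng(truth.seed + 2)
    roi_labels = np.concatenate([[name] * roi.n_voxels
                                 for name, roi in truth.rois.items()])
    n_vox = len(roi_labels)
    n_vol = dm.matrix.shape[0]
    data = np.zeros((n_vox, n_vol))
    amp_cols = list(design.amplitudes.columns)
    v0 = 0
    for name, roi in truth.rois.items():
        profile = gamma_hrf(lags, roi.hrf_shape, roi.hrf_scale)
        # map regressor name -> per-voxel coupling, by convention of names
        named = {"parallelism": roi.beta_parallelism,
                 "luminance": roi.beta_luminance,
                 "contrast": roi.beta_contrast}
        sl = slice(v0, v0 + roi.n_voxels)
        for col in amp_cols:
            coup = named.get(col)
            if coup is None:
                continue
            X = dm.columns(col)  # (n_vol, 7)
            data[sl] += np.outer(coup, X @ profile)
        data[sl] += np.outer(roi.unmod_amplitude, dm.columns("event") @ profile)
        v0 += roi.n_voxels
    # drift through the matrix's own drift columns
    drift_cols = dm.columns("drift")
    coef = truth.drift_amplitude * rng.standard_normal((n_vox, drift_cols.shape[1]))
    data += coef @ drift_cols.T
    if truth.noise_sigma > 0:
        data += _ar1_noise(rng, (n_vox, n_vol), truth.noise_sigma, truth.ar_phi)
    return EventBoldData(data=data, roi_labels=roi_labels, design=design,
                         design_matrix=dm, truth=truth)
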