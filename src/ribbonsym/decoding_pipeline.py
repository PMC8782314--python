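"""Category decoding from block-design BOLD data.

Pipeline: percent signal change per run -> motion-nuisance residuals ->
block-averaged voxel patterns at a 4 s hemodynamic delay -> ANOVA-F voxel
ranking with the selection proportion tuned by nested leave-one-run-out
cross-validation -> linear SVM decoding, one classifier per image
condition -> group-level paired t-tests with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from ribbonsym.experiment_design import BlockDesign

__all__ = [
    "RoiDataset",
    "BlockPatterns",
    "DecodingResult",
    "preprocess_run",
    "preprocess",
    "block_average",
    "anova_f",
    "select_voxels_nested",
    "decode_loro",
    "group_stats",
    "DEFAULT_PROPORTION_GRID",
]

DEFAULT_PROPORTION_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
HEMODYNAMIC_DELAY = 4.0  # s


@dataclass
class RoiDataset:
    """Voxels x volumes BOLD matrix with run/block annotations.

    data       : (V, T) float
    roi_labels : (V,) str, ROI assignment per voxel
    run_ids    : (T,) int, run index per volume
    design     : the generating BlockDesign (block timing per run)
    motion     : (T, 6) nuisance series
    tr         : s
    """

    data: np.ndarray
    roi_labels: np.ndarray
    run_ids: np.ndarray
    design: BlockDesign
    motion: np.ndarray
    tr: float = 2.0

    def __post_init__(self):
        if self.data.shape[1] != len(self.run_ids):
            raise ValueError("run_ids length must match number of volumes")
        if self.motion.shape[0] != self.data.shape[1]:
            raise ValueError("motion rows must match number of volumes")

    def roi_voxels(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.roi_labels == roi)


@dataclass
class BlockPatterns:
    """One voxel pattern per block, with (run, category, condition) labels."""

    patterns: np.ndarray  # (n_blocks, V)
    labels: pd.DataFrame  # columns: run, category, condition

    def subset(self, condition: str) -> "BlockPatterns":
        keep = self.labels["condition"] == condition
        return BlockPatterns(self.patterns[keep.to_numpy()],
                             self.labels[keep].reset_index(drop=True))


@dataclass
class DecodingResult:
    accuracy: float
    predictions: pd.DataFrame  # run, true, predicted
    chosen_proportions: list[float] = field(default_factory=list)
    condition: str | None = None
    roi: str | None = None


def preprocess_run(run_data: np.ndarray, motion: np.ndarray) -> np.ndarray:
    """Percent signal change, then OLS residuals against motion nuisance.

    run_data : (V, T_run); motion : (T_run, 6). Returns (V, T_run)
    residuals orthogonal to [intercept, motion columns].
    """
    if run_data.shape[1] <= 20:
        raise ValueError("run too short to preprocess (need > 20 volumes)")
    mean = run_data.mean(axis=1, keepdims=True)
    if np.any(mean == 0):
        dead = np.flatnonzero(mean[:, 0] == 0)
        raise ValueError(f"dead voxels with zero mean: {dead[:10].tolist()}")
    psc = 100.0 * (run_data - mean) / mean
    X = np.column_stack([np.ones(motion.shape[0]), motion])
    beta, *_ = np.linalg.lstsq(X, psc.T, rcond=None)
    return psc - (X @ beta).T


def preprocess(dataset: RoiDataset) -> np.ndarray:
    """Apply :func:`preprocess_run` run by run; returns (V, T) residuals."""
    out = np.empty_like(dataset.data, dtype=float)
    for run in np.unique(dataset.run_ids):
        cols = dataset.run_ids == run
        out[:, cols] = preprocess_run(dataset.data[:, cols], dataset.motion[cols])
    return out


def block_average(residuals: np.ndarray, dataset: RoiDataset,
                  delay: float = HEMODYNAMIC_DELAY) -> BlockPatterns:
    """Average residuals over each block's volumes, shifted by `delay` s."""
    tr = dataset.tr
    if delay % tr:
        raise ValueError(f"delay {delay} s must be divisible by TR {tr} s")
    shift = int(delay / tr)
    rows, labels = [], []
    for ri, run in enumerate(dataset.design.runs):
        cols = np.flatnonzero(dataset.run_ids == ri)
        n_run = len(cols)
        for b in run:
            v0 = int(np.floor(b.onset / tr)) + shift
            v1 = int(np.ceil(b.offset / tr)) + shift
            if v1 > n_run:
                warnings.warn(f"block window truncated at run end (run {ri})",
                              stacklevel=2)
                v1 = n_run
            rows.append(residuals[:, cols[v0:v1]].mean(axis=1))
            labels.append(dict(run=ri, category=b.category, condition=b.condition))
    return BlockPatterns(np.asarray(rows), pd.DataFrame(labels))


def anova_f(patterns: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F across label groups, per voxel (vectorized).

    patterns : (n, V); labels : (n,). Returns (V,) F statistics.
    """
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 label groups for ANOVA")
    grand = patterns.mean(axis=0)
    ss_between = np.zeros(patterns.shape[1])
    ss_within = np.zeros(patterns.shape[1])
    for g in groups:
        sub = patterns[labels == g]
        m = sub.mean(axis=0)
        ss_between += len(sub) * (m - grand) ** 2
        ss_within += ((sub - m) ** 2).sum(axis=0)
    df_b = len(groups) - 1
    df_w = patterns.shape[0] - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return np.where(np.isfinite(f), f, 0.0)


def _top_voxels(f: np.ndarray, proportion: float) -> np.ndarray:
    k = max(1, int(round(proportion * len(f))))
    return np.argsort(-f, kind="stable")[:k]


def select_voxels_nested(patterns: np.ndarray, categories: np.ndarray,
                         runs: np.ndarray,
                         grid: tuple[float, ...] = DEFAULT_PROPORTION_GRID,
                         C: float = 1.0) -> tuple[float, np.ndarray]:
    """Tune the F-ranked voxel proportion by inner leave-one-run-out CV.

    Only the training data of the outer fold is passed in. Returns the
    proportion with the best inner accuracy (ties favor the larger
    proportion) and the voxel index mask ranked on the full training set.
    """
    uruns = np.unique(runs)
    if len(uruns) < 2:
        raise ValueError("nested selection needs >= 2 training runs")
    if len(np.unique(categories)) < 2:
        raise ValueError("training set must contain >= 2 categories")
    grid = tuple(sorted(grid))
    hits = np.zeros(len(grid))
    total = 0
    for held in uruns:
        tr_idx = runs != held
        te_idx = ~tr_idx
        f = anova_f(patterns[tr_idx], categories[tr_idx])
        rank = np.argsort(-f, kind="stable")
        for gi, prop in enumerate(grid):
            k = max(1, int(round(prop * patterns.shape[1])))
            vox = rank[:k]
            clf = SVC(kernel="linear", C=C)
            clf.fit(patterns[np.ix_(tr_idx, vox)], categories[tr_idx])
            pred = clf.predict(patterns[np.ix_(te_idx, vox)])
            hits[gi] += (pred == categories[te_idx]).sum()
        total += te_idx.sum()
    acc = hits / total
    best = np.flatnonzero(acc == acc.max()).max()  # tie -> larger proportion
    proportion = grid[best]
    f_full = anova_f(patterns, categories)
    return proportion, _top_voxels(f_full, proportion)


def decode_loro(patterns: BlockPatterns, condition: str,
                grid: tuple[float, ...] = DEFAULT_PROPORTION_GRID,
                C: float = 1.0, roi: str | None = None,
                voxels: np.ndarray | None = None) -> DecodingResult:
    """Leave-one-run-out linear SVM decoding of category for one condition.

    Voxel selection is re-run inside every outer fold on training runs
    only; no left-out-run data reaches selection or training.
    """
    sub = patterns.subset(condition)
    X = sub.patterns if voxels is None else sub.patterns[:, voxels]
    cats = sub.labels["category"].to_numpy()
    runs = sub.labels["run"].to_numpy()
    uruns = np.unique(runs)
    if len(uruns) < 3:
        raise ValueError("leave-one-run-out decoding needs >= 3 runs")
    preds = np.empty(len(cats), dtype=object)
    chosen = []
    for held in uruns:
        tr_idx = runs != held
        if len(np.unique(cats[tr_idx])) > tr_idx.sum():
            raise ValueError("fewer training patterns than classes")
        prop, vox = select_voxels_nested(X[tr_idx], cats[tr_idx], runs[tr_idx],
                                         grid=grid, C=C)
        chosen.append(prop)
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[np.ix_(tr_idx, vox)], cats[tr_idx])
        preds[~tr_idx] = clf.predict(X[np.ix_(~tr_idx, vox)])
    acc = float(np.mean(preds == cats))
    return DecodingResult(
        accuracy=acc,
        predictions=pd.DataFrame({"run": runs, "true": cats, "predicted": preds}),
        chosen_proportions=chosen, condition=condition, roi=roi)


def group_stats(values: pd.DataFrame, condition_a: str = "most",
                condition_b: str = "least") -> pd.DataFrame:
    """Per-ROI paired t-test (condition_a vs condition_b) across subjects,
    with Benjamini-Hochberg FDR adjustment across ROIs.

    `values` columns: subject, roi, condition, value (one row per cell).
    Returns a table with mean difference, t, p, and q per ROI.
    """
    if values["subject"].nunique() < 2:
        raise ValueError("group stats need >= 2 subjects")
    rows = []
    for roi, sub in values.groupby("roi", sort=True):
        wide = sub.pivot_table(index="subject", columns="condition",
                               values="value")
        a, b = wide[condition_a].to_numpy(), wide[condition_b].to_numpy()
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff, 0.0):
                t, p, note = 0.0, 1.0, "zero-variance, zero-mean differences"
            else:
                t, p, note = np.inf * np.sign(diff.mean()), 0.0, \
                    "zero-variance, nonzero-mean differences"
        else:
            t, p = stats.ttest_rel(a, b)
            note = ""
        rows.append(dict(roi=roi, mean_a=a.mean(), mean_b=b.mean(),
                         mean_diff=diff.mean(), t=float(t), p=float(p),
                         note=note))
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table
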