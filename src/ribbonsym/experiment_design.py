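"""Block and slow event-related fMRI designs, and tent-basis design matrices.

Block design (category decoding experiment): 9 runs of 18 blocks, one per
category x condition; each block shows 8 images (800 ms image + 200 ms
gap), with a 10 s fixation before the first block and after every block.
At TR = 2 s each run lasts 334 s = 167 volumes, so a full participant has
1503 volumes.

Event design (model-based experiment): one image per trial, 1 s image +
9 s fixation, so onsets fall every 10 s. Responses are deconvolved with a
7-tent piecewise-linear basis spanning 0-12 s post-onset (apexes on the
2 s acquisition grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "CONDITIONS",
    "Block",
    "BlockDesign",
    "EventDesign",
    "DesignMatrix",
    "build_block_design",
    "build_event_design",
    "build_tent_design_matrix",
    "tent_basis",
]

CATEGORIES = ("beach", "city", "forest", "highway", "mountain", "office")
CONDITIONS = ("intact", "most", "least")

TR = 2.0
N_TENTS = 7
TENT_SPACING = 2.0  # s; apexes at 0, 2, ..., 12 s post-onset

IMAGE_DUR = 0.8
GAP_DUR = 0.2
TRIALS_PER_BLOCK = 8
FIXATION_DUR = 10.0


@dataclass(frozen=True)
class Block:
    category: str
    condition: str
    onset: float  # s, run-relative
    trial_onsets: tuple[float, ...]

    @property
    def offset(self) -> float:
        return self.onset + TRIALS_PER_BLOCK * (IMAGE_DUR + GAP_DUR)


@dataclass
class BlockDesign:
    runs: list[list[Block]]
    tr: float = TR

    @property
    def run_duration(self) -> float:
        last = self.runs[0][-1]
        return last.offset + FIXATION_DUR

    @property
    def volumes_per_run(self) -> int:
        dur = self.run_duration
        if dur % self.tr:
            raise ValueError(f"run duration {dur} s not divisible by TR {self.tr}")
        return int(dur / self.tr)

    @property
    def total_volumes(self) -> int:
        return self.volumes_per_run * len(self.runs)

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, run, category, condition)."""
        rows = []
        for ri, run in enumerate(self.runs):
            for b in run:
                rows.append(dict(run=ri, onset=b.onset,
                                 duration=b.offset - b.onset,
                                 category=b.category, condition=b.condition))
        return pd.DataFrame(rows)


@dataclass
class EventDesign:
    image_ids: np.ndarray
    onsets: np.ndarray  # s, strictly increasing on a 10 s grid
    amplitudes: pd.DataFrame  # one column per parametric regressor
    tr: float = TR
    lead_out: float = 16.0  # s of rest after the last trial

    def __post_init__(self):
        if not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_volumes(self) -> int:
        return int(np.ceil((self.onsets[-1] + self.lead_out) / self.tr))

    def to_events_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"onset": self.onsets, "duration": 1.0,
                           "image_id": self.image_ids})
        return pd.concat([df, self.amplitudes.reset_index(drop=True)], axis=1)


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # volumes x regressors
    names: list[str]
    groups: dict[str, list[int]] = field(default_factory=dict)  # name -> column idx
    tr: float = TR
    n_tents: int = N_TENTS
    tent_spacing: float = TENT_SPACING

    def columns(self, group: str) -> np.ndarray:
        return self.matrix[:, self.groups[group]]


def build_block_design(n_runs: int = 9, seed: int = 0) -> BlockDesign:
    """Seeded block design: per run, the 18 category x condition blocks in
    random order on the stated timing grid."""
    rng = np.random.default_rng(seed)
    pairs = [(cat, cond) for cat in CATEGORIES for cond in CONDITIONS]
    runs = []
    for _ in range(n_runs):
        order = rng.permutation(len(pairs))
        t = FIXATION_DUR
        blocks = []
        for k in order:
            cat, cond = pairs[k]
            trial_onsets = tuple(t + j * (IMAGE_DUR + GAP_DUR)
                                 for j in range(TRIALS_PER_BLOCK))
            blocks.append(Block(cat, cond, t, trial_onsets))
            t = blocks[-1].offset + FIXATION_DUR
        runs.append(blocks)
    return BlockDesign(runs=runs)


def build_event_design(amplitudes: pd.DataFrame, seed: int = 0,
                       lead_in: float = 10.0, spacing: float = 10.0) -> EventDesign:
    """Seeded slow event design: one trial per image, onsets every `spacing` s.

    `amplitudes` has one row per image and one column per parametric
    regressor (e.g. parallelism, luminance, contrast)."""
    if len(amplitudes) < 1:
        raise ValueError("need at least one image")
    if amplitudes.isna().any().any():
        bad = amplitudes.columns[amplitudes.isna().any()].tolist()
        raise ValueError(f"missing parametric values in columns {bad}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(amplitudes))
    onsets = lead_in + spacing * np.arange(len(amplitudes), dtype=float)
    return EventDesign(image_ids=np.asarray(amplitudes.index)[order],
                       onsets=onsets,
                       amplitudes=amplitudes.iloc[order])


def tent_basis(t: np.ndarray, k: int, spacing: float = TENT_SPACING) -> np.ndarray:
    """Tent k: piecewise-linear bump with apex at k*spacing, half-width spacing."""
    return np.clip(1.0 - np.abs(t - k * spacing) / spacing, 0.0, None)


def build_tent_design_matrix(design: EventDesign,
                             center: bool = True,
                             drift_order: int = 2) -> DesignMatrix:
    """Volumes x regressors tent design matrix for a slow event design.

    For each parametric regressor r and tent k, the column value at volume
    time t is sum over events of a_r(event) * tent_k(t - onset). Amplitudes
    are mean-centered per regressor when `center` is set; an unmodulated
    event regressor (amplitude 1) and Legendre drift columns up to
    `drift_order` are appended.
    """
    amp = design.amplitudes
    if not np.all(np.isfinite(amp.to_numpy(dtype=float))):
        raise ValueError("non-finite parametric amplitude")
    n_vol = design.n_volumes
    t = np.arange(n_vol) * design.tr
    # event-by-tent loadings at each volume: (n_vol, n_events, n_tents)
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    cols: list[np.ndarray] = []

    lag_load = np.stack(
        [tent_basis(t[:, None] - design.onsets[None, :], k) for k in range(N_TENTS)],
        axis=2,
    )  # (n_vol, n_events, N_TENTS)

    def add_group(name: str, a: np.ndarray):
        groups[name] = list(range(len(cols), len(cols) + N_TENTS))
        for k in range(N_TENTS):
            cols.append(lag_load[:, :, k] @ a)
            names.append(f"{name}_lag{k}")

    for col in amp.columns:
        a = amp[col].to_numpy(dtype=float)
        if center:
            a = a - a.mean()
        add_group(col, a)
    add_group("event", np.ones(len(design.onsets)))

    # per-run (single run here) Legendre drift
    x = np.linspace(-1, 1, n_vol)
    groups["drift"] = list(range(len(cols), len(cols) + drift_order + 1))
    for d in range(drift_order + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(d)(x))
        names.append(f"drift_{d}")

    return DesignMatrix(matrix=np.column_stack(cols), names=names,
                        groups=groups, tr=design.tr)
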