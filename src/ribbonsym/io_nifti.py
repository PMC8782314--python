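"""Disk round-trip of simulated BOLD datasets.

Voxels are abstract rows; for NIfTI export each ROI occupies a disjoint
slab along the first axis of a (V, 1, 1, T) volume, with an integer-coded
ROI-mask image alongside. Block annotations go to a BIDS-style events CSV
and motion parameters to a 6-column text file.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ribbonsym.decoding_pipeline import RoiDataset
from ribbonsym.experiment_design import (
    Block,
    BlockDesign,
    IMAGE_DUR,
    GAP_DUR,
    TRIALS_PER_BLOCK,
)

__all__ = ["save_roi_dataset", "load_roi_dataset"]


def save_roi_dataset(dataset: RoiDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    bold = dataset.data[:, None, None, :].astype(np.float32)
    nib.save(nib.Nifti1Image(bold, affine), out / "bold.nii")
    rois = sorted(set(dataset.roi_labels))
    codes = {r: i + 1 for i, r in enumerate(rois)}
    mask = np.array([codes[r] for r in dataset.roi_labels],
                    dtype=np.int16)[:, None, None]
    nib.save(nib.Nifti1Image(mask, affine), out / "roi_mask.nii")
    with open(out / "roi_codes.json", "w") as fh:
        json.dump(codes, fh, indent=2)
    ev = dataset.design.to_events_frame()
    ev.to_csv(out / "events.csv", index=False)
    np.savetxt(out / "motion.txt", dataset.motion, fmt="%.6f")
    meta = dict(tr=dataset.tr, n_runs=len(dataset.design.runs),
                volumes_per_run=dataset.design.volumes_per_run)
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def _design_from_events(ev: pd.DataFrame, tr: float) -> BlockDesign:
    runs = []
    for _, sub in ev.groupby("run", sort=True):
        blocks = []
        for _, row in sub.iterrows():
            onsets = tuple(row["onset"] + j * (IMAGE_DUR + GAP_DUR)
                           for j in range(TRIALS_PER_BLOCK))
            blocks.append(Block(row["category"], row["condition"],
                                row["onset"], onsets))
        runs.append(blocks)
    return BlockDesign(runs=runs, tr=tr)


def load_roi_dataset(in_dir) -> RoiDataset:
    src = Path(in_dir)
    with open(src / "meta.json") as fh:
        meta = json.load(fh)
    bold = np.asanyarray(nib.load(src / "bold.nii").dataobj)
    data = bold[:, 0, 0, :].astype(float)
    mask = np.asanyarray(nib.load(src / "roi_mask.nii").dataobj)[:, 0, 0]
    with open(src / "roi_codes.json") as fh:
        codes = json.load(fh)
    names = {v: k for k, v in codes.items()}
    roi_labels = np.array([names[int(c)] for c in mask])
    ev = pd.read_csv(src / "events.csv")
    design = _design_from_events(ev, meta["tr"])
    n_per_run = meta["volumes_per_run"]
    run_ids = np.repeat(np.arange(meta["n_runs"]), n_per_run)
    motion = np.loadtxt(src / "motion.txt")
    return RoiDataset(data=data, roi_labels=roi_labels, run_ids=run_ids,
                      design=design, motion=motion, tr=meta["tr"])
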