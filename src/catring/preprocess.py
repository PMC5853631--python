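"""Signal conditioning and trial epoching.

Only two conditioning steps act on the simulated series (the remaining steps
of a volumetric fMRI stream — motion correction, smoothing, high-pass
filtering, registration — act on volumes that are not simulated here):

* run-wise linear detrending — per run and per voxel, remove the
  least-squares line (intercept + slope);
* global scaling — divide each timepoint by its spatial mean, then subtract
  the voxelwise mean, removing the global signal component.

``epoch_trials`` cuts the continuous series back into trial segments on the
TR grid, optionally dropping initial timepoints of each trial (the transient
samples the connectivity analysis discards).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ROIDataset

__all__ = ["RunSeries", "detrend_runwise", "global_scale", "epoch_trials"]


@dataclass
class RunSeries:
    """Timepoints x voxels values with a run label per timepoint; runs must
    be contiguous blocks."""

    values: np.ndarray
    run_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (timepoints x voxels)")
        self.run_labels = np.asarray(self.run_labels)
        if len(self.run_labels) != self.values.shape[0]:
            raise ValueError("one run label per timepoint required")
        change = np.flatnonzero(self.run_labels[1:] != self.run_labels[:-1])
        if len(np.unique(self.run_labels)) != len(change) + 1:
            raise ValueError("runs must be contiguous")

    def runs(self):
        for r in pd.unique(self.run_labels):
            yield r, np.flatnonzero(self.run_labels == r)


def detrend_runwise(s: RunSeries) -> RunSeries:
    """Remove the per-run, per-voxel least-squares line (intercept + slope).

    After detrending each run's mean is 0 and its regression slope on time
    is 0 for every voxel."""
    out = np.empty_like(s.values)
    for _, idx in s.runs():
        if idx.size < 3:
            raise ValueError("each run needs at least 3 timepoints to detrend")
        t = np.arange(idx.size, dtype=float)
        design = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(design, s.values[idx], rcond=None)
        out[idx] = s.values[idx] - design @ beta
    return RunSeries(out, s.run_labels.copy())


def global_scale(s: RunSeries, mode: str = "ratio") -> RunSeries:
    """Remove the global signal.

    ``mode="ratio"`` (classical global scaling): divide each timepoint's
    values by that timepoint's spatial mean, then subtract the voxelwise
    mean; the output spatial mean is constant (zero) across timepoints.
    ``mode="regress"``: regress the spatial-mean time course out of every
    voxel instead.
    """
    v = s.values
    if mode == "ratio":
        g = v.mean(axis=1, keepdims=True)
        if np.any(np.abs(g) < 1e-12):
            raise ValueError("zero spatial mean at some timepoint; cannot scale")
        scaled = v / g
        out = scaled - scaled.mean(axis=0, keepdims=True)
    elif mode == "regress":
        g = v.mean(axis=1, keepdims=True)
        gc = g - g.mean()
        denom = float((gc.T @ gc).item())
        if denom < 1e-24:
            raise ValueError("global signal has zero variance; cannot regress")
        beta = (gc.T @ (v - v.mean(axis=0, keepdims=True))) / denom
        out = v - v.mean(axis=0, keepdims=True) - gc @ beta
    else:
        raise ValueError("mode must be 'ratio' or 'regress'")
    return RunSeries(out, s.run_labels.copy())


def epoch_trials(
    s: RunSeries,
    trials: pd.DataFrame,
    tr: float,
    trial_len: float,
    drop_initial: int = 0,
    roi_name: str = "",
    time_offset: float = 0.0,
    task_only: bool = True,
) -> ROIDataset:
    """Cut a continuous series into per-trial segments on the TR grid.

    ``trials`` must carry run, onset (seconds within run), trial_type,
    position, correct columns (the generator's trial table).  Each trial
    yields ``trial_len/tr - drop_initial`` timepoints; a 14-s trial at a 2-s
    TR gives 7, or 5 after dropping the 2 transient samples.
    """
    n_keep = int(round(trial_len / tr)) - drop_initial
    if n_keep <= 0:
        raise ValueError("drop_initial leaves no timepoints per trial")
    run_start = {}
    pos = 0
    for r, idx in s.runs():
        run_start[r] = idx[0]
    rows = trials[trials.trial_type == "task"] if task_only else trials
    segs, runs_out, pos_out, corr_out = [], [], [], []
    for _, row in rows.iterrows():
        on = row.onset / tr
        if abs(on - round(on)) > 1e-9:
            raise ValueError(f"trial onset {row.onset} s is off the TR grid")
        start = run_start[row.run] + int(round(on)) + drop_initial
        seg = s.values[start : start + n_keep]
        if seg.shape[0] != n_keep:
            raise ValueError("trial extends past the end of the series")
        segs.append(seg)
        runs_out.append(row.run)
        pos_out.append(row.position)
        corr_out.append(bool(row.correct))
    time_labels = (np.arange(drop_initial, drop_initial + n_keep) * tr) + time_offset
    return ROIDataset(
        roi_name=roi_name,
        data=np.stack(segs),
        run_labels=np.asarray(runs_out),
        position_labels=np.asarray(pos_out),
        correct=np.asarray(corr_out),
        time_labels=time_labels,
    )
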