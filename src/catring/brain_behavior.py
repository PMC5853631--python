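"""Brain-behavior link: standardized GC vs reaction time across runs.

Runs are ranked by mean reaction time and binned into overlapping sliding
groups (15 runs, window 5 -> 11 groups).  Per group, the standardized GC is
averaged over member runs (and across subjects), the RT is averaged after
within-subject z-scoring, and the group-level relation is summarized by
Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

__all__ = ["RTGroups", "rt_groups", "gc_rt_correlation"]


@dataclass
class RTGroups:
    """Runs ranked by mean RT with sliding windows of neighbors."""

    order: np.ndarray  # run indices sorted ascending by RT
    groups: list[np.ndarray]  # each a window of `window` ranked runs
    window: int


def rt_groups(run_rts, window: int = 5) -> RTGroups:
    """Sort runs ascending by mean RT and slide a window of neighbors:
    ``n_runs - window + 1`` groups, adjacent groups sharing window-1 runs."""
    rts = np.asarray(run_rts, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if rts.size < window:
        raise ValueError("need at least `window` runs")
    order = np.argsort(rts, kind="stable")
    groups = [order[i : i + window] for i in range(rts.size - window + 1)]
    return RTGroups(order=order, groups=groups, window=window)


def gc_rt_correlation(
    std_gc, run_rts, window: int = 5
) -> tuple[stats.TestResult, pd.DataFrame]:
    """Rank correlation between group-mean standardized GC and group-mean
    z-scored RT.

    ``std_gc`` and ``run_rts`` are per-run values, either 1-D (one subject)
    or (n_subjects, n_runs).  Ranking and z-scoring happen within subject;
    group values are then averaged across subjects (group g always collects
    each subject's g-th ranked window).  Returns the Spearman test over the
    group points plus the group-level table.
    """
    gc = np.atleast_2d(np.asarray(std_gc, dtype=float))
    rt = np.atleast_2d(np.asarray(run_rts, dtype=float))
    if gc.shape != rt.shape:
        raise ValueError("std_gc and run_rts must have matching shapes")
    n_sub, n_runs = gc.shape
    n_groups = n_runs - window + 1
    if n_groups < 3:
        raise ValueError("need at least 3 groups for a rank correlation")
    g_gc = np.empty((n_sub, n_groups))
    g_rt = np.empty((n_sub, n_groups))
    for s in range(n_sub):
        z = (rt[s] - rt[s].mean()) / rt[s].std(ddof=1)
        grp = rt_groups(rt[s], window)
        for g, members in enumerate(grp.groups):
            g_gc[s, g] = gc[s, members].mean()
            g_rt[s, g] = z[members].mean()
    mean_gc = g_gc.mean(axis=0)
    mean_rt = g_rt.mean(axis=0)
    res = stats.spearman_corr(mean_rt, mean_gc)
    table = pd.DataFrame(
        dict(group=np.arange(n_groups), mean_rt_z=mean_rt, mean_std_gc=mean_gc)
    )
    return res, table
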