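"""Bivariate Granger causality on condition-labeled ROI series.

Directed influence between two ROI-mean series is quantified in Geweke's
log-variance-ratio form: ``GC(x -> y) = ln(var_restricted / var_full)``,
where the restricted model predicts y from its own lags only and the full
model adds lags of x.  Fits are ordinary least squares on lagged designs
built within trial segments only — lagged regressors never bridge a segment
edge, so concatenated trials behave as independent realizations of the same
process.  Per condition (categorization vs fixation trials) the first two
timepoints (4 s) of every trial are discarded to remove onset transients,
GC is estimated per run, and the condition contrast is summarized by the
bounded statistic ``(GCc - GCf) / (GCc + GCf)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ROISeriesPair

__all__ = [
    "VARFit",
    "GCResult",
    "fit_var",
    "granger",
    "condition_gc",
    "condition_gc_table",
    "standardized_gc",
]


@dataclass
class VARFit:
    """Least-squares bivariate VAR fit with nested restricted models.

    ``sigma_full[i]`` is the residual variance of equation i (0: x, 1: y)
    under the full model; ``sigma_restricted[i]`` under the own-lags-only
    model of the same order on the same observations.
    """

    order: int
    coef_x: np.ndarray
    coef_y: np.ndarray
    sigma_full: tuple[float, float]
    sigma_restricted: tuple[float, float]
    nobs: int


def _lagged_design(
    x: np.ndarray, y: np.ndarray, order: int, segments
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack (x_t, y_t, lagged x, lagged y) rows, never crossing segment
    boundaries."""
    rows_x, rows_y, lx, ly = [], [], [], []
    for seg in segments:
        seg = np.asarray(seg)
        if seg.size <= order:
            continue
        for t in range(order, seg.size):
            idx = seg[t]
            lags = seg[t - order : t][::-1]
            rows_x.append(x[idx])
            rows_y.append(y[idx])
            lx.append(x[lags])
            ly.append(y[lags])
    if not rows_x:
        raise ValueError("no usable observations after lagging")
    return (
        np.asarray(rows_x),
        np.asarray(rows_y),
        np.asarray(lx),
        np.asarray(ly),
    )


def _ols_resid_var(target: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float]:
    q, r = np.linalg.qr(design)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(r)))):
        raise ValueError("rank-deficient lagged design")
    beta = np.linalg.solve(r, q.T @ target)
    resid = target - design @ beta
    return beta, float(resid @ resid / len(target))


def fit_var(
    x: np.ndarray,
    y: np.ndarray,
    order: int = 1,
    segments=None,
) -> VARFit:
    """Fit the full bivariate VAR and both own-lags-only restricted models.

    ``segments`` is an iterable of index arrays treated as independent
    realizations (default: one contiguous segment)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("series contain non-finite values")
    if order < 1:
        raise ValueError("order must be >= 1")
    if segments is None:
        segments = [np.arange(x.size)]
    tx, ty, lx, ly = _lagged_design(x, y, order, segments)
    n = len(tx)
    if n <= 10 * order:
        raise ValueError("series too short for the requested order")
    ones = np.ones((n, 1))
    full = np.hstack([ones, lx, ly])
    own_x = np.hstack([ones, lx])
    own_y = np.hstack([ones, ly])
    bx, sx_full = _ols_resid_var(tx, full)
    by, sy_full = _ols_resid_var(ty, full)
    _, sx_r = _ols_resid_var(tx, own_x)
    _, sy_r = _ols_resid_var(ty, own_y)
    return VARFit(
        order=order,
        coef_x=bx,
        coef_y=by,
        sigma_full=(sx_full, sy_full),
        sigma_restricted=(sx_r, sy_r),
        nobs=n,
    )


def granger(fit: VARFit) -> tuple[float, float]:
    """(GC x->y, GC y->x) in nats: log ratio of restricted to full residual
    variance of the driven series."""
    gc_xy = float(np.log(fit.sigma_restricted[1] / fit.sigma_full[1]))
    gc_yx = float(np.log(fit.sigma_restricted[0] / fit.sigma_full[0]))
    return gc_xy, gc_yx


@dataclass(frozen=True)
class GCResult:
    run: int
    condition: str
    gc_xy: float
    gc_yx: float


def condition_gc(
    pair: ROISeriesPair,
    condition: str,
    order: int = 1,
    drop_initial: int = 2,
) -> list[GCResult]:
    """Per-run Granger causality for one trial condition.

    Within each run, trials of the condition are collected, each trimmed of
    its first ``drop_initial`` timepoints, and fit as independent segments of
    one VAR.  A 16-trial condition with 5 retained timepoints per trial
    yields 80 usable timepoints per run."""
    if condition not in ("categorization", "fixation"):
        raise ValueError("condition must be 'categorization' or 'fixation'")
    results = []
    for run in np.unique(pair.run_labels):
        in_run = pair.run_labels == run
        mask = in_run & (pair.conditions == condition)
        if not mask.any():
            raise ValueError(f"run {run} has no {condition} trials")
        segments = []
        for tid in np.unique(pair.trial_ids[mask]):
            seg = np.flatnonzero(pair.trial_ids == tid)
            seg = seg[drop_initial:]
            if seg.size:
                segments.append(seg)
        fit = fit_var(pair.x, pair.y, order=order, segments=segments)
        gc_xy, gc_yx = granger(fit)
        results.append(GCResult(int(run), condition, gc_xy, gc_yx))
    return results


def condition_gc_table(
    pair: ROISeriesPair, order: int = 1, drop_initial: int = 2
) -> pd.DataFrame:
    """Long-format per-run GC for both conditions and directions, with the
    per-run standardized contrast for the top-down (x->y) and bottom-up
    directions."""
    rows = []
    by_run: dict[int, dict[str, GCResult]] = {}
    for condition in ("categorization", "fixation"):
        for res in condition_gc(pair, condition, order, drop_initial):
            by_run.setdefault(res.run, {})[condition] = res
            rows.append(
                dict(run=res.run, condition=condition,
                     direction=f"{pair.name_x}->{pair.name_y}", gc=res.gc_xy)
            )
            rows.append(
                dict(run=res.run, condition=condition,
                     direction=f"{pair.name_y}->{pair.name_x}", gc=res.gc_yx)
            )
    df = pd.DataFrame(rows)
    std_rows = []
    for run, conds in sorted(by_run.items()):
        c, f = conds["categorization"], conds["fixation"]
        std_rows.append(
            dict(
                run=run,
                direction=f"{pair.name_x}->{pair.name_y}",
                standardized=standardized_gc(c.gc_xy, f.gc_xy),
            )
        )
        std_rows.append(
            dict(
                run=run,
                direction=f"{pair.name_y}->{pair.name_x}",
                standardized=standardized_gc(c.gc_yx, f.gc_yx),
            )
        )
    return df.merge(pd.DataFrame(std_rows), on=["run", "direction"], how="left")


def standardized_gc(gcc: float, gcf: float, clamp: bool = True) -> float:
    """Bounded condition contrast ``(GCc - GCf) / (GCc + GCf)``.

    Small negative finite-sample GC estimates are clamped to 0 first (the
    statistic is defined for non-negative GC); a zero denominator is an
    error."""
    if clamp:
        gcc = max(gcc, 0.0)
        gcf = max(gcf, 0.0)
    denom = gcc + gcf
    if denom <= 0:
        raise ValueError("GCc + GCf must be positive")
    return (gcc - gcf) / denom
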