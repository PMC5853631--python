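"""Synthetic delayed match-to-category experiments.

Generates everything the analysis chain consumes, with the statistical
structure the analyses assume, so the full pipeline is testable without any
scanner data:

* a trial/event table per subject (15 runs x 16 task + 16 fixation trials of
  14 s sampled at a 2-s TR -> 448 s runs, 240 task trials, 30 per position);
* per-ROI voxel responses per task trial and timepoint: a von Mises
  position-tuned population code (narrow tuning emulating V1, broad tuning
  emulating posterior IPS), an injectable shared category component with a
  time-varying amplitude profile, and i.i.d. Gaussian noise;
* reaction times that slow for samples near the category boundary and track
  run-level fluctuations of directed inter-areal coupling;
* a pair of coupled ROI-mean time series per run, a regime-switching
  bivariate VAR(1) whose top-down (IPS -> V1) coefficient depends on whether
  the current trial is a categorization or a fixation trial.

All randomness flows from a single integer seed through a documented
splitting scheme (seed -> subject -> stream -> run), so any sub-array is
reproducible in isolation and subject tuning maps survive a retraining
re-generation with the orthogonal boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Boundary, StimulusRing, boundary_distance

__all__ = [
    "ROISpec",
    "GCCoupling",
    "SyntheticConfig",
    "ROIDataset",
    "ROISeriesPair",
    "SubjectData",
    "Experiment",
    "default_rois",
    "generate_experiment",
    "generate_trial_table",
    "generate_rt",
    "generate_coupled_series",
]

# stream ids for the seed-splitting scheme
_S_TUNING, _S_TRIALS, _S_NOISE, _S_SERIES, _S_RT, _S_COUPLING = range(6)


@dataclass(frozen=True)
class ROISpec:
    """Response model of one region of interest.

    ``tuning_width`` is the von Mises concentration of voxel position tuning
    (large = fine spatial code, small = coarse); ``category_amplitude`` is the
    per-timepoint amplitude lambda(t) of the shared category component, in
    units of the noise SD per voxel.
    """

    name: str
    tuning_width: float
    category_amplitude: tuple[float, ...]
    n_voxels: int = 120
    tuning_amplitude: float = 1.0
    noise_sd: float = 1.0


@dataclass(frozen=True)
class GCCoupling:
    """Directed coupling of the regime-switching VAR(1) ROI-series model.

    ``categorization``/``fixation`` are the top-down (x -> y) coefficients in
    the two trial regimes; ``reverse`` is the fixed bottom-up (y -> x)
    coefficient; ``ar`` the self-lag coefficients; ``run_sd`` the SD of the
    run-level deviation added to the categorization coupling (the same
    deviation feeds the RT model through ``gc_rt_link``).
    """

    categorization: float = 0.35
    fixation: float = 0.05
    reverse: float = 0.0
    ar: tuple[float, float] = (0.3, 0.3)
    run_sd: float = 0.08


def default_rois(n_timepoints: int = 7) -> tuple[ROISpec, ROISpec]:
    """Default two-ROI setup: V1-like (fine code, late category signal) and
    IPS-like (coarse code, early category signal).

    Category-amplitude peaks (0.20 / 0.25 noise-SD units) are the documented
    default effect size: large enough that the boundary scan recovers an
    injected boundary in >=90% of single-subject experiments at the ROI's
    preferred timepoint, small enough that single-trial patterns stay
    noise-dominated.
    """
    if n_timepoints != 7:
        raise ValueError("default ROI profiles are defined for 7 timepoints")
    v1_profile = 0.20 * np.array([0.0, 0.0, 0.1, 0.3, 0.7, 1.0, 0.7])
    ips_profile = 0.25 * np.array([0.0, 0.3, 0.8, 1.0, 0.7, 0.4, 0.2])
    return (
        ROISpec("V1", tuning_width=8.0, category_amplitude=tuple(v1_profile)),
        ROISpec("IPS12", tuning_width=1.5, category_amplitude=tuple(ips_profile)),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic experiment."""

    n_subjects: int = 12
    n_runs: int = 15
    task_trials_per_run: int = 16
    fixation_trials_per_run: int = 16
    tr: float = 2.0
    trial_len: float = 14.0
    ring: StimulusRing = field(default_factory=StimulusRing)
    boundary: Boundary = field(default_factory=lambda: Boundary(45.0))
    rois: tuple[ROISpec, ...] = field(default_factory=default_rois)
    rt_base: float = 0.9
    rt_near_penalty: float = 0.12
    rt_noise_sd: float = 0.15
    accuracy_rate: float = 0.95
    gc_coupling: GCCoupling = field(default_factory=GCCoupling)
    gc_rt_link: float = -0.5
    baseline: float = 100.0
    drift_sd: float = 0.02
    hrf: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        n_pos = self.ring.n_positions
        if (self.task_trials_per_run * self.n_runs) % n_pos:
            raise ValueError(
                "task_trials_per_run * n_runs must be divisible by n_positions"
            )
        if abs(self.trial_len / self.tr - round(self.trial_len / self.tr)) > 1e-9:
            raise ValueError("trial_len must be an integer multiple of tr")
        for roi in self.rois:
            if len(roi.category_amplitude) != self.n_timepoints:
                raise ValueError(
                    f"ROI {roi.name}: category_amplitude needs "
                    f"{self.n_timepoints} entries"
                )
        _check_var_stable(self.gc_coupling)

    @property
    def n_timepoints(self) -> int:
        return int(round(self.trial_len / self.tr))

    @property
    def trials_per_run(self) -> int:
        return self.task_trials_per_run + self.fixation_trials_per_run

    @property
    def run_duration(self) -> float:
        return self.trials_per_run * self.trial_len

    @property
    def time_labels(self) -> np.ndarray:
        """Seconds relative to sample onset for within-trial timepoints."""
        return np.arange(self.n_timepoints) * self.tr

    def near_positions(self) -> tuple[int, ...]:
        d = np.array(
            [boundary_distance(self.ring, self.boundary, k) for k in self.ring.positions]
        )
        return tuple(int(k) for k in np.flatnonzero(np.isclose(d, d.min())))


def _check_var_stable(c: GCCoupling) -> None:
    for cross in (c.categorization, c.fixation):
        a = np.array([[c.ar[0], c.reverse], [cross, c.ar[1]]])
        if np.max(np.abs(np.linalg.eigvals(a))) >= 1.0:
            raise ValueError("unstable VAR coupling coefficients")


@dataclass
class ROIDataset:
    """Task-trial responses of one ROI: trials x timepoints x voxels."""

    roi_name: str
    data: np.ndarray
    run_labels: np.ndarray
    position_labels: np.ndarray
    correct: np.ndarray
    time_labels: np.ndarray

    def __post_init__(self) -> None:
        n, t, _ = self.data.shape
        if not (
            len(self.run_labels) == len(self.position_labels) == len(self.correct) == n
        ):
            raise ValueError("label lengths must match the trial dimension")
        if len(self.time_labels) != t:
            raise ValueError("time_labels must match the timepoint dimension")
        if np.any(np.diff(self.time_labels) <= 0):
            raise ValueError("time_labels must be strictly increasing")

    def time_index(self, t: float) -> int:
        idx = np.flatnonzero(np.isclose(self.time_labels, t))
        if idx.size != 1:
            raise ValueError(f"timepoint {t} s not sampled")
        return int(idx[0])


@dataclass
class ROISeriesPair:
    """Two coupled ROI-mean series over a whole session, with per-timepoint
    run, trial and condition labels (x drives y top-down)."""

    name_x: str
    name_y: str
    x: np.ndarray
    y: np.ndarray
    run_labels: np.ndarray
    trial_ids: np.ndarray
    conditions: np.ndarray  # 'categorization' | 'fixation' per timepoint
    tr: float
    timepoints_per_trial: int

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (
            len(self.y) == len(self.run_labels) == len(self.trial_ids)
            == len(self.conditions) == n
        ):
            raise ValueError("series and labels must have equal length")


@dataclass
class SubjectData:
    subject: int
    trials: pd.DataFrame
    datasets: dict[str, ROIDataset]
    series: ROISeriesPair
    run_coupling_dev: np.ndarray  # per-run deviation of the top-down coupling


@dataclass
class Experiment:
    config: SyntheticConfig
    experiment_id: int
    boundary: Boundary
    subjects: list[SubjectData]


def _rng(cfg: SyntheticConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), *map(int, key)]))


def generate_rt(
    cfg: SyntheticConfig,
    is_near: bool,
    run_coupling_dev: float,
    rng: np.random.Generator,
) -> float:
    """Reaction time for one task trial (seconds, truncated to (0, 2]).

    rt = base + near-boundary penalty + link * run-coupling deviation + noise.
    A negative ``gc_rt_link`` makes runs with stronger top-down coupling
    faster, the brain-behavior relation the GC-RT analysis estimates.
    """
    rt = (
        cfg.rt_base
        + (cfg.rt_near_penalty if is_near else 0.0)
        + cfg.gc_rt_link * run_coupling_dev
        + rng.normal(0.0, cfg.rt_noise_sd)
    )
    return float(np.clip(rt, 1e-3, 2.0))


def generate_trial_table(
    cfg: SyntheticConfig,
    subject: int,
    run_coupling_dev: np.ndarray,
    experiment: int = 1,
    boundary: Boundary | None = None,
) -> pd.DataFrame:
    """Event table for one subject: run, onset, type, position, match, RT,
    correctness.  Task trials are position-balanced within every run when the
    per-run count divides the number of positions, and exactly balanced
    across the experiment otherwise."""
    b = boundary or cfg.boundary
    ring = cfg.ring
    n_pos = ring.n_positions
    near = set(cfg.near_positions()) if b == cfg.boundary else {
        k for k in ring.positions
        if np.isclose(
            boundary_distance(ring, b, k),
            min(boundary_distance(ring, b, j) for j in ring.positions),
        )
    }
    total_task = cfg.task_trials_per_run * cfg.n_runs
    positions = np.tile(np.arange(n_pos), total_task // n_pos)
    rng_trials = _rng(cfg, subject, _S_TRIALS, experiment)
    rng_rt = _rng(cfg, subject, _S_RT, experiment)

    rows = []
    for run in range(cfg.n_runs):
        run_pos = positions[
            run * cfg.task_trials_per_run : (run + 1) * cfg.task_trials_per_run
        ].copy()
        rng_trials.shuffle(run_pos)
        kinds = np.array(
            ["task"] * cfg.task_trials_per_run
            + ["fixation"] * cfg.fixation_trials_per_run
        )
        rng_trials.shuffle(kinds)
        task_iter = iter(run_pos)
        for slot, kind in enumerate(kinds):
            onset = slot * cfg.trial_len
            if kind == "fixation":
                rows.append(
                    dict(run=run, onset=onset, trial_type="fixation",
                         position=-1, match=False, rt=np.nan, correct=False)
                )
                continue
            k = int(next(task_iter))
            test_pos = int(rng_trials.integers(n_pos))
            match = b.category_of(ring, k) == b.category_of(ring, test_pos)
            correct = bool(rng_trials.random() < cfg.accuracy_rate)
            rt = generate_rt(cfg, k in near, float(run_coupling_dev[run]), rng_rt)
            rows.append(
                dict(run=run, onset=onset, trial_type="task",
                     position=k, match=match, rt=rt, correct=correct)
            )
    return pd.DataFrame(rows)


def _hrf_kernel(tr: float, length: float = 24.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, length, tr)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    return h / h.max()


def _subject_maps(
    cfg: SyntheticConfig, subject: int, roi: ROISpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject tuning curves (positions x voxels) and the two category
    prototype patterns (2 x voxels), orthogonal to the mean tuning map."""
    rng = _rng(cfg, subject, _S_TUNING, _roi_id(cfg, roi))
    phi = rng.uniform(0.0, 2 * np.pi, roi.n_voxels)
    theta = np.radians([cfg.ring.angle_of(k) for k in cfg.ring.positions])
    tuning = roi.tuning_amplitude * np.exp(
        roi.tuning_width * (np.cos(theta[:, None] - phi[None, :]) - 1.0)
    )
    protos = rng.standard_normal((2, roi.n_voxels))
    mean_map = tuning.mean(axis=0)
    basis = [mean_map / np.linalg.norm(mean_map)]
    out = []
    for g in protos:
        for u in basis:
            g = g - (g @ u) * u
        g = g / np.linalg.norm(g) * np.sqrt(roi.n_voxels)  # unit per-voxel RMS
        basis.append(g / np.linalg.norm(g))
        out.append(g)
    return tuning, np.stack(out)


def _roi_id(cfg: SyntheticConfig, roi: ROISpec) -> int:
    return [r.name for r in cfg.rois].index(roi.name)


def _roi_dataset(
    cfg: SyntheticConfig,
    subject: int,
    roi: ROISpec,
    trials: pd.DataFrame,
    boundary: Boundary,
    experiment: int,
) -> ROIDataset:
    tuning, protos = _subject_maps(cfg, subject, roi)
    lam = np.asarray(roi.category_amplitude) * roi.noise_sd
    task = trials[trials.trial_type == "task"].reset_index(drop=True)
    n_t = cfg.n_timepoints
    rng = _rng(cfg, subject, _S_NOISE, _roi_id(cfg, roi), experiment)
    pos = task.position.to_numpy()
    cats = np.array([boundary.category_of(cfg.ring, int(k)) for k in pos])
    signal = (
        tuning[pos][:, None, :]
        + lam[None, :, None] * protos[cats][:, None, :]
    )  # (trials, timepoints, voxels) via broadcasting
    if cfg.hrf:
        h = _hrf_kernel(cfg.tr)[:n_t]
        sig_t = np.ones(n_t)
        prof = np.convolve(sig_t, h)[:n_t]
        prof = prof / prof.max()
        signal = signal * prof[None, :, None]
    data = signal + rng.normal(0.0, roi.noise_sd, (len(task), n_t, roi.n_voxels))
    return ROIDataset(
        roi_name=roi.name,
        data=data,
        run_labels=task.run.to_numpy(),
        position_labels=pos,
        correct=task.correct.to_numpy(),
        time_labels=cfg.time_labels,
    )


def generate_coupled_series(
    cfg: SyntheticConfig,
    subject: int,
    run: int,
    trials: pd.DataFrame,
    run_coupling_dev: np.ndarray,
    experiment: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Regime-switching VAR(1) pair for one run.

    x (IPS-like) drives y (V1-like) with coefficient
    ``categorization + run deviation`` during categorization trials and
    ``fixation`` during fixation trials; innovations are unit-variance
    Gaussian.  Returns (x, y, trial_ids, conditions) at the TR grid.
    """
    c = cfg.gc_coupling
    n_t = cfg.n_timepoints
    run_trials = trials[trials.run == run].sort_values("onset")
    conds = np.repeat(
        np.where(run_trials.trial_type.to_numpy() == "task",
                 "categorization", "fixation"),
        n_t,
    )
    trial_ids = np.repeat(np.arange(len(run_trials)), n_t)
    total = len(conds)
    rng = _rng(cfg, subject, _S_SERIES, run, experiment)
    cross = np.where(
        conds == "categorization",
        c.categorization + run_coupling_dev[run],
        c.fixation,
    )
    burn = 50
    x = np.empty(total + burn)
    y = np.empty(total + burn)
    x[0], y[0] = rng.standard_normal(2)
    eps = rng.standard_normal((total + burn, 2))
    cross_full = np.concatenate([np.full(burn, c.fixation), cross])
    for t in range(1, total + burn):
        x[t] = c.ar[0] * x[t - 1] + c.reverse * y[t - 1] + eps[t, 0]
        y[t] = c.ar[1] * y[t - 1] + cross_full[t] * x[t - 1] + eps[t, 1]
    return x[burn:], y[burn:], trial_ids, conds


def _series_pair(
    cfg: SyntheticConfig,
    subject: int,
    trials: pd.DataFrame,
    run_coupling_dev: np.ndarray,
    experiment: int,
) -> ROISeriesPair:
    xs, ys, rids, tids, conds = [], [], [], [], []
    offset = 0
    for run in range(cfg.n_runs):
        x, y, trial_ids, cond = generate_coupled_series(
            cfg, subject, run, trials, run_coupling_dev, experiment
        )
        xs.append(x)
        ys.append(y)
        rids.append(np.full(len(x), run))
        tids.append(trial_ids + offset)
        conds.append(cond)
        offset += len(np.unique(trial_ids))
    name_x = cfg.rois[1].name if len(cfg.rois) > 1 else "x"
    name_y = cfg.rois[0].name
    return ROISeriesPair(
        name_x=name_x,
        name_y=name_y,
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        run_labels=np.concatenate(rids),
        trial_ids=np.concatenate(tids),
        conditions=np.concatenate(conds),
        tr=cfg.tr,
        timepoints_per_trial=cfg.n_timepoints,
    )


def generate_experiment(cfg: SyntheticConfig, experiment: int = 1) -> Experiment:
    """Generate a complete synthetic experiment.

    ``experiment=2`` models retraining: the category boundary is rotated to
    the perpendicular axis while each subject's voxel tuning maps and
    category prototypes are kept identical (tuning randomness is keyed by
    subject only, not by experiment)."""
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    boundary = cfg.boundary if experiment == 1 else cfg.boundary.perpendicular()
    subjects = []
    for s in range(cfg.n_subjects):
        dev = _rng(cfg, s, _S_COUPLING, experiment).normal(
            0.0, cfg.gc_coupling.run_sd, cfg.n_runs
        )
        trials = generate_trial_table(cfg, s, dev, experiment, boundary)
        datasets = {
            roi.name: _roi_dataset(cfg, s, roi, trials, boundary, experiment)
            for roi in cfg.rois
        }
        series = _series_pair(cfg, s, trials, dev, experiment)
        subjects.append(
            SubjectData(
                subject=s,
                trials=trials,
                datasets=datasets,
                series=series,
                run_coupling_dev=dev,
            )
        )
    return Experiment(
        config=cfg, experiment_id=experiment, boundary=boundary, subjects=subjects
    )


def roi_run_series(
    cfg: SyntheticConfig,
    subject: int,
    ds: ROIDataset,
    trials: pd.DataFrame,
    experiment: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble a raw voxel run series (timepoints x voxels, plus run labels)
    from epoched task-trial data: trial blocks placed at their onsets,
    fixation trials filled with noise, plus a positive baseline and a
    run-wise linear drift.  This is the surface the preprocessing steps
    (global scaling, run-wise detrending, epoching) operate on."""
    n_t = cfg.n_timepoints
    n_vox = ds.data.shape[2]
    per_run = cfg.trials_per_run * n_t
    rng = _rng(cfg, subject, _S_NOISE, 99, experiment)
    roi = next(r for r in cfg.rois if r.name == ds.roi_name)
    values = np.empty((cfg.n_runs * per_run, n_vox))
    run_labels = np.repeat(np.arange(cfg.n_runs), per_run)
    task_counter = 0
    for run in range(cfg.n_runs):
        base = run * per_run
        drift = rng.normal(0.0, cfg.drift_sd)
        tgrid = np.arange(per_run)
        block = rng.normal(0.0, roi.noise_sd, (per_run, n_vox))
        run_trials = trials[trials.run == run].sort_values("onset")
        for _, row in run_trials.iterrows():
            start = int(round(row.onset / cfg.tr))
            if row.trial_type == "task":
                block[start : start + n_t] = ds.data[task_counter]
                task_counter += 1
        values[base : base + per_run] = (
            cfg.baseline + drift * tgrid[:, None] + block
        )
    return values, run_labels
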