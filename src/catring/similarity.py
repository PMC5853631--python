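"""Pattern-similarity analyses and the category index.

Position patterns are the mean multivoxel responses per stimulus position at
one timepoint; all 28 position pairs are scored with Spearman's rank
correlation.  The category index at a given ring separation is
``WCS - BCS``: the mean similarity of within-category pairs minus the mean
similarity of pairs spanning the category boundary.  The boundary-optimality
scan recomputes the index for each of the four candidate boundaries and asks
whether the trained boundary wins; group-level optimality counts are tested
against chance 1/4 with an exact binomial tail.  Two further contrasts
control for alternative accounts: diametric (14 dva) pairs near vs far from
the boundary, and between-category pairs at different vs equal boundary
distances (the attention account); a position-group x experiment ANOVA
interaction separates category effects from retinotopy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .geometry import (
    Boundary,
    StimulusRing,
    boundary_distance,
    candidate_boundaries,
    pair_sets,
)
from .synthetic import ROIDataset

__all__ = [
    "SimilarityTable",
    "CategoryIndexResult",
    "position_patterns",
    "similarity_table",
    "category_index",
    "boundary_scan",
    "boundary_scan_group",
    "near_far_contrast",
    "attention_contrast",
    "retinotopy_interaction",
]


@dataclass
class SimilarityTable:
    """Rank correlations between the 8 position patterns at one timepoint."""

    rho: np.ndarray  # (n_positions, n_positions), symmetric, diag 1
    t: float | None = None
    subject: int | None = None

    def value(self, i: int, j: int) -> float:
        return float(self.rho[i, j])

    def mean_over(self, pairs) -> float:
        if len(pairs) == 0:
            raise ValueError("empty pair set")
        return float(np.mean([self.rho[i, j] for i, j in pairs]))

    def to_frame(self) -> pd.DataFrame:
        n = self.rho.shape[0]
        rows = [
            dict(i=i, j=j, rho=float(self.rho[i, j]), t=self.t, subject=self.subject)
            for i in range(n)
            for j in range(i + 1, n)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CategoryIndexResult:
    separation_steps: int
    separation_dva: float
    t: float | None
    boundary: Boundary
    wcs: float
    bcs: float

    @property
    def ci(self) -> float:
        return self.wcs - self.bcs


def position_patterns(
    ds: ROIDataset,
    t: float,
    voxel_set: np.ndarray | None = None,
    correct_only: bool = True,
    n_positions: int = 8,
) -> np.ndarray:
    """Mean multivoxel pattern per position at timepoint ``t`` (restricted
    to ``voxel_set`` when given), correct task trials only by default."""
    ti = ds.time_index(t)
    sel = ds.correct if correct_only else np.ones(len(ds.correct), bool)
    x = ds.data[sel, ti, :]
    if voxel_set is not None:
        voxel_set = np.asarray(voxel_set)
        if voxel_set.size == 0:
            raise ValueError("empty voxel set")
        x = x[:, voxel_set]
    pos = ds.position_labels[sel]
    out = np.empty((n_positions, x.shape[1]))
    for k in range(n_positions):
        mask = pos == k
        if not mask.any():
            raise ValueError(f"no usable trials at position {k}")
        out[k] = x[mask].mean(axis=0)
    return out


def similarity_table(
    patterns: np.ndarray, t: float | None = None, subject: int | None = None
) -> SimilarityTable:
    """Spearman rank correlation between every pair of position patterns."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[1] < 3:
        raise ValueError("rank correlation needs at least 3 voxels")
    rho, _ = sps.spearmanr(patterns.T)
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    return SimilarityTable(rho=rho, t=t, subject=subject)


def category_index(
    st: SimilarityTable,
    ring: StimulusRing,
    b: Boundary,
    steps: int,
    bcs_rule: str = "symmetric",
) -> CategoryIndexResult:
    """WCS, BCS and their difference at one ring separation.

    At the diametric separation there are no within pairs; the near/far
    diametric sets take the WCS/BCS roles there (near pairs straddle the
    boundary where category separation is weakest)."""
    ps = pair_sets(ring, b, steps, bcs_rule)
    from .geometry import chord_distance

    dva = chord_distance(ring, steps)
    if steps == ring.n_positions // 2:
        wcs = st.mean_over(ps.near_pairs)
        bcs = st.mean_over(ps.far_pairs)
    else:
        wcs = st.mean_over(ps.wcs_pairs)
        bcs = st.mean_over(ps.bcs_pairs)
    return CategoryIndexResult(steps, dva, st.t, b, wcs=wcs, bcs=bcs)


def boundary_scan(
    st: SimilarityTable,
    ring: StimulusRing,
    steps: int,
    bcs_rule: str = "symmetric",
) -> tuple[dict[float, float], Boundary]:
    """Category index under each of the four candidate boundaries and the
    boundary maximizing it (ties broken by axis angle, stable)."""
    cis: dict[float, float] = {}
    best: Boundary | None = None
    for b in candidate_boundaries(ring):
        ci = category_index(st, ring, b, steps, bcs_rule).ci
        cis[b.axis_angle] = ci
        if best is None or ci > cis[best.axis_angle]:
            best = b
    assert best is not None
    return cis, best


def boundary_scan_group(
    argmax_matches: np.ndarray, chance: float = 0.25
) -> stats.TestResult:
    """Binomial tail for the number of subjects whose optimal boundary is
    the trained one, against chance 1/4."""
    flags = np.asarray(argmax_matches, bool)
    return stats.TestResult(
        float(flags.sum()),
        stats.binomial_tail(int(flags.sum()), flags.size, chance),
        df=flags.size,
        sided="greater",
    )


def _paired_or_null(a: np.ndarray, b: np.ndarray) -> stats.TestResult:
    """Paired t test, degrading gracefully when every difference is zero."""
    if np.allclose(a, b):
        return stats.TestResult(0.0, 1.0, df=len(a) - 1)
    return stats.paired_t(a, b)


def near_far_contrast(
    tables: list[SimilarityTable], ring: StimulusRing, b: Boundary
) -> tuple[np.ndarray, np.ndarray, stats.TestResult]:
    """Similarity of diametric (14 dva) pairs near vs far from the boundary,
    paired t test across subjects."""
    ps = pair_sets(ring, b, ring.n_positions // 2)
    near = np.array([st.mean_over(ps.near_pairs) for st in tables])
    far = np.array([st.mean_over(ps.far_pairs) for st in tables])
    return near, far, _paired_or_null(near, far)


def attention_contrast(
    tables: list[SimilarityTable], ring: StimulusRing, b: Boundary
) -> tuple[np.ndarray, np.ndarray, stats.TestResult]:
    """Between-category pairs at different boundary distances (one member
    near, one far) vs equal distances (both far), paired across subjects.

    Under an attention-to-the-boundary account, positions sharing a distance
    to the boundary receive similar attentional modulation, so same-distance
    pairs should be more similar; a category account predicts no such
    ordering."""
    dmin = min(boundary_distance(ring, b, k) for k in ring.positions)
    near = {
        k
        for k in ring.positions
        if np.isclose(boundary_distance(ring, b, k), dmin)
    }
    between = [
        (i, j)
        for s in range(1, ring.n_positions // 2 + 1)
        for (i, j) in pair_sets(ring, b, s, bcs_rule="all").bcs_pairs
    ]
    # diametric pairs live in near/far annotations, add them
    dia = pair_sets(ring, b, ring.n_positions // 2)
    between = sorted(set(between) | set(dia.bcs_pairs))
    diff_dist = [p for p in between if (p[0] in near) != (p[1] in near)]
    same_far = [p for p in between if p[0] not in near and p[1] not in near]
    d = np.array([st.mean_over(diff_dist) for st in tables])
    s = np.array([st.mean_over(same_far) for st in tables])
    return d, s, _paired_or_null(d, s)


#: Adjacent-pair groups for the retinotopy control, 0-based position indices.
#: Group 1 pairs share a category under the 45 deg boundary only; group 2
#: pairs share a category under the 135 deg boundary only.
RETINOTOPY_GROUPS: dict[int, tuple[tuple[int, int], ...]] = {
    1: ((0, 1), (4, 5)),
    2: ((2, 3), (6, 7)),
}


def retinotopy_interaction(
    tables_exp1: list[SimilarityTable],
    tables_exp2: list[SimilarityTable],
    groups: dict[int, tuple[tuple[int, int], ...]] | None = None,
) -> stats.TestResult:
    """Position-group x experiment ANOVA interaction on subject-level mean
    similarity of adjacent pairs.

    A pure retinotopic code predicts identical similarity in both
    experiments (no interaction); a category code predicts a crossover,
    since each group's pairs are within-category in one experiment and
    between-category in the other."""
    groups = groups or RETINOTOPY_GROUPS
    values, ga, gb = [], [], []
    for exp_id, tables in ((1, tables_exp1), (2, tables_exp2)):
        for st in tables:
            for gid, pairs in groups.items():
                values.append(st.mean_over(pairs))
                ga.append(gid)
                gb.append(exp_id)
    return stats.two_way_interaction(values, ga, gb)
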