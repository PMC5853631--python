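"""Stimulus-ring geometry: positions, category boundaries and pair sets.

The experimental display is a ring of eight circular stimuli equally spaced
at 7 degrees of visual angle (dva) from fixation, partitioned into two learned
categories by an invisible diameter ("category boundary").  Boundary axes sit
at multiples of 45 deg, offset 22.5 deg from every stimulus, so no stimulus
ever lies on a boundary.  Everything downstream — within/between-category
pair sets, near/far annotations, chord and boundary distances — derives from
this module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "StimulusRing",
    "Boundary",
    "PairSet",
    "chord_distance",
    "boundary_distance",
    "candidate_boundaries",
    "pair_sets",
    "geometry_json",
]


@dataclass(frozen=True)
class StimulusRing:
    """Equally spaced stimulus positions on a circle centred at fixation.

    Position ``k`` (counter-clockwise from the rightward horizontal) sits at
    ``360/(2n) + k * 360/n`` degrees, i.e. ``22.5 + 45k`` for the default
    eight-position ring.  The half-step offset keeps every position off the
    candidate boundary axes.
    """

    n_positions: int = 8
    eccentricity: float = 7.0

    def __post_init__(self) -> None:
        if self.n_positions < 2 or self.n_positions % 2:
            raise ValueError("n_positions must be an even count >= 2")
        if self.eccentricity <= 0:
            raise ValueError("eccentricity must be positive (dva)")

    @property
    def step_deg(self) -> float:
        return 360.0 / self.n_positions

    def angle_of(self, k: int) -> float:
        """Polar angle of position ``k`` in degrees, CCW from rightward."""
        return (self.step_deg / 2.0 + k * self.step_deg) % 360.0

    def position_xy(self, k: int) -> tuple[float, float]:
        a = math.radians(self.angle_of(k))
        return (self.eccentricity * math.cos(a), self.eccentricity * math.sin(a))

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(self.n_positions))


@dataclass(frozen=True)
class Boundary:
    """A diameter through fixation splitting the ring into two categories.

    ``axis_angle`` is the orientation of the boundary line in degrees; valid
    axes for the 8-position ring are multiples of 45 (0, 45, 90, 135), each
    offset 22.5 deg from every stimulus angle.
    """

    axis_angle: float

    def side_of(self, ring: StimulusRing, k: int) -> int:
        """+1/-1 for the two half-planes; 0 would mean on the line (never
        happens for valid ring/axis combinations)."""
        s = math.sin(math.radians(ring.angle_of(k) - self.axis_angle))
        if abs(s) < 1e-12:
            return 0
        return 1 if s > 0 else -1

    def partition(self, ring: StimulusRing) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """The two category position sets (positive side first)."""
        pos, neg = [], []
        for k in ring.positions:
            side = self.side_of(ring, k)
            if side == 0:
                raise ValueError(
                    f"position {k} lies on the boundary at {self.axis_angle} deg"
                )
            (pos if side > 0 else neg).append(k)
        return tuple(pos), tuple(neg)

    def category_of(self, ring: StimulusRing, k: int) -> int:
        """0 for the positive-side category, 1 for the other."""
        return 0 if self.side_of(ring, k) > 0 else 1

    def reflect(self, ring: StimulusRing, k: int) -> int:
        """Index of the mirror image of position ``k`` across the axis."""
        # angle -> 2*axis - angle; solve 22.5 + 45 m = 2a - 22.5 - 45 k (mod 360)
        target = (2.0 * self.axis_angle - ring.angle_of(k)) % 360.0
        m = round((target - ring.step_deg / 2.0) / ring.step_deg) % ring.n_positions
        if not math.isclose(ring.angle_of(m), target, abs_tol=1e-9):
            raise ValueError("axis does not map positions onto positions")
        return m

    def perpendicular(self) -> "Boundary":
        return Boundary((self.axis_angle + 90.0) % 180.0)


@dataclass(frozen=True)
class PairSet:
    """Within- (WCS) and between-category (BCS) stimulus pairs at one
    separation, plus near/far annotations for diametric pairs."""

    separation_steps: int
    wcs_pairs: tuple[tuple[int, int], ...]
    bcs_pairs: tuple[tuple[int, int], ...]
    near_pairs: tuple[tuple[int, int], ...] = field(default=())
    far_pairs: tuple[tuple[int, int], ...] = field(default=())


def chord_distance(ring: StimulusRing, steps: int) -> float:
    """Straight-line (chord) distance in dva between positions ``steps``
    apart on the ring: ``2 r sin(steps * pi / n)``.

    For the 7-dva ring this gives 5.36, 9.90, 12.93 and 14.0 dva at 1-4
    steps (printed as 5.4, 9.9, 12.9, 14).
    """
    if not 1 <= steps <= ring.n_positions // 2:
        raise ValueError(f"steps must be in 1..{ring.n_positions // 2}")
    return 2.0 * ring.eccentricity * math.sin(steps * math.pi / ring.n_positions)


def boundary_distance(ring: StimulusRing, b: Boundary, k: int) -> float:
    """Perpendicular distance (dva) from position ``k`` to the boundary line."""
    if k not in ring.positions:
        raise ValueError(f"invalid position index {k}")
    return ring.eccentricity * abs(
        math.sin(math.radians(ring.angle_of(k) - b.axis_angle))
    )


def candidate_boundaries(ring: StimulusRing) -> list[Boundary]:
    """All diameters splitting the ring into two contiguous arcs of n/2
    positions — four for the 8-position ring (axes 0, 45, 90, 135 deg)."""
    step = ring.step_deg
    return [Boundary(step * i) for i in range(ring.n_positions // 2)]


def _all_pairs(ring: StimulusRing, steps: int) -> list[tuple[int, int]]:
    n = ring.n_positions
    pairs = {tuple(sorted(((k), (k + steps) % n))) for k in range(n)}
    return sorted(pairs)


def _is_within(ring: StimulusRing, b: Boundary, pair: tuple[int, int]) -> bool:
    return b.side_of(ring, pair[0]) == b.side_of(ring, pair[1])


def pair_sets(
    ring: StimulusRing,
    b: Boundary,
    steps: int,
    bcs_rule: str = "symmetric",
) -> PairSet:
    """WCS/BCS pair sets at a given ring separation for one boundary.

    Construction, for the 8-position ring:

    * ``steps=1`` — of the 8 adjacent pairs exactly 2 straddle the boundary
      (BCS); the matched WCS set is the 2 pairs straddling the perpendicular
      axis, so both sets have the same chord length and balanced counts.
    * ``steps=2`` — all 4 within pairs vs all 4 between pairs (no
      boundary-symmetric subset exists at this separation).
    * ``steps=3`` — WCS = the 2 pairs internal to a category; BCS defaults to
      the 2 between pairs that are mirror-symmetric about the boundary axis
      (``bcs_rule="symmetric"``); ``bcs_rule="all"`` uses all 6 between pairs.
    * ``steps=4`` — the 4 diametric pairs, all between-category, annotated
      near (both members nearest the boundary) or far.
    """
    half = ring.n_positions // 2
    if not 1 <= steps <= half:
        raise ValueError(f"steps must be in 1..{half}")
    if bcs_rule not in ("symmetric", "all"):
        raise ValueError("bcs_rule must be 'symmetric' or 'all'")

    pairs = _all_pairs(ring, steps)
    within = tuple(p for p in pairs if _is_within(ring, b, p))
    between = tuple(p for p in pairs if not _is_within(ring, b, p))

    if steps == half:
        dmin = min(boundary_distance(ring, b, k) for k in ring.positions)
        near = tuple(
            p
            for p in between
            if all(
                math.isclose(boundary_distance(ring, b, k), dmin, rel_tol=1e-9)
                for k in p
            )
        )
        far = tuple(p for p in between if p not in near)
        return PairSet(steps, wcs_pairs=(), bcs_pairs=between,
                       near_pairs=near, far_pairs=far)

    if steps == 1:
        perp = b.perpendicular()
        wcs = tuple(p for p in within if not _is_within(ring, perp, p))
        return PairSet(steps, wcs_pairs=wcs, bcs_pairs=between)

    if steps * 3 == ring.n_positions or (ring.n_positions == 8 and steps == 3):
        if bcs_rule == "symmetric":
            sym = tuple(
                p
                for p in between
                if tuple(sorted((b.reflect(ring, p[0]), b.reflect(ring, p[1])))) == p
            )
            return PairSet(steps, wcs_pairs=within, bcs_pairs=sym)
        return PairSet(steps, wcs_pairs=within, bcs_pairs=between)

    return PairSet(steps, wcs_pairs=within, bcs_pairs=between)


def geometry_json(ring: StimulusRing, b: Boundary | None = None) -> str:
    """JSON description of the geometry (positions, boundary, pair sets)
    for inclusion in reports."""
    doc: dict = {
        "n_positions": ring.n_positions,
        "eccentricity_dva": ring.eccentricity,
        "positions": [
            {
                "index": k,
                "angle_deg": ring.angle_of(k),
                "xy_dva": list(ring.position_xy(k)),
            }
            for k in ring.positions
        ],
        "chord_dva": {
            s: chord_distance(ring, s) for s in range(1, ring.n_positions // 2 + 1)
        },
    }
    if b is not None:
        pos_side, neg_side = b.partition(ring)
        doc["boundary"] = {
            "axis_angle_deg": b.axis_angle,
            "partition": [list(pos_side), list(neg_side)],
            "boundary_distance_dva": {
                k: boundary_distance(ring, b, k) for k in ring.positions
            },
            "pair_sets": {
                s: {
                    "wcs": [list(p) for p in pair_sets(ring, b, s).wcs_pairs],
                    "bcs": [list(p) for p in pair_sets(ring, b, s).bcs_pairs],
                    "near": [list(p) for p in pair_sets(ring, b, s).near_pairs],
                    "far": [list(p) for p in pair_sets(ring, b, s).far_pairs],
                }
                for s in range(1, ring.n_positions // 2 + 1)
            },
        }
    return json.dumps(doc, indent=2)
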