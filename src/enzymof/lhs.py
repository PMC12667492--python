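"""Latin hypercube seeding of the synthesis campaign.

The seed stage selects a handful of recipes (default 15, ≈0.08‰ of the default
space) that spread over the whole synthesis space, so the first surrogate model
sees every region rather than a cluster chosen by intuition. LHS stratifies
each axis into ``n`` equal-width bins and places exactly one sample in every
bin of every axis before the samples are snapped to the discrete grid.

The sampler is hand-rolled (per-axis stratum permutation + uniform draw within
the stratum) because snapping to a coarse grid can collide two samples onto
one point, and the resolution rule — redraw within the *colliding stratum*,
then fall back to the nearest unoccupied level — needs the per-sample stratum
bookkeeping that library LHS implementations do not expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design_space import DesignGrid, Recipe

__all__ = ["SeedPlan", "lhs_sample", "min_pairwise_distance", "uniform_random_plan"]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class SeedPlan:
    """The seed-stage design: ``n`` distinct on-grid recipes.

    ``unit_samples`` holds the pre-snap coordinates in the unit cube (one row
    per recipe), kept so the stratification property remains checkable after
    snapping.
    """

    recipes: list[Recipe]
    n: int
    seed: int
    unit_samples: np.ndarray  # (n, 3) in [0, 1)

    def __post_init__(self) -> None:
        assert len(self.recipes) == self.n
        assert len({r.as_tuple() for r in self.recipes}) == self.n, "recipes must be distinct"


def _snap_index(ax_levels: int, u: float) -> int:
    """Map a unit-cube coordinate to the nearest level index of an axis."""
    return int(np.clip(round(u * (ax_levels - 1)), 0, ax_levels - 1))


def lhs_sample(grid: DesignGrid, n: int, seed: int) -> SeedPlan:
    """Draw ``n`` distinct on-grid recipes by Latin hypercube sampling.

    Each axis is split into ``n`` equal strata; a random permutation assigns
    one stratum per sample per axis and the coordinate is drawn uniformly
    within its stratum, then snapped to the nearest grid level. If two samples
    snap to the same grid point, the later one is redrawn within its own
    strata up to 100 times; if collisions persist (grids much coarser than
    ``n``), the nearest unoccupied grid point is taken instead.

    Deterministic for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > grid.size:
        raise ValueError(f"cannot draw {n} distinct recipes from a {grid.size}-point grid")
    rng = np.random.default_rng(seed)
    d = len(grid.axes)
    # One stratum per sample per axis: permuted stratum indices + uniform offsets.
    strata = np.stack([rng.permutation(n) for _ in range(d)], axis=1)  # (n, d)
    unit = (strata + rng.random((n, d))) / n

    levels = [ax.levels() for ax in grid.axes]
    occupied: set[tuple[float, float, float]] = set()
    recipes: list[Recipe] = []
    for i in range(n):
        u = unit[i].copy()
        point = None
        for _ in range(_MAX_REDRAWS):
            idx = [_snap_index(len(levels[j]), u[j]) for j in range(d)]
            cand = tuple(float(levels[j][idx[j]]) for j in range(d))
            if cand not in occupied:
                point = cand
                break
            # Redraw within this sample's own strata.
            u = (strata[i] + rng.random(d)) / n
        if point is None:
            point = _nearest_unoccupied(grid, unit[i], occupied)
        occupied.add(point)
        recipes.append(Recipe(*point))
    return SeedPlan(recipes=recipes, n=n, seed=seed, unit_samples=unit)


def _nearest_unoccupied(
    grid: DesignGrid, u: np.ndarray, occupied: set
) -> tuple[float, float, float]:
    """Fallback for persistent snap collisions: nearest free point in normalized axes."""
    pts = grid.points()
    lo = np.array([ax.minimum for ax in grid.axes])
    span = np.array([ax.maximum - ax.minimum for ax in grid.axes])
    target = lo + u * span
    dist = np.linalg.norm((pts - target) / span, axis=1)
    for i in np.argsort(dist, kind="stable"):
        cand = tuple(float(v) for v in pts[i])
        if cand not in occupied:
            return cand
    raise RuntimeError("grid exhausted")  # unreachable: n <= grid.size


def uniform_random_plan(grid: DesignGrid, n: int, seed: int) -> list[Recipe]:
    """Baseline design: ``n`` distinct grid points drawn uniformly at random."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(grid.size, size=n, replace=False)
    pts = grid.points()[idx]
    return [Recipe(*row) for row in pts]


def min_pairwise_distance(recipes: list[Recipe], grid: DesignGrid) -> float:
    """Minimum pairwise Euclidean distance between recipes on normalized axes.

    Axes are scaled to [0, 1] so millimolar and mg/mL coordinates weigh
    equally; larger is better for space-filling designs.
    """
    lo = np.array([ax.minimum for ax in grid.axes])
    span = np.array([ax.maximum - ax.minimum for ax in grid.axes])
    pts = (np.array([r.as_array() for r in recipes]) - lo) / span
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(len(recipes), k=1)
    return float(dist[iu].min())
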