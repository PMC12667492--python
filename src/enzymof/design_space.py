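"""Discrete synthesis space for one-pot enzyme@MOF biocomposite formulation.

A synthesis condition ("recipe") is a point in a three-axis space of final
concentrations in the reaction volume: [Ca2+] and [ligand] in mM and [enzyme]
in mg/mL. The space is a finite grid — each axis carries evenly spaced levels —
so the optimization loop can score every candidate exhaustively.

This module defines the axes and grid, converts between final-concentration
recipes and integer-microliter pipetting plans, and validates that recipes are
achievable from the stock solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleRecipeError

__all__ = [
    "Axis",
    "DesignGrid",
    "Recipe",
    "StockSet",
    "VolumePlan",
    "enumerate_grid",
    "recipe_to_volumes",
    "volumes_to_recipe",
    "check_feasibility",
    "default_axes",
    "default_stocks",
    "default_grid",
    "FULL_SPACE_SIZE",
]

#: Cardinality of the default screening space (17 Ca x 101 ligand x 103 enzyme levels).
FULL_SPACE_SIZE = 176_851

_COMMENSURATE_TOL = 1e-9


@dataclass(frozen=True)
class Axis:
    """One concentration axis of the synthesis space.

    Parameters
    ----------
    name:
        Label, e.g. ``"ca_mM"``.
    minimum, maximum:
        Inclusive bounds (mM or mg/mL).
    step:
        Level spacing. ``maximum - minimum`` must be an integer multiple of
        ``step`` (within 1e-9) so the axis closes exactly on its bounds.
    """

    name: str
    minimum: float
    maximum: float
    step: float

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise ConfigurationError(
                f"axis {self.name!r}: minimum {self.minimum} must be < maximum {self.maximum}"
            )
        if not self.step > 0:
            raise ConfigurationError(f"axis {self.name!r}: step must be > 0")
        span = self.maximum - self.minimum
        ratio = span / self.step
        if abs(ratio - round(ratio)) > _COMMENSURATE_TOL * max(1.0, ratio):
            raise ConfigurationError(
                f"axis {self.name!r}: span {span} is not an integer multiple of step {self.step}"
            )

    @classmethod
    def from_levels(cls, name: str, minimum: float, maximum: float, n_levels: int) -> "Axis":
        """Declare an axis by its level count instead of its increment."""
        if n_levels < 2:
            raise ConfigurationError(f"axis {name!r}: need at least 2 levels")
        return cls(name, minimum, maximum, (maximum - minimum) / (n_levels - 1))

    @property
    def n_levels(self) -> int:
        return int(round((self.maximum - self.minimum) / self.step)) + 1

    def levels(self) -> np.ndarray:
        return np.linspace(self.minimum, self.maximum, self.n_levels)

    def snap(self, value: float) -> float:
        """Nearest on-axis level to ``value`` (clipped to the bounds)."""
        idx = int(round((value - self.minimum) / self.step))
        idx = min(max(idx, 0), self.n_levels - 1)
        return float(self.levels()[idx])

    def contains(self, value: float, tol: float = 1e-9) -> bool:
        return self.minimum - tol <= value <= self.maximum + tol


@dataclass(frozen=True)
class Recipe:
    """A synthesis condition: final concentrations in the reaction volume."""

    ca_conc: float  # mM
    idc_conc: float  # mM
    enzyme_conc: float  # mg/mL

    def as_array(self) -> np.ndarray:
        return np.array([self.ca_conc, self.idc_conc, self.enzyme_conc], dtype=float)

    def as_tuple(self) -> tuple[float, float, float]:
        return (float(self.ca_conc), float(self.idc_conc), float(self.enzyme_conc))


@dataclass(frozen=True)
class StockSet:
    """Stock concentrations and the total reaction volume.

    Feasibility of an individual recipe is checked when converting it to a
    pipetting plan; see :func:`check_feasibility` for a whole-grid audit.
    """

    ca_stock: float = 100.0  # mM
    idc_stock: float = 125.0  # mM (the deprotonated-ligand stock)
    enzyme_stock: float = 2.0  # mg/mL
    total_volume: float = 500.0  # µL

    def __post_init__(self) -> None:
        for field in ("ca_stock", "idc_stock", "enzyme_stock", "total_volume"):
            if getattr(self, field) <= 0:
                raise ConfigurationError(f"stock field {field} must be strictly positive")


@dataclass(frozen=True)
class VolumePlan:
    """Integer-µL pipetting plan; water is the balance to the total volume."""

    water_vol: float
    idc_vol: float
    enzyme_vol: float
    ca_vol: float

    @property
    def total(self) -> float:
        return self.water_vol + self.idc_vol + self.enzyme_vol + self.ca_vol


class DesignGrid:
    """The enumerable set of recipes: the Cartesian product of the axis levels.

    Iteration order is lexicographic by axis order (Ca slowest), so point
    indices are stable identifiers across runs.
    """

    def __init__(self, axes: Sequence[Axis]):
        if len(axes) != 3:
            raise ConfigurationError(f"expected 3 axes, got {len(axes)}")
        self.axes: tuple[Axis, Axis, Axis] = tuple(axes)  # type: ignore[assignment]

    @property
    def size(self) -> int:
        return int(np.prod([ax.n_levels for ax in self.axes]))

    def points(self) -> np.ndarray:
        """All grid points as an (size, 3) array in lexicographic order."""
        grids = np.meshgrid(*[ax.levels() for ax in self.axes], indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterable[Recipe]:
        for row in self.points():
            yield Recipe(*row)

    def snap(self, ca: float, idc: float, enzyme: float) -> Recipe:
        a_ca, a_idc, a_enz = self.axes
        return Recipe(a_ca.snap(ca), a_idc.snap(idc), a_enz.snap(enzyme))

    def contains(self, recipe: Recipe) -> bool:
        a_ca, a_idc, a_enz = self.axes
        return (
            a_ca.contains(recipe.ca_conc)
            and a_idc.contains(recipe.idc_conc)
            and a_enz.contains(recipe.enzyme_conc)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points(), columns=["ca_mM", "idc_mM", "enzyme_mg_per_ml"]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def enumerate_grid(axes: Sequence[Axis]) -> DesignGrid:
    """Build the discrete synthesis space from validated axes.

    The grid size is the product of the per-axis level counts and enumeration
    is exhaustive and duplicate-free by construction.
    """
    return DesignGrid(axes)


def default_axes() -> list[Axis]:
    """The default screening space: Ca 2–98 mM, ligand 22.5–122.5 mM, enzyme 0.2–1.96 mg/mL.

    Level counts 17 × 101 × 103 (Ca step 6 mM, ligand step 1 mM, enzyme 103
    even levels ≈ 0.01725 mg/mL apart) give 176,851 combinations.
    """
    return [
        Axis("ca_mM", 2.0, 98.0, 6.0),
        Axis("idc_mM", 22.5, 122.5, 1.0),
        Axis.from_levels("enzyme_mg_per_ml", 0.2, 1.96, 103),
    ]


def default_stocks() -> StockSet:
    return StockSet()


def default_grid() -> DesignGrid:
    grid = enumerate_grid(default_axes())
    if grid.size != FULL_SPACE_SIZE:
        warnings.warn(
            f"default grid has {grid.size} points, expected {FULL_SPACE_SIZE}",
            stacklevel=2,
        )
    return grid


def recipe_to_volumes(recipe: Recipe, stocks: StockSet) -> VolumePlan:
    """Convert a final-concentration recipe into an integer-µL pipetting plan.

    Each component volume is ``conc × total_volume / stock`` rounded to the
    nearest microliter; water makes up the balance so the plan sums exactly to
    the reaction volume.

    Raises
    ------
    InfeasibleRecipeError
        If the component volumes exceed the total reaction volume.
    """
    ca_vol = round(recipe.ca_conc * stocks.total_volume / stocks.ca_stock)
    idc_vol = round(recipe.idc_conc * stocks.total_volume / stocks.idc_stock)
    enzyme_vol = round(recipe.enzyme_conc * stocks.total_volume / stocks.enzyme_stock)
    if min(ca_vol, idc_vol, enzyme_vol) < 0:
        raise InfeasibleRecipeError("negative component volume (negative concentration?)")
    water = stocks.total_volume - ca_vol - idc_vol - enzyme_vol
    if water < 0:
        raise InfeasibleRecipeError(
            f"recipe {recipe} needs {ca_vol + idc_vol + enzyme_vol} µL of stocks "
            f"but the reaction volume is {stocks.total_volume} µL"
        )
    return VolumePlan(water_vol=water, idc_vol=idc_vol, enzyme_vol=enzyme_vol, ca_vol=ca_vol)


def volumes_to_recipe(plan: VolumePlan, stocks: StockSet) -> Recipe:
    """Recover the final-concentration recipe implied by a pipetting plan.

    Uses the plan's own total volume (which may differ from ``stocks.total_volume``
    by rounding, or more for hand-written plans) as the dilution denominator.
    """
    total = plan.total
    if total <= 0:
        raise ConfigurationError("plan total volume must be positive")
    if min(plan.water_vol, plan.idc_vol, plan.enzyme_vol, plan.ca_vol) < 0:
        raise ConfigurationError("plan volumes must be non-negative")
    return Recipe(
        ca_conc=plan.ca_vol * stocks.ca_stock / total,
        idc_conc=plan.idc_vol * stocks.idc_stock / total,
        enzyme_conc=plan.enzyme_vol * stocks.enzyme_stock / total,
    )


def check_feasibility(grid: DesignGrid, stocks: StockSet) -> None:
    """Verify that every grid point can be pipetted from the stocks.

    Sufficient to check the all-axes-at-maximum corner (volumes are monotone
    in concentration). Raises :class:`InfeasibleRecipeError` naming the corner
    if it cannot fit in the reaction volume. Note the default space is
    deliberately not feasibility-checked at construction: its high-Ca corner
    (98 mM from a 100 mM stock needs 490 of 500 µL) is unreachable with the
    default stocks, and recipes near it fail individually on conversion.
    """
    a_ca, a_idc, a_enz = grid.axes
    corner = Recipe(a_ca.maximum, a_idc.maximum, a_enz.maximum)
    try:
        recipe_to_volumes(corner, stocks)
    except InfeasibleRecipeError as exc:
        raise InfeasibleRecipeError(
            f"grid corner {corner} infeasible under stocks {stocks}: {exc}"
        ) from exc
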