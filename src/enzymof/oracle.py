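"""Synthetic wet-lab oracle: ground-truth response surfaces plus assay emulation.

The closed-loop optimizer was designed around laboratory measurements; this
module stands in for the bench. It holds smooth ground-truth EE and REA
surfaces over the design grid, adds replicate noise of realistic magnitude
(default SD 1.7 percentage points, triplicate), and can optionally emit the
*raw* signals a plate reader would produce — BCA standards and supernatant
absorbances on a known calibration line, and kinetic hydrolysis traces with
the implied initial slope — so the assay-reduction code path is exercised
end-to-end exactly as it would be on real exports.

Default surfaces encode the qualitative structure expected of this chemistry:
EE rises monotonically with both the metal and ligand concentrations
(saturating Hill terms, scaled to [0.2, 0.9], with a mild enzyme factor),
while REA peaks in a different region of the space (a Gaussian bump), so the
EE-optimal and activity-optimal recipes do not coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np

from .assays import (
    KineticTrace,
    TrialResult,
    compute_ee,
    compute_rea,
    concentration_from_absorbance,
    fit_bca_calibration,
    initial_rate,
)
from .design_space import DesignGrid, Recipe
from .errors import ConfigurationError

__all__ = [
    "OracleConfig",
    "GroundTruth",
    "RawSignalBundle",
    "make_surface",
    "measure",
    "measure_raw",
    "reduce_bundle",
    "Oracle",
    "DEFAULT_EE_PARAMS",
    "DEFAULT_REA_PARAMS",
]

# --- default surface parameters -------------------------------------------------

DEFAULT_EE_PARAMS: dict = {
    "lo": 0.2,          # EE fraction floor (worst recipes still co-precipitate a little)
    "hi": 0.9,          # EE fraction ceiling
    "k_ca": 30.0,       # mM, half-saturation of the Ca term
    "p_ca": 2.0,
    "k_idc": 50.0,      # mM, half-saturation of the ligand term
    "p_idc": 2.0,
    "enzyme_center": 1.08,     # mg/mL with the mildest penalty
    "enzyme_halfwidth": 0.88,  # mg/mL to the worst-case edge
    "enzyme_weight": 0.15,     # max fractional penalty from the enzyme axis
}

DEFAULT_REA_PARAMS: dict = {
    "base": 0.05,
    "amp": 0.80,
    "center": (26.0, 60.0, 0.6),   # (Ca mM, ligand mM, enzyme mg/mL)
    "width": (25.0, 30.0, 0.5),
}

# Fixed instrument model for raw-signal emission. The calibration line is the
# known generating line; reduction re-estimates it from the emitted standards.
_CAL_SLOPE = 0.8        # AU per mg/mL at 562 nm
_CAL_INTERCEPT = 0.05   # AU
_STANDARD_CONCS = (0.125, 0.25, 0.5, 1.0)  # mg/mL
_REACTION_VOLUME_ML = 0.5
_SUPERNATANT_VOLUME_ML = 0.5
_FREE_RATE = 0.002      # AU/s initial slope of the free-enzyme assay
_TRACE_TIMES = np.arange(0.0, 125.0, 5.0)  # s
_TRACE_BASELINE = 0.05  # AU


@dataclass(frozen=True)
class OracleConfig:
    """Parameters of the synthetic ground truth and its noise model.

    ``noise_sd`` is in percentage points on the response scale (homoscedastic
    Gaussian, truncated to keep fractions in [0, 1]); ``replicates`` mirrors
    the triplicate protein assays.
    """

    surface_kind: str = "saturating_product"
    ee_params: Mapping = field(default_factory=lambda: dict(DEFAULT_EE_PARAMS))
    rea_params: Mapping = field(default_factory=lambda: dict(DEFAULT_REA_PARAMS))
    noise_sd: float = 1.7
    replicates: int = 3
    emit_raw: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.surface_kind not in ("saturating_product", "gaussian_bump", "custom_table"):
            raise ConfigurationError(f"unknown surface kind {self.surface_kind!r}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Vectorized true response fractions over the space."""

    ee_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    rea_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]

    def ee_true(self, recipe: Recipe) -> float:
        return float(self.ee_fn(*[np.asarray(v) for v in recipe.as_tuple()]))

    def rea_true(self, recipe: Recipe) -> float:
        return float(self.rea_fn(*[np.asarray(v) for v in recipe.as_tuple()]))

    def ee_grid(self, grid: DesignGrid) -> np.ndarray:
        p = grid.points()
        return np.asarray(self.ee_fn(p[:, 0], p[:, 1], p[:, 2]), dtype=float)

    def rea_grid(self, grid: DesignGrid) -> np.ndarray:
        p = grid.points()
        return np.asarray(self.rea_fn(p[:, 0], p[:, 1], p[:, 2]), dtype=float)


def _hill(x, k, p):
    xp = np.power(np.maximum(x, 0.0), p)
    return xp / (xp + k**p)


def _saturating_product(params: Mapping):
    pr = dict(DEFAULT_EE_PARAMS)
    pr.update(params)

    def fn(ca, idc, enz):
        g = 1.0 - pr["enzyme_weight"] * np.minimum(
            ((enz - pr["enzyme_center"]) / pr["enzyme_halfwidth"]) ** 2, 1.0
        )
        return pr["lo"] + (pr["hi"] - pr["lo"]) * _hill(ca, pr["k_ca"], pr["p_ca"]) * _hill(
            idc, pr["k_idc"], pr["p_idc"]
        ) * g

    return fn


def _gaussian_bump(params: Mapping):
    pr = dict(DEFAULT_REA_PARAMS)
    pr.update(params)
    c = np.asarray(pr["center"], dtype=float)
    w = np.asarray(pr["width"], dtype=float)

    def fn(ca, idc, enz):
        q = ((ca - c[0]) / w[0]) ** 2 + ((idc - c[1]) / w[1]) ** 2 + ((enz - c[2]) / w[2]) ** 2
        return pr["base"] + pr["amp"] * np.exp(-0.5 * q)

    return fn


def _custom_table(params: Mapping):
    table = {tuple(np.round(k, 9)) if isinstance(k, tuple) else k: v for k, v in params["table"].items()}
    default = params.get("default", 0.0)

    def fn(ca, idc, enz):
        scalar = np.ndim(ca) == 0 and np.ndim(idc) == 0 and np.ndim(enz) == 0
        ca, idc, enz = np.broadcast_arrays(np.atleast_1d(ca), np.atleast_1d(idc), np.atleast_1d(enz))
        out = np.array(
            [
                table.get(tuple(np.round((a, b, c), 9)), default)
                for a, b, c in zip(ca.ravel(), idc.ravel(), enz.ravel())
            ]
        )
        return float(out[0]) if scalar else out.reshape(ca.shape)

    return fn


def make_surface(config: OracleConfig, grid: DesignGrid) -> GroundTruth:
    """Build the ground truth and verify it is bounded in [0, 1] over the grid.

    ``saturating_product`` uses the monotone product form for EE and the
    off-center Gaussian bump for REA; ``gaussian_bump`` uses bumps for both;
    ``custom_table`` pins explicit per-recipe values (tests use this).
    """
    if config.surface_kind == "saturating_product":
        ee_fn = _saturating_product(config.ee_params)
        rea_fn = _gaussian_bump(config.rea_params)
    elif config.surface_kind == "gaussian_bump":
        ee_fn = _gaussian_bump(config.ee_params)
        rea_fn = _gaussian_bump(config.rea_params)
    else:
        ee_fn = _custom_table(config.ee_params)
        rea_fn = _custom_table(config.rea_params) if "table" in config.rea_params else _gaussian_bump({})
    truth = GroundTruth(ee_fn=ee_fn, rea_fn=rea_fn)
    for name, vals in (("EE", truth.ee_grid(grid)), ("REA", truth.rea_grid(grid))):
        if np.any(vals < 0.0) or np.any(vals > 1.0):
            raise ConfigurationError(
                f"{name} surface leaves [0, 1] over the grid "
                f"(range [{vals.min():.3f}, {vals.max():.3f}])"
            )
    return truth


@dataclass(frozen=True)
class RawSignalBundle:
    """Plate-reader-shaped raw signals for one synthesis trial.

    Carries everything the assay module needs: BCA standards, one supernatant
    absorbance per replicate, the enzyme mass pipetted into the synthesis, the
    supernatant volume, and kinetic traces for the composite replicates and
    the free-enzyme reference.
    """

    recipe: Recipe
    standards: list
    supernatant_absorbances: list
    mass_used_mg: float
    supernatant_volume_ml: float
    sample_traces: list
    free_trace: KineticTrace


def _recipe_rng(config: OracleConfig, recipe: Recipe) -> np.random.Generator:
    # Deterministic per (seed, recipe): same recipe always yields the same
    # replicate draws regardless of measurement order.
    key = [int(round(v * 1e6)) for v in recipe.as_tuple()]
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


def _replicate_fractions(truth_val: float, config: OracleConfig, rng) -> np.ndarray:
    reps = truth_val + rng.normal(0.0, config.noise_sd / 100.0, size=config.replicates)
    return np.clip(reps, 0.0, 1.0)


def measure(truth: GroundTruth, recipe: Recipe, config: OracleConfig) -> TrialResult:
    """Simulate one synthesis + assay: replicate-averaged EE/REA with noise.

    Replicates are truth ± N(0, noise_sd) on the percent scale, truncated to
    the physical range; the reported value is the replicate mean and
    ``replicate_sd`` the replicate standard deviation.
    """
    rng = _recipe_rng(config, recipe)
    ee_reps = _replicate_fractions(truth.ee_true(recipe), config, rng)
    rea_reps = _replicate_fractions(truth.rea_true(recipe), config, rng)
    sd = float(np.std(ee_reps, ddof=1) * 100.0) if config.replicates > 1 else None
    return TrialResult(
        recipe=recipe,
        ee=float(ee_reps.mean() * 100.0),
        rea=float(rea_reps.mean() * 100.0),
        replicate_sd=sd,
    )


def measure_raw(truth: GroundTruth, recipe: Recipe, config: OracleConfig) -> RawSignalBundle:
    """Emit raw assay signals whose reduction reproduces the noisy responses.

    The replicate draws are identical to :func:`measure` (same child RNG), so
    reducing the bundle with the assay module recovers the same trial values;
    at ``noise_sd = 0`` the round trip recovers the ground truth itself.
    """
    rng = _recipe_rng(config, recipe)
    ee_reps = _replicate_fractions(truth.ee_true(recipe), config, rng)
    rea_reps = _replicate_fractions(truth.rea_true(recipe), config, rng)

    standards = [(c, _CAL_SLOPE * c + _CAL_INTERCEPT) for c in _STANDARD_CONCS]
    mass_used = recipe.enzyme_conc * _REACTION_VOLUME_ML  # mg
    sup_abs = []
    for ee_frac in ee_reps:
        residual_conc = (1.0 - ee_frac) * mass_used / _SUPERNATANT_VOLUME_ML
        sup_abs.append(_CAL_SLOPE * residual_conc + _CAL_INTERCEPT)
    traces = [
        KineticTrace(_TRACE_TIMES, _TRACE_BASELINE + rea_frac * _FREE_RATE * _TRACE_TIMES)
        for rea_frac in rea_reps
    ]
    free = KineticTrace(_TRACE_TIMES, _TRACE_BASELINE + _FREE_RATE * _TRACE_TIMES)
    return RawSignalBundle(
        recipe=recipe,
        standards=standards,
        supernatant_absorbances=sup_abs,
        mass_used_mg=mass_used,
        supernatant_volume_ml=_SUPERNATANT_VOLUME_ML,
        sample_traces=traces,
        free_trace=free,
    )


def reduce_bundle(bundle: RawSignalBundle) -> TrialResult:
    """Reduce a raw bundle to a trial via the assay module (the real-data path)."""
    curve = fit_bca_calibration(bundle.standards)
    ees = []
    for a in bundle.supernatant_absorbances:
        conc = concentration_from_absorbance(curve, a)
        ees.append(compute_ee(bundle.mass_used_mg, conc, bundle.supernatant_volume_ml))
    rate_free = initial_rate(bundle.free_trace)
    reas = [compute_rea(initial_rate(tr), rate_free) for tr in bundle.sample_traces]
    sd = float(np.std(ees, ddof=1)) if len(ees) > 1 else None
    return TrialResult(
        recipe=bundle.recipe,
        ee=float(np.mean(ees)),
        rea=float(np.mean(reas)),
        replicate_sd=sd,
    )


class Oracle:
    """Callable measurement source for the campaign loop.

    ``oracle(recipe)`` returns a reduced :class:`TrialResult`; with
    ``emit_raw`` set, each measurement round-trips through raw-signal emission
    and assay reduction instead of being reduced analytically.
    """

    def __init__(self, config: OracleConfig, grid: DesignGrid, truth: Optional[GroundTruth] = None):
        self.config = config
        self.grid = grid
        self.truth = truth if truth is not None else make_surface(config, grid)

    def __call__(self, recipe: Recipe) -> TrialResult:
        if self.config.emit_raw:
            return reduce_bundle(measure_raw(self.truth, recipe, self.config))
        return measure(self.truth, recipe, self.config)
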