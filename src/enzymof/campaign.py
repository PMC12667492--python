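"""The closed training–design–synthesis–measurement loop, plus reporting.

A campaign starts from an LHS seed set (default 15 recipes), selects the
surrogate family once by 10-fold CV on the seed data, then alternates
``fit → propose batch → measure → append`` for up to ``max_iterations`` rounds
(default 9 × batches of 10, i.e. 105 trials in a full run). The loop stops
early when the grid-wide predicted maximum has been stable — relative change
below ``convergence_rel_tol`` for ``convergence_patience`` consecutive
iterations.

Reporting covers the response distribution, per-feature Shapley attributions
of the fitted surrogate (exact interventional values: with three features the
2³ subset sum is cheap, no sampling needed), and a t-SNE embedding of the
trial recipes for visualizing where high-EE and high-REA regions sit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .acquisition import AcquisitionConfig, propose_batch
from .assays import TrialResult
from .design_space import DesignGrid, Recipe
from .errors import ConfigurationError
from .lhs import lhs_sample
from .surrogate import ModelFamily, SurrogateFit, cross_validate, default_families, fit, select_model

__all__ = [
    "CampaignConfig",
    "CampaignState",
    "run_campaign",
    "check_convergence",
    "space_fraction",
    "shap_summary",
    "tsne_embed",
    "distribution_report",
    "DistributionReport",
]

logger = logging.getLogger("enzymof")

FEATURE_NAMES = ("ca_mM", "idc_mM", "enzyme_mg_per_ml")


@dataclass(frozen=True)
class CampaignConfig:
    """Campaign-level knobs; acquisition-level ones live in ``acquisition``."""

    n_seed: int = 15
    batch_size: int = 10
    max_iterations: int = 9
    convergence_rel_tol: float = 0.01
    convergence_patience: int = 2
    target: str = "EE"
    master_seed: int = 0
    early_stop: bool = True
    #: "predicted": f' is the largest model-predicted value over tested recipes;
    #: "observed": f' is the best raw observation.
    f_best_mode: str = "predicted"
    families: Optional[Sequence[ModelFamily]] = None
    reselect_each_round: bool = False
    cv_folds: int = 10
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        for name in ("n_seed", "batch_size", "max_iterations", "convergence_patience", "cv_folds"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if not 0.0 < self.convergence_rel_tol < 1.0:
            raise ConfigurationError("convergence_rel_tol must lie in (0, 1)")
        if self.target not in ("EE", "PI"):
            raise ConfigurationError("target must be 'EE' or 'PI'")
        if self.f_best_mode not in ("predicted", "observed"):
            raise ConfigurationError("f_best_mode must be 'predicted' or 'observed'")
        if self.acquisition.top_k != self.batch_size:
            object.__setattr__(
                self, "acquisition",
                AcquisitionConfig(
                    kind=self.acquisition.kind,
                    xi=self.acquisition.xi,
                    n_generate=max(self.acquisition.n_generate, self.batch_size),
                    top_k=self.batch_size,
                ),
            )


@dataclass
class CampaignState:
    """Full audit of one campaign run."""

    grid: DesignGrid
    config: CampaignConfig
    trials: list[TrialResult] = field(default_factory=list)
    stages: list[tuple[str, int]] = field(default_factory=list)  # (stage, iteration) per trial
    iteration: int = 0
    predicted_max_history: list[float] = field(default_factory=list)
    seed_predicted_max: Optional[float] = None
    model_selection_record: Optional[pd.DataFrame] = None
    selected_family: Optional[ModelFamily] = None
    cv_mse_history: list[float] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)

    @property
    def ok_trials(self) -> list[TrialResult]:
        return [t for t in self.trials if t.status == "ok"]

    @property
    def best_observed(self) -> TrialResult:
        return max(self.ok_trials, key=lambda t: t.target_value(self.config.target))

    def trials_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (t, (stage, it)) in enumerate(zip(self.trials, self.stages)):
            rows.append(
                {
                    "trial_id": i,
                    "stage": stage,
                    "iteration": it,
                    "ca_mM": t.recipe.ca_conc,
                    "idc_mM": t.recipe.idc_conc,
                    "enzyme_mg_per_ml": t.recipe.enzyme_conc,
                    "ee_pct": t.ee,
                    "rea_pct": t.rea,
                    "pi": t.pi,
                    "replicate_sd": t.replicate_sd,
                    "status": t.status,
                }
            )
        return pd.DataFrame(rows)

    def audit_json(self) -> str:
        best = self.best_observed
        payload = {
            "target": self.config.target,
            "master_seed": self.config.master_seed,
            "stage_seeds": self.seeds,
            "iterations": self.iteration,
            "n_trials": len(self.trials),
            "selected_family": self.selected_family.name if self.selected_family else None,
            "seed_predicted_max": self.seed_predicted_max,
            "predicted_max_history": self.predicted_max_history,
            "cv_mse_history": self.cv_mse_history,
            "model_selection": (
                self.model_selection_record.to_dict(orient="records")
                if self.model_selection_record is not None
                else None
            ),
            "best_observed": {
                "recipe": list(best.recipe.as_tuple()),
                "value": best.target_value(self.config.target),
            },
        }
        return json.dumps(payload, indent=2)


def _stage_seed(master_seed: int, label: str, index: int = 0) -> int:
    """Deterministic child seed for a named stage, kept below 2**31."""
    key = sum(ord(c) * (31**i) for i, c in enumerate(label)) % (2**31)
    return int(np.random.SeedSequence([master_seed, key, index]).generate_state(1)[0] % (2**31))


def check_convergence(history: Sequence[float], rel_tol: float, patience: int) -> bool:
    """True iff the last ``patience`` successive relative changes are all < rel_tol.

    A zero-to-zero step counts as no change; a step away from an exactly-zero
    baseline counts as infinite change.
    """
    if len(history) < patience + 1:
        return False
    tail = list(history)[-(patience + 1):]
    for prev, cur in zip(tail, tail[1:]):
        if prev == 0:
            change = 0.0 if cur == 0 else math.inf
        else:
            change = abs(cur - prev) / abs(prev)
        if change >= rel_tol:
            return False
    return True


def space_fraction(n_trials: int, grid_size: int) -> float:
    """Fraction of the synthesis space visited, in per mille (‰)."""
    if grid_size <= 0:
        raise ConfigurationError("grid_size must be positive")
    return 1000.0 * n_trials / grid_size


def run_campaign(
    oracle: Callable[[Recipe], TrialResult],
    config: CampaignConfig,
    grid: DesignGrid,
) -> CampaignState:
    """Execute the full closed loop against a measurement source.

    ``oracle`` is any callable ``recipe -> TrialResult`` (the synthetic oracle,
    or a lookup into ingested lab CSVs). A raising oracle marks that trial
    ``failed``; failed trials stay in the audit but never reach the surrogate.
    Bit-reproducible given (config, oracle): every stochastic stage draws from
    a child seed derived from ``master_seed`` and the stage label.
    """
    state = CampaignState(grid=grid, config=config)
    families = list(config.families) if config.families is not None else default_families()
    acq = config.acquisition

    def run_one(recipe: Recipe, stage: str, iteration: int) -> None:
        try:
            trial = oracle(recipe)
        except Exception as exc:  # failed synthesis/measurement: audit and move on
            logger.warning("measurement failed for %s: %s", recipe, exc)
            trial = TrialResult(recipe=recipe, ee=float("nan"), status="failed")
        state.trials.append(trial)
        state.stages.append((stage, iteration))

    # --- seed stage -------------------------------------------------------
    lhs_seed = _stage_seed(config.master_seed, "lhs")
    state.seeds["lhs"] = lhs_seed
    plan = lhs_sample(grid, config.n_seed, lhs_seed)
    for r in plan.recipes:
        run_one(r, "seed", 0)
    logger.info("seed stage complete: %d trials", len(state.trials))

    # --- model selection on seed data ------------------------------------
    sel_seed = _stage_seed(config.master_seed, "select")
    state.seeds["select"] = sel_seed
    k = min(config.cv_folds, len(state.ok_trials))
    family, table = select_model(families, state.ok_trials, config.target, k=k, seed=sel_seed)
    state.selected_family = family
    state.model_selection_record = table
    logger.info("selected surrogate family: %s", family.name)

    # Baseline predicted maximum from the seed-stage fit (the reference the
    # first iteration's convergence delta is measured against).
    fit_seed = _stage_seed(config.master_seed, "fit", 0)
    sfit = fit(family, state.ok_trials, config.target, seed=fit_seed)
    grid_pts = grid.points()
    mu_all, sigma_all = sfit.predict(grid_pts)
    state.seed_predicted_max = float(mu_all.max())

    # --- iteration stage --------------------------------------------------
    for it in range(1, config.max_iterations + 1):
        if config.reselect_each_round and it > 1:
            k = min(config.cv_folds, len(state.ok_trials))
            family, table = select_model(
                families, state.ok_trials, config.target, k=k,
                seed=_stage_seed(config.master_seed, "select", it),
            )
            state.selected_family = family
            state.model_selection_record = table
        if it > 1:  # iteration 1 reuses the selection-stage fit
            fit_seed = _stage_seed(config.master_seed, "fit", it)
            sfit = fit(family, state.ok_trials, config.target, seed=fit_seed)
            mu_all, sigma_all = sfit.predict(grid_pts)
        k = min(config.cv_folds, len(state.ok_trials))
        state.cv_mse_history.append(
            cross_validate(family, state.ok_trials, config.target, k=k,
                           seed=_stage_seed(config.master_seed, "cv", it))
        )
        state.predicted_max_history.append(float(mu_all.max()))

        tested = [t.recipe for t in state.trials]
        if config.f_best_mode == "predicted":
            X_ok = np.array([t.recipe.as_array() for t in state.ok_trials])
            mu_ok, _ = sfit.predict(X_ok)
            f_best = float(np.max(mu_ok))
        else:
            f_best = float(max(t.target_value(config.target) for t in state.ok_trials))

        batch = propose_batch(sfit, grid, tested, acq, f_best, precomputed=(mu_all, sigma_all))
        for cand in batch:
            run_one(cand.recipe, "iteration", it)
        state.iteration = it
        logger.info(
            "iteration %d: predicted max %.4g, best observed %.4g, %d trials",
            it, state.predicted_max_history[-1],
            state.best_observed.target_value(config.target), len(state.trials),
        )

        if config.early_stop and check_convergence(
            [state.seed_predicted_max, *state.predicted_max_history],
            config.convergence_rel_tol,
            config.convergence_patience,
        ):
            logger.info("predicted maximum converged; stopping after iteration %d", it)
            break
    return state


# --- reporting -----------------------------------------------------------------


def shap_summary(
    sfit: SurrogateFit,
    trials: Sequence[TrialResult],
    max_background: int = 50,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Per-feature mean |Shapley attribution| of the fitted surrogate, descending.

    Exact interventional Shapley values: the value of a feature subset S at a
    point x is the model's mean prediction with x's coordinates on S and
    background coordinates elsewhere, averaged over a background sample of the
    trial recipes. With three features all 2³ subsets are enumerated, so the
    attributions are exact for the given background (no sampling error) and
    sum to f(x) − E[f] per point.
    """
    ok = [t for t in trials if t.status == "ok"]
    if len(ok) < 10:
        raise ValueError("need at least 10 trials for attribution analysis")
    X = np.array([t.recipe.as_array() for t in ok])
    rng = np.random.default_rng(seed)
    bg = X if len(X) <= max_background else X[rng.choice(len(X), max_background, replace=False)]

    d = X.shape[1]
    n, m = len(X), len(bg)
    subset_value: dict[frozenset, np.ndarray] = {}
    for r in range(d + 1):
        for S in combinations(range(d), r):
            # rows: every (x, background) pair with x's coords on S
            Xrep = np.repeat(bg[None, :, :], n, axis=0)  # (n, m, d)
            for j in S:
                Xrep[:, :, j] = X[:, None, j]
            mu, _ = sfit.predict(Xrep.reshape(n * m, d))
            subset_value[frozenset(S)] = mu.reshape(n, m).mean(axis=1)

    attributions = np.zeros((n, d))
    for i in range(d):
        others = [j for j in range(d) if j != i]
        for r in range(d):
            w = math.factorial(r) * math.factorial(d - r - 1) / math.factorial(d)
            for S in combinations(others, r):
                s = frozenset(S)
                attributions[:, i] += w * (subset_value[s | {i}] - subset_value[s])
    mean_abs = np.abs(attributions).mean(axis=0)
    ranked = sorted(zip(FEATURE_NAMES, mean_abs), key=lambda kv: -kv[1])
    return [(name, float(v)) for name, v in ranked]


def tsne_embed(trials: Sequence[TrialResult], seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of the trial recipes (z-scored axes), one row per trial.

    Deterministic for a fixed seed (exact-gradient solver, PCA init).
    """
    if len(trials) < 5:
        raise ValueError("need at least 5 trials for an embedding")
    X = np.array([t.recipe.as_array() for t in trials])
    Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    perplexity = min(30.0, (len(trials) - 1) / 3.0)
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        method="exact",
    ).fit_transform(Xz)
    return np.asarray(emb, dtype=float)


@dataclass(frozen=True)
class DistributionReport:
    """Histogram of a response over the campaign plus its extremes."""

    target: str
    bin_edges: np.ndarray
    counts: np.ndarray
    minimum: float
    maximum: float
    best: TrialResult

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def distribution_report(trials: Sequence[TrialResult], target: str = "EE") -> DistributionReport:
    """Bin the observed responses (5-point bins for EE, 0.05 for PI) and report extremes."""
    ok = [t for t in trials if t.status == "ok"]
    if not ok:
        raise ValueError("need at least one successful trial")
    vals = np.array([t.target_value(target) for t in ok])
    if target == "EE":
        edges = np.arange(0.0, 105.0, 5.0)
    else:
        edges = np.arange(0.0, 1.05, 0.05)
    # responses may legitimately exceed the nominal top edge (REA > 100%); widen if so
    while vals.max() > edges[-1]:
        edges = np.append(edges, edges[-1] + (edges[1] - edges[0]))
    counts, edges = np.histogram(vals, bins=edges)
    best = max(ok, key=lambda t: t.target_value(target))
    return DistributionReport(
        target=target,
        bin_edges=edges,
        counts=counts,
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        best=best,
    )
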