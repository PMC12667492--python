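"""Acquisition functions and batch proposal for the optimization loop.

Candidates are scored pointwise over the untested grid with either expected
improvement (EI, the default exploration stage) or probability of improvement
(PoI, the exploitation stage), relative to the improvement baseline f′ — by
default the largest model-predicted target value among already-tested recipes.

Batch proposal mirrors a two-stage scheme: ``n_generate`` candidates (default
30) are generated by acquisition score, then ranked by predicted mean response
and truncated to the ``top_k`` (default 10) that go to the bench.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .design_space import DesignGrid, Recipe
from .surrogate import SurrogateFit

__all__ = [
    "AcquisitionConfig",
    "ScoredCandidate",
    "expected_improvement",
    "probability_of_improvement",
    "propose_batch",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Batch-design knobs.

    ``xi`` trades exploration against exploitation (added to the improvement
    threshold); ``n_generate`` candidates are generated per round and the top
    ``top_k`` by predicted response are synthesized.
    """

    kind: str = "expected_improvement"
    xi: float = 0.01
    n_generate: int = 30
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("expected_improvement", "probability_of_improvement"):
            raise ValueError(f"unknown acquisition kind {self.kind!r}")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")
        if not 0 < self.top_k <= self.n_generate:
            raise ValueError("need 0 < top_k <= n_generate")


@dataclass(frozen=True)
class ScoredCandidate:
    recipe: Recipe
    mu: float
    sigma: float
    z: float
    score: float


def expected_improvement(mu, sigma, f_best: float, xi: float = 0.01):
    """Closed-form expected improvement over ``f_best + xi``.

    With Z = (μ − f′ − ξ)/σ:  EI = (μ − f′ − ξ)·Φ(Z) + σ·φ(Z) for σ > 0, and
    0 where σ = 0 (a known point cannot improve in expectation under the
    model). Vectorized over ``mu``/``sigma``; scalars in, scalar out.
    """
    mu_a = np.asarray(mu, dtype=float)
    sigma_a = np.asarray(sigma, dtype=float)
    if np.any(sigma_a < 0):
        raise ValueError("sigma must be >= 0")
    imp = mu_a - f_best - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma_a > 0, imp / np.where(sigma_a > 0, sigma_a, 1.0), 0.0)
    ei = np.where(sigma_a > 0, imp * norm.cdf(z) + sigma_a * norm.pdf(z), 0.0)
    ei = np.maximum(ei, 0.0)  # guard the tiny negative round-off in the far tail
    if np.isscalar(mu) and np.isscalar(sigma):
        return float(ei)
    return ei


def probability_of_improvement(mu, sigma, f_best: float, xi: float = 0.01):
    """Φ((μ − f′ − ξ)/σ): probability the candidate beats the baseline by ξ.

    At σ = 0 the limit convention applies: 1 if μ > f′ + ξ, else 0.
    """
    mu_a = np.asarray(mu, dtype=float)
    sigma_a = np.asarray(sigma, dtype=float)
    if np.any(sigma_a < 0):
        raise ValueError("sigma must be >= 0")
    imp = mu_a - f_best - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma_a > 0, imp / np.where(sigma_a > 0, sigma_a, 1.0), 0.0)
    poi = np.where(sigma_a > 0, norm.cdf(z), (imp > 0).astype(float))
    if np.isscalar(mu) and np.isscalar(sigma):
        return float(poi)
    return poi


def _z_values(mu: np.ndarray, sigma: np.ndarray, f_best: float, xi: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sigma > 0, (mu - f_best - xi) / np.where(sigma > 0, sigma, 1.0), 0.0)


def propose_batch(
    fit: SurrogateFit,
    grid: DesignGrid,
    tested: Iterable[Recipe],
    config: AcquisitionConfig,
    f_best: float,
    precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[ScoredCandidate]:
    """Score every untested grid point and propose the next batch.

    Stage 1 takes the ``n_generate`` highest acquisition scores as the
    generated candidate set; stage 2 ranks those by predicted mean μ and
    returns the ``top_k``, best first. Tested recipes are excluded exactly;
    ties break lexicographically by recipe so the proposal is deterministic
    given (fit, tested). ``precomputed`` may carry (μ, σ) over the full grid in
    enumeration order to avoid re-prediction.

    If fewer than ``top_k`` untested points remain, all of them are returned
    with a warning.
    """
    pts = grid.points()
    tested_keys = {r.as_tuple() for r in tested}
    mask = np.array([tuple(row) not in tested_keys for row in pts])
    untested = pts[mask]
    if untested.shape[0] == 0:
        warnings.warn("no untested grid points remain", stacklevel=2)
        return []
    if precomputed is not None:
        mu_all, sigma_all = precomputed
        mu, sigma = mu_all[mask], sigma_all[mask]
    else:
        mu, sigma = fit.predict(untested)
    if config.kind == "expected_improvement":
        score = expected_improvement(mu, sigma, f_best, config.xi)
    else:
        score = probability_of_improvement(mu, sigma, f_best, config.xi)
    z = _z_values(mu, sigma, f_best, config.xi)

    n = untested.shape[0]
    if n < config.top_k:
        warnings.warn(
            f"only {n} untested points remain (< top_k = {config.top_k}); returning all",
            stacklevel=2,
        )
    # Stage 1: top n_generate by acquisition score, lexicographic tie-break.
    order = sorted(range(n), key=lambda i: (-score[i], tuple(untested[i])))
    generated = order[: config.n_generate]
    # Stage 2: rank the generated set by predicted mean, keep top_k.
    generated.sort(key=lambda i: (-mu[i], tuple(untested[i])))
    chosen = generated[: config.top_k]
    return [
        ScoredCandidate(
            recipe=Recipe(*untested[i]),
            mu=float(mu[i]),
            sigma=float(sigma[i]),
            z=float(z[i]),
            score=float(score[i]),
        )
        for i in chosen
    ]
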