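import numpy as np
import pytest

from enzymof.assays import TrialResult
from enzymof.campaign import (
    CampaignConfig,
    check_convergence,
    distribution_report,
    run_campaign,
    shap_summary,
    space_fraction,
    tsne_embed,
)
from enzymof.design_space import Recipe
from enzymof.errors import ConfigurationError
from enzymof.oracle import GroundTruth, Oracle, OracleConfig, make_surface
from enzymof.surrogate import ModelFamily, fit

from conftest import constant_oracle_config

FAST_RF = ModelFamily("random_forest", {"n_estimators": 50})


def fast_config(**kw) -> CampaignConfig:
    defaults = dict(families=[FAST_RF], master_seed=0)
    defaults.update(kw)
    return CampaignConfig(**defaults)


class TestConvergence:
    @pytest.mark.parametrize(
        "history,expected",
        [
            ([0.5, 0.5, 0.5], True),
            ([0.1, 0.2, 0.4], False),
            ([0.50, 0.502, 0.503], True),  # relative deltas 0.4%, 0.2%
            ([0.5, 0.5], False),  # only one delta, patience 2
            ([0.0, 0.0, 0.0], True),  # zero-to-zero counts as no change
            ([0.0, 0.0, 0.1], False),  # a step away from zero is infinite change
        ],
    )
    def test_examples(self, history, expected):
        assert check_convergence(history, rel_tol=0.01, patience=2) is expected


class TestSpaceFraction:
    def test_published_per_mille_figures(self):
        assert round(space_fraction(105, 176_851), 2) == 0.59
        assert round(space_fraction(15, 176_851), 2) == 0.08

    def test_full_coverage_is_1000_per_mille(self):
        assert space_fraction(500, 500) == 1000.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            space_fraction(10, 0)


class TestCampaignLoop:
    def test_constant_oracle_stops_after_patience_iterations(self, toy_grid):
        oracle = Oracle(constant_oracle_config(0.5, noise_sd=0.0, seed=1), toy_grid)
        cfg = fast_config(n_seed=10, batch_size=5, max_iterations=9,
                          convergence_patience=2, early_stop=True)
        state = run_campaign(oracle, cfg, toy_grid)
        assert state.iteration == 2
        assert len(state.trials) == 10 + 2 * 5

    def test_bit_reproducible(self, toy_grid):
        def run():
            oracle = Oracle(OracleConfig(seed=4), toy_grid)
            cfg = fast_config(n_seed=8, batch_size=4, max_iterations=3, early_stop=False)
            return run_campaign(oracle, cfg, toy_grid)

        a, b = run(), run()
        assert a.trials_dataframe().equals(b.trials_dataframe())
        assert a.predicted_max_history == b.predicted_max_history

    def test_trial_accounting_and_stage_labels(self, toy_grid):
        oracle = Oracle(OracleConfig(seed=4), toy_grid)
        cfg = fast_config(n_seed=8, batch_size=4, max_iterations=3, early_stop=False)
        state = run_campaign(oracle, cfg, toy_grid)
        df = state.trials_dataframe()
        assert len(df) == 8 + 3 * 4
        assert (df["stage"] == "seed").sum() == 8
        assert (df["stage"] == "iteration").sum() == 12
        assert len(state.predicted_max_history) == state.iteration == 3
        # no recipe measured twice
        assert df[["ca_mM", "idc_mM", "enzyme_mg_per_ml"]].duplicated().sum() == 0

    def test_best_observed_nondecreasing_over_iterations(self, toy_grid):
        oracle = Oracle(OracleConfig(seed=4), toy_grid)
        cfg = fast_config(n_seed=8, batch_size=4, max_iterations=3, early_stop=False)
        state = run_campaign(oracle, cfg, toy_grid)
        df = state.trials_dataframe()
        best_so_far = df["ee_pct"].cummax()
        per_iter_best = df.groupby("iteration")["ee_pct"].max()
        assert best_so_far.is_monotonic_increasing
        assert state.best_observed.ee == df["ee_pct"].max()
        assert per_iter_best.notna().all()

    def test_failed_measurements_audited_but_excluded(self, toy_grid):
        inner = Oracle(OracleConfig(seed=4), toy_grid)
        poisoned = {tuple(toy_grid.points()[i]) for i in range(0, toy_grid.size, 7)}

        def flaky(recipe: Recipe) -> TrialResult:
            if recipe.as_tuple() in poisoned:
                raise RuntimeError("synthesis yielded amorphous product")
            return inner(recipe)

        cfg = fast_config(n_seed=10, batch_size=5, max_iterations=2, early_stop=False)
        state = run_campaign(flaky, cfg, toy_grid)
        df = state.trials_dataframe()
        assert (df["status"] == "failed").sum() > 0
        assert len(df) == 10 + 2 * 5  # failures still occupy their slot
        assert state.best_observed.status == "ok"

    def test_pi_campaign_balances_distinct_optima(self, small_grid):
        # the EE and REA optima sit in different regions; optimizing the
        # product lands somewhere that is neither
        oracle = Oracle(OracleConfig(seed=2), small_grid)
        cfg = fast_config(target="PI", n_seed=12, batch_size=6,
                          max_iterations=5, early_stop=False, master_seed=5)
        state = run_campaign(oracle, cfg, small_grid)
        pts = small_grid.points()
        ee_opt = tuple(pts[np.argmax(oracle.truth.ee_grid(small_grid))])
        rea_opt = tuple(pts[np.argmax(oracle.truth.rea_grid(small_grid))])
        best = state.best_observed.recipe.as_tuple()
        assert best != ee_opt and best != rea_opt

    def test_audit_json_roundtrip(self, toy_grid):
        import json

        oracle = Oracle(OracleConfig(seed=4), toy_grid)
        cfg = fast_config(n_seed=8, batch_size=4, max_iterations=2, early_stop=False)
        state = run_campaign(oracle, cfg, toy_grid)
        audit = json.loads(state.audit_json())
        assert audit["n_trials"] == 16
        assert audit["selected_family"] == "random_forest"
        assert len(audit["predicted_max_history"]) == 2

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            CampaignConfig(n_seed=0)
        with pytest.raises(ConfigurationError):
            CampaignConfig(convergence_rel_tol=1.5)
        with pytest.raises(ConfigurationError):
            CampaignConfig(target="REA")


def _ca_only_trials(grid, rng, n=40):
    cfg = OracleConfig(
        surface_kind="gaussian_bump",
        ee_params={"base": 0.1, "amp": 0.8, "center": (50.0, 0.0, 0.0), "width": (20.0, 1e9, 1e9)},
    )
    truth = make_surface(cfg, grid)
    pts = grid.points()[rng.choice(grid.size, size=n, replace=False)]
    return [
        TrialResult(recipe=Recipe(*row), ee=100.0 * truth.ee_true(Recipe(*row))) for row in pts
    ]


class TestShapSummary:
    def test_single_active_feature_ranks_first(self, small_grid, rng):
        trials = _ca_only_trials(small_grid, rng)
        sfit = fit(FAST_RF, trials, "EE", seed=0)
        ranked = shap_summary(sfit, trials, seed=0)
        assert ranked[0][0] == "ca_mM"
        assert ranked[0][1] > 5 * max(ranked[1][1], 1e-12)

    def test_symmetric_features_attributed_equally(self, rng):
        # EE depends on ca + idc through identical terms on identical axes
        from enzymof.design_space import Axis, enumerate_grid

        grid = enumerate_grid(
            [Axis("ca_mM", 0.0, 100.0, 10.0), Axis("idc_mM", 0.0, 100.0, 10.0),
             Axis.from_levels("enzyme_mg_per_ml", 0.2, 1.8, 3)]
        )
        pts = grid.points()[rng.choice(grid.size, size=60, replace=False)]
        trials = [
            TrialResult(recipe=Recipe(*row), ee=float(np.clip(0.4 * row[0] + 0.4 * row[1], 0, 100)))
            for row in pts
        ]
        sfit = fit(ModelFamily("random_forest"), trials, "EE", seed=0)
        ranked = dict(shap_summary(sfit, trials, seed=0))
        assert ranked["ca_mM"] == pytest.approx(ranked["idc_mM"], rel=0.2)

    def test_three_finite_attributions(self, small_grid, rng):
        trials = _ca_only_trials(small_grid, rng)
        sfit = fit(FAST_RF, trials, "EE", seed=0)
        ranked = shap_summary(sfit, trials, seed=0)
        assert len(ranked) == 3
        assert np.isfinite(sum(v for _, v in ranked))

    def test_requires_ten_trials(self, small_grid, rng):
        trials = _ca_only_trials(small_grid, rng, n=9)
        sfit = fit(FAST_RF, trials, "EE", seed=0)
        with pytest.raises(ValueError):
            shap_summary(sfit, trials)


class TestEmbeddingAndDistribution:
    def _trials(self, grid, rng, n=30):
        pts = grid.points()[rng.choice(grid.size, size=n, replace=False)]
        return [TrialResult(recipe=Recipe(*row), ee=50.0) for row in pts]

    def test_embedding_shape_and_determinism(self, small_grid, rng):
        trials = self._trials(small_grid, rng)
        e1 = tsne_embed(trials, seed=3)
        e2 = tsne_embed(trials, seed=3)
        assert e1.shape == (30, 2)
        assert np.isfinite(e1).all()
        assert np.array_equal(e1, e2)

    def test_too_few_trials_rejected(self, small_grid, rng):
        with pytest.raises(ValueError):
            tsne_embed(self._trials(small_grid, rng, n=4))

    def test_separated_recipe_clusters_stay_separated(self):
        rng = np.random.default_rng(0)
        low = [TrialResult(recipe=Recipe(2 + rng.uniform(0, 4), 25 + rng.uniform(0, 4), 0.2), ee=30.0) for _ in range(12)]
        high = [TrialResult(recipe=Recipe(90 + rng.uniform(0, 4), 115 + rng.uniform(0, 4), 1.9), ee=80.0) for _ in range(12)]
        emb = tsne_embed(low + high, seed=0)
        a, b = emb[:12], emb[12:]
        between = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        within = np.mean([np.linalg.norm(x - a.mean(axis=0)) for x in a] +
                         [np.linalg.norm(x - b.mean(axis=0)) for x in b])
        assert between > within

    def test_distribution_single_trial(self):
        rep = distribution_report([TrialResult(recipe=Recipe(10, 25, 0.2), ee=50.0)], "EE")
        assert rep.minimum == rep.maximum == 50.0
        assert rep.counts.sum() == 1
        assert (rep.counts > 0).sum() == 1

    def test_distribution_range_matches_observed(self):
        trials = [
            TrialResult(recipe=Recipe(10, 25, 0.2), ee=24.9),
            TrialResult(recipe=Recipe(50, 65, 1.0), ee=85.4),
        ]
        rep = distribution_report(trials, "EE")
        assert rep.minimum == 24.9 and rep.maximum == 85.4
        assert rep.best.ee == 85.4

    def test_counts_conserved(self, small_grid, rng):
        trials = self._trials(small_grid, rng, n=25)
        rep = distribution_report(trials, "EE")
        assert rep.counts.sum() == 25
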