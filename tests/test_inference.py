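"""Posterior sampling: oracles, determinism, diagnostics, summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mnartrial.data import TrialDataset
from mnartrial.mcmc import (
    IdentificationWarning,
    McmcConfig,
    PriorSpec,
    SelectionModel,
    UniformPrior,
)
from mnartrial.model import ModelFrame, ModelSpec, mar_spec
from mnartrial.results import SelectionResults, gelman_rubin
from mnartrial.simulate import SimulationParams, simulate_trial


def _no_missing_dataset(n=600, seed=3, effect=2.0):
    p = SimulationParams(
        n_total=n, seed=seed,
        r0_coefs={"const": 20.0},
        y1_coefs={"const": 40.0, "Y0": 6.0, "T": effect},
        r1_coefs={"const": 20.0},
    )
    return simulate_trial(p)[0]


class TestFit:
    def test_posterior_matches_least_squares_without_missing_data(self):
        """With nothing missing and flat priors the treatment-effect posterior
        is centred on the least-squares estimate of the final-score regression."""
        ds = _no_missing_dataset()
        from mnartrial.data import Standardizer

        std0 = Standardizer.from_observed(ds.y0, ds.centre)
        X = np.column_stack(
            [
                np.ones(len(ds)), ds.centre == 2, ds.centre == 3, ds.centre == 4,
                std0.transform(ds.y0), ds.r0, ds.arm,
            ]
        ).astype(float)
        ols = sm.OLS(ds.y1, X).fit()
        res = SelectionModel(ds, mar_spec()).fit(
            McmcConfig(n_chains=2, n_burn=500, n_keep=800, seed=5)
        )
        eff = res.treatment_effect_summary()
        assert eff["mean"] == pytest.approx(ols.params[-1], abs=0.15)
        assert eff["sd"] == pytest.approx(ols.bse[-1], rel=0.2)

    def test_identical_seed_gives_identical_draws(self, mar_dataset):
        cfg = McmcConfig(n_chains=2, n_burn=200, n_keep=200, seed=11)
        r1 = SelectionModel(mar_dataset, mar_spec()).fit(cfg)
        r2 = SelectionModel(mar_dataset, mar_spec()).fit(cfg)
        for name in r1.parameter_names:
            np.testing.assert_array_equal(r1.draws[name], r2.draws[name])
        np.testing.assert_array_equal(r1.imputations["y1"], r2.imputations["y1"])

    def test_point_mass_constraint_held_exactly(self, mar_dataset):
        spec = ModelSpec(fixed_deltas={"delta.Y0.R0": 0.0, "delta.Y1.R1": 0.5})
        res = SelectionModel(mar_dataset, spec).fit(
            McmcConfig(n_chains=2, n_burn=100, n_keep=150, seed=2)
        )
        assert np.all(res.stacked("delta.Y1.R1") == 0.5)
        assert np.all(res.stacked("delta.Y0.R0") == 0.0)

    def test_draw_count_contract(self, mar_dataset):
        cfg = McmcConfig(n_chains=3, n_burn=100, n_keep=200, thin=2, seed=1)
        res = SelectionModel(mar_dataset, mar_spec()).fit(cfg)
        assert res.n_draws == 3 * 100
        assert np.asarray(res.imputations["y1"]).shape[:2] == (3, 100)

    def test_unconstrained_model_warns_about_identification(self, mar_dataset):
        with pytest.warns(IdentificationWarning):
            SelectionModel(mar_dataset, ModelSpec())

    def test_mar_credible_intervals_cover_truth(self):
        """Scaled-down coverage study: nominal 95% intervals on MAR data."""
        cover, reps = 0, 30
        for rep in range(reps):
            p = SimulationParams(
                n_total=150, seed=1000 + rep,
                r0_coefs={"const": 2.5},
                y1_coefs={"const": 40.0, "Y0": 6.0, "T": 2.0},
                r1_coefs={"const": 2.0},
            )
            ds, _ = simulate_trial(p)
            res = SelectionModel(ds, mar_spec()).fit(
                McmcConfig(n_chains=2, n_burn=300, n_keep=500, seed=rep)
            )
            lo, hi = res.treatment_effect_summary()["ci"]
            cover += lo <= 2.0 <= hi
        assert cover >= 24  # binomial slack below the nominal 28.5/30


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(500)
        # identical chains have no between-chain variance; the statistic sits
        # at its floor sqrt((n-1)/n), i.e. 1 up to O(1/n)
        assert gelman_rubin(np.stack([row, row])) == pytest.approx(1.0, abs=5e-3)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(400)
        assert gelman_rubin(np.stack([a, a + 50])) > 10

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        chains = rng.standard_normal((4, 500))
        m, n = chains.shape
        # explicit loop implementation of the between/within formula
        means = [chains[j].mean() for j in range(m)]
        grand = np.mean(means)
        B = n / (m - 1) * sum((mu - grand) ** 2 for mu in means)
        W = np.mean([chains[j].var(ddof=1) for j in range(m)])
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-8)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


def _manual_results(draws, imputations=None, dataset=None, frame=None):
    return SelectionResults(
        draws=draws,
        imputations=imputations or {},
        dataset=dataset,
        spec=None,
        priors=None,
        mcmc=None,
        frame=frame,
    )


class TestSummaries:
    def test_degenerate_posterior(self):
        res = _manual_results({"delta.T.Y1": np.full((2, 50), 3.25)})
        out = res.treatment_effect_summary()
        assert out == {"mean": 3.25, "sd": 0.0, "ci": (3.25, 3.25)}

    def test_summary_matches_quantile_oracle(self):
        rng = np.random.default_rng(12)
        draws = rng.standard_normal((4, 250)) * 1.3 - 0.4
        res = _manual_results({"delta.T.Y1": draws})
        out = res.treatment_effect_summary()
        pooled = draws.reshape(-1)
        assert out["mean"] == pytest.approx(pooled.mean())
        assert out["ci"][0] == pytest.approx(np.percentile(pooled, 2.5))
        assert out["ci"][1] == pytest.approx(np.percentile(pooled, 97.5))
        assert out["ci"][0] < out["mean"] < out["ci"][1]

    def test_delta_zero_when_imputations_equal_observed_mean(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "d"],
                "centre": [1, 1, 2, 2],
                "arm": [1, 1, 1, 0],
                "y0": [38.0, 40.0, 42.0, 39.0],
                "y1": [40.0, 44.0, np.nan, 41.0],
            }
        )
        ds = TrialDataset(df)
        frame = ModelFrame(ds, mar_spec())
        obs_mean = 42.0  # mean of observed intervention-arm y1
        imps = {"y1": np.full((2, 10, 1), obs_mean)}
        res = _manual_results({"delta.T.Y1": np.zeros((2, 10))}, imps, ds, frame)
        out = res.delta_missing_minus_observed(arm=1)
        assert out["mean"] == pytest.approx(0.0)
        assert out["sd"] == 0.0

    def test_delta_requires_missing_scores_in_arm(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "d"],
                "centre": [1, 1, 1, 1],
                "arm": [1, 1, 0, 0],
                "y0": [38.0, 40.0, 41.0, 37.0],
                "y1": [40.0, 43.0, 39.0, np.nan],
            }
        )
        ds = TrialDataset(df)
        frame = ModelFrame(ds, mar_spec())
        res = _manual_results({"delta.T.Y1": np.zeros((2, 5))}, {"y1": np.zeros((2, 5, 1))}, ds, frame)
        with pytest.raises(ValueError):
            res.delta_missing_minus_observed(arm=1)

    def test_draws_frame_export_round_trip(self, tmp_path, mar_dataset):
        res = SelectionModel(mar_dataset, mar_spec()).fit(
            McmcConfig(n_chains=2, n_burn=100, n_keep=100, seed=6)
        )
        path = tmp_path / "draws.csv"
        res.to_csv(path)
        back = pd.read_csv(path)
        assert len(back) == res.n_draws
        np.testing.assert_allclose(back["delta.T.Y1"], res.stacked("delta.T.Y1"))


class TestPriors:
    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            UniformPrior(2.0, 1.0)
        with pytest.raises(ValueError):
            PriorSpec(precision_shape=0.0)

    def test_with_normal_builder(self):
        pr = PriorSpec().with_normal(delta_Y1_R1=(0.25, 0.3))
        prior = pr.for_name("delta.Y1.R1")
        assert prior.mean == 0.25 and prior.variance == 0.3
        assert isinstance(pr.for_name("delta.Y0.R0"), UniformPrior)
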