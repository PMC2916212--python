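"""Joint model likelihood, linear predictors, attempts model, conversions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mnartrial.data import Standardizer, TrialDataset, TrialRecord
from mnartrial.model import (
    ConversionInputs,
    ImputedRecord,
    MissingCovariateError,
    ModelFrame,
    ModelSpec,
    attempt_success_probability,
    complete_data_loglik,
    linear_predictor,
    mar_spec,
    pattern_mixture_to_selection,
    selection_to_pattern_mixture,
)


def _small_dataset(n=20, seed=5, with_attempts=False, all_observed=False):
    rng = np.random.default_rng(seed)
    y0 = 39 + 11 * rng.standard_normal(n)
    y1 = 41 + 12 * rng.standard_normal(n)
    r0 = np.ones(n, int) if all_observed else (rng.random(n) < 0.85).astype(int)
    r1 = np.ones(n, int) if all_observed else (rng.random(n) < 0.8).astype(int)
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "centre": rng.integers(1, 5, n),
            "arm": rng.integers(0, 2, n),
            "y0": np.where(r0 == 1, y0, np.nan),
            "y1": np.where(r1 == 1, y1, np.nan),
        }
    )
    attempts = None
    if with_attempts:
        rows = []
        for i in range(n):
            k = int(rng.integers(1, 4))
            if r1[i] == 1:
                for m in range(1, k + 1):
                    rows.append((f"p{i}", m, int(rng.integers(0, 2)), int(m == k)))
            else:
                for m in range(1, k + 1):
                    rows.append((f"p{i}", m, int(rng.integers(0, 2)), 0))
        attempts = pd.DataFrame(rows, columns=["participant_id", "m", "attempt_type", "success"])
    return TrialDataset(df, attempts), {"y0": y0, "y1": y1}


def _full_params(frame, rng):
    params = {}
    for f in frame.factor_names:
        for nm in frame.coef_names(f):
            params[nm] = float(rng.normal(scale=0.4))
    params["beta.Y0.const"] = 39.0
    if "Y1" in frame.factor_names:
        params["beta.Y1.const"] = 41.0
    params["sigma2.Y0"] = 121.0
    params["sigma2.Y1"] = 144.0
    if frame.spec.use_proxy:
        params["beta.Z.const"] = 20.0
        params["sigma2.Z"] = 36.0
    return params


class TestLinearPredictor:
    def test_all_zero_and_intercept_only(self):
        rec = TrialRecord("a", centre=2, arm=1, y0=40.0, y1=45.0)
        std = {"Y0": Standardizer(39, 11), "Y1": Standardizer(41, 12)}
        assert linear_predictor({}, rec, std) == 0.0
        assert linear_predictor({"const": 2.5}, rec, std) == 2.5

    def test_matches_brute_force_dot_product(self):
        rng = np.random.default_rng(7)
        std = {"Y0": Standardizer(39, 11), "Y1": Standardizer(41, 12)}
        for _ in range(20):
            rec = TrialRecord(
                "a",
                centre=int(rng.integers(1, 5)),
                arm=int(rng.integers(0, 2)),
                y0=float(rng.normal(39, 11)),
                y1=float(rng.normal(41, 12)),
            )
            coefs = {
                "const": rng.normal(),
                "centre2": rng.normal(),
                "centre3": rng.normal(),
                "T": rng.normal(),
                "R0": rng.normal(),
                "Y0": rng.normal(),
                "Y1": rng.normal(),
            }
            expected = (
                coefs["const"]
                + coefs["centre2"] * (rec.centre == 2)
                + coefs["centre3"] * (rec.centre == 3)
                + coefs["T"] * rec.arm
                + coefs["R0"] * rec.r0
                + coefs["Y0"] * (rec.y0 - 39) / 11
                + coefs["Y1"] * (rec.y1 - 41) / 12
            )
            assert linear_predictor(coefs, rec, std) == pytest.approx(expected)

    def test_missing_covariate_without_imputation_raises(self):
        rec = TrialRecord("a", centre=1, arm=0, y0=None, y1=41.0)
        std = {"Y0": Standardizer(39, 11), "Y1": Standardizer(41, 12)}
        with pytest.raises(MissingCovariateError):
            linear_predictor({"Y0": 1.0}, rec, std)
        imputed = ImputedRecord(rec, y0=39.0)
        assert linear_predictor({"Y0": 1.0}, imputed, std) == pytest.approx(0.0)
        assert imputed.r0 == 0  # indicator reflects the original missingness


class TestCompleteDataLoglik:
    def test_zero_logistic_coefs_give_log_half_per_indicator(self):
        ds, truth = _small_dataset(n=6, all_observed=True)
        frame = ModelFrame(ds, ModelSpec())
        params = {nm: 0.0 for f in frame.factor_names for nm in frame.coef_names(f)}
        params.update(
            {"beta.Y0.const": 39.0, "beta.Y1.const": 41.0, "sigma2.Y0": 121.0, "sigma2.Y1": 144.0}
        )
        ll = complete_data_loglik(params, ds, ModelSpec())
        normal_part = stats.norm.logpdf(ds.y0, 39.0, 11.0).sum() + stats.norm.logpdf(
            ds.y1, 41.0, 12.0
        ).sum()
        assert ll == pytest.approx(normal_part + 2 * 6 * math.log(0.5))

    def test_matches_factor_by_factor_oracle(self):
        """Sum of per-record, per-factor densities computed independently."""
        ds, truth = _small_dataset(n=20, seed=11)
        spec = ModelSpec()
        frame = ModelFrame(ds, spec)
        rng = np.random.default_rng(3)
        params = _full_params(frame, rng)
        imps = {
            "y0": truth["y0"][frame.mis_y0],
            "y1": truth["y1"][frame.mis_y1],
        }
        ll = complete_data_loglik(params, ds, spec, imps)

        std = frame.std
        total = 0.0
        for rec in ds.records():
            filled = ImputedRecord(
                rec,
                y0=rec.y0 if rec.y0 is not None else truth["y0"][int(rec.participant_id[1:])],
                y1=rec.y1 if rec.y1 is not None else truth["y1"][int(rec.participant_id[1:])],
            )
            mu0 = linear_predictor(
                {
                    "const": params["beta.Y0.const"],
                    "centre2": params["beta.Y0.centre2"],
                    "centre3": params["beta.Y0.centre3"],
                    "centre4": params["beta.Y0.centre4"],
                },
                filled,
                std,
            )
            total += stats.norm.logpdf(filled.y0, mu0, math.sqrt(params["sigma2.Y0"]))
            eta0 = linear_predictor(
                {
                    "const": params["beta.R0.const"],
                    "centre2": params["beta.R0.centre2"],
                    "centre3": params["beta.R0.centre3"],
                    "centre4": params["beta.R0.centre4"],
                    "Y0": params["delta.Y0.R0"],
                },
                filled,
                std,
            )
            total += stats.bernoulli.logpmf(rec.r0, 1 / (1 + math.exp(-eta0)))
            mu1 = linear_predictor(
                {
                    "const": params["beta.Y1.const"],
                    "centre2": params["beta.Y1.centre2"],
                    "centre3": params["beta.Y1.centre3"],
                    "centre4": params["beta.Y1.centre4"],
                    "Y0": params["delta.Y0.Y1"],
                    "R0": params["delta.R0.Y1"],
                    "T": params["delta.T.Y1"],
                },
                filled,
                std,
            )
            total += stats.norm.logpdf(filled.y1, mu1, math.sqrt(params["sigma2.Y1"]))
            eta1 = linear_predictor(
                {
                    "const": params["beta.R1.const"],
                    "centre2": params["beta.R1.centre2"],
                    "centre3": params["beta.R1.centre3"],
                    "centre4": params["beta.R1.centre4"],
                    "Y0": params["delta.Y0.R1"],
                    "R0": params["delta.R0.R1"],
                    "T": params["delta.T.R1"],
                    "Y1": params["delta.Y1.R1"],
                },
                filled,
                std,
            )
            total += stats.bernoulli.logpmf(rec.r1, 1 / (1 + math.exp(-eta1)))
        assert ll == pytest.approx(total, rel=1e-10)

    def test_t_family_approaches_normal_for_large_df(self):
        ds, truth = _small_dataset(n=15, seed=2)
        spec_n = ModelSpec()
        frame = ModelFrame(ds, spec_n)
        params = _full_params(frame, np.random.default_rng(1))
        imps = {"y0": truth["y0"][frame.mis_y0], "y1": truth["y1"][frame.mis_y1]}
        ll_normal = complete_data_loglik(params, ds, spec_n, imps)
        ll_t = complete_data_loglik(params, ds, ModelSpec(y1_family="t", y1_df=1e6), imps)
        assert ll_t == pytest.approx(ll_normal, abs=1e-4)

    def test_selection_factors_invariant_to_imputations_under_mar_constraints(self):
        """With score coefficients zeroed in the selection regressions, the
        indicator factors do not move when imputations are perturbed."""
        ds, truth = _small_dataset(n=25, seed=13)
        spec = mar_spec()
        frame = ModelFrame(ds, spec)
        params = _full_params(frame, np.random.default_rng(8))
        for nm in ("delta.Y0.R0", "delta.Y0.R1", "delta.R0.Y1", "delta.Y1.R1"):
            params[nm] = 0.0
        fill_a = frame.fill(truth["y0"][frame.mis_y0], truth["y1"][frame.mis_y1])
        fill_b = frame.fill(
            truth["y0"][frame.mis_y0] + 7.0, truth["y1"][frame.mis_y1] - 9.0
        )
        for f in ("R0", "R1"):
            assert frame.factor_loglik(f, params, fill_a) == pytest.approx(
                frame.factor_loglik(f, params, fill_b)
            )
        # ... while the score factors do move
        assert frame.factor_loglik("Y1", params, fill_a) != pytest.approx(
            frame.factor_loglik("Y1", params, fill_b)
        )


class TestAttemptsModel:
    def test_all_slopes_zero_gives_inverse_logit_alpha(self):
        spec = ModelSpec(use_attempts=True)
        rec = TrialRecord("a", centre=3, arm=1, y0=39.0, y1=41.0)
        std = {"Y0": Standardizer(39, 11), "Y1": Standardizer(41, 12)}
        params = {f"alpha.m{m}": 0.7 * m for m in range(1, 10)}
        for m in (1, 5, 9):
            p = attempt_success_probability(m, rec, params, spec, std)
            assert p == pytest.approx(1 / (1 + math.exp(-0.7 * m)))

    def test_attempt_index_enters_only_through_intercept(self):
        spec = ModelSpec(use_attempts=True, attempts_centre_by_attempt=False)
        rec = TrialRecord("a", centre=2, arm=1, y0=45.0, y1=30.0)
        std = {"Y0": Standardizer(39, 11), "Y1": Standardizer(41, 12)}
        params = {f"alpha.m{m}": 0.0 for m in range(1, 10)}
        params.update({"gamma.T": 0.4, "gamma.Y0": 0.2, "delta.Y1.Rstar": 0.5, "gamma.centre2": 0.3})
        probs = [attempt_success_probability(m, rec, params, spec, std) for m in (4, 7)]
        assert probs[0] == pytest.approx(probs[1])

    def test_out_of_range_attempt_rejected(self):
        spec = ModelSpec(use_attempts=True)
        rec = TrialRecord("a", centre=1, arm=0, y0=39.0, y1=41.0)
        std = {"Y0": Standardizer(39, 11), "Y1": Standardizer(41, 12)}
        with pytest.raises(ValueError):
            attempt_success_probability(10, rec, {}, spec, std)

    def test_matches_brute_force_logistic(self):
        spec = ModelSpec(use_attempts=True, attempts_arm_interaction=True)
        rng = np.random.default_rng(4)
        std = {"Y0": Standardizer(39, 11), "Y1": Standardizer(41, 12)}
        params = {f"alpha.m{m}": float(rng.normal()) for m in range(1, 10)}
        for nm in (
            "gamma.type", "gamma.centre2", "gamma.centre3", "gamma.centre4",
            "gamma.centre2.m2", "gamma.centre3.m2", "gamma.centre4.m2",
            "gamma.centre2.m3", "gamma.centre3.m3", "gamma.centre4.m3",
            "gamma.T", "gamma.Y0", "delta.Y1.Rstar", "delta.T.Y1.Rstar",
        ):
            params[nm] = float(rng.normal())
        for m in (1, 2, 3, 4):
            rec = TrialRecord(
                "a", centre=int(rng.integers(1, 5)), arm=int(rng.integers(0, 2)),
                y0=float(rng.normal(39, 11)), y1=float(rng.normal(41, 12)),
            )
            at = int(rng.integers(0, 2))
            eta = params[f"alpha.m{m}"] + params["gamma.type"] * at
            for c in (2, 3, 4):
                if rec.centre == c:
                    eta += params[f"gamma.centre{c}"]
                    if m in (2, 3):
                        eta += params[f"gamma.centre{c}.m{m}"]
            ys0 = (rec.y0 - 39) / 11
            ys1 = (rec.y1 - 41) / 12
            eta += params["gamma.T"] * rec.arm + params["gamma.Y0"] * ys0
            eta += params["delta.Y1.Rstar"] * ys1 + params["delta.T.Y1.Rstar"] * rec.arm * ys1
            expected = 1 / (1 + math.exp(-eta))
            assert attempt_success_probability(
                m, rec, params, spec, std, attempt_type=at
            ) == pytest.approx(expected)

    def test_one_attempt_likelihood_reduces_to_single_logistic(self):
        """With exactly one attempt per participant, the attempts factor
        equals the single-logistic R1 factor at matched coefficients."""
        ds, truth = _small_dataset(n=30, seed=17, with_attempts=False)
        # one attempt per participant, success iff final score observed
        attempts = pd.DataFrame(
            {
                "participant_id": ds.participants["participant_id"],
                "m": 1,
                "attempt_type": 0,
                "success": ds.r1,
            }
        )
        ds1 = TrialDataset(ds.participants, attempts)
        rng = np.random.default_rng(9)
        common = {
            "const": 0.4, "centre2": -0.2, "centre3": 0.3, "centre4": 0.1,
            "Y0": 0.25, "T": -0.5, "Y1": 0.6,
        }
        frame_att = ModelFrame(ds1, ModelSpec(use_attempts=True, max_attempts=1))
        frame_log = ModelFrame(ds1, ModelSpec())
        imps = {"y0": truth["y0"][frame_att.mis_y0], "y1": truth["y1"][frame_att.mis_y1]}
        fill = frame_att.fill(imps["y0"], imps["y1"])
        params_att = {
            "alpha.m1": common["const"], "gamma.type": 0.0,
            "gamma.centre2": common["centre2"], "gamma.centre3": common["centre3"],
            "gamma.centre4": common["centre4"], "gamma.T": common["T"],
            "gamma.Y0": common["Y0"], "delta.Y1.Rstar": common["Y1"],
        }
        params_log = {
            "beta.R1.const": common["const"], "beta.R1.centre2": common["centre2"],
            "beta.R1.centre3": common["centre3"], "beta.R1.centre4": common["centre4"],
            "delta.Y0.R1": common["Y0"], "delta.R0.R1": 0.0, "delta.T.R1": common["T"],
            "delta.Y1.R1": common["Y1"],
        }
        ll_att = frame_att.factor_loglik("ATT", params_att, fill)
        ll_log = frame_log.factor_loglik("R1", params_log, frame_log.fill(imps["y0"], imps["y1"]))
        assert ll_att == pytest.approx(ll_log, rel=1e-12)


class TestConversion:
    def test_zero_difference_gives_zero_slope(self):
        b, b_sd = pattern_mixture_to_selection(ConversionInputs(40.0, 40.0, 10.0))
        assert b == 0.0 and b_sd == 0.0

    def test_published_reference_case(self):
        # mean difference 2.5 at SD 10 corresponds to a per-SD slope of 0.25
        b, b_sd = pattern_mixture_to_selection(ConversionInputs(40.0, 37.5, 10.0))
        assert b_sd == pytest.approx(0.25)

    @given(
        st.floats(-20, 20),
        st.floats(-20, 20),
        st.floats(0.5, 30),
    )
    def test_round_trip_bijection(self, mu_o, mu_m, sigma):
        b, _ = pattern_mixture_to_selection(ConversionInputs(mu_o, mu_m, sigma))
        diff = selection_to_pattern_mixture(b, sigma)
        assert diff == pytest.approx(mu_o - mu_m, abs=1e-10)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            ConversionInputs(40.0, 39.0, 0.0)
        with pytest.raises(ValueError):
            selection_to_pattern_mixture(0.1, -1.0)


class TestModelSpec:
    def test_conflicting_constraints_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(arm_specific_outcome_selection=True, fixed_deltas={"delta.Y1.R1": 0.5})
        with pytest.raises(ValueError):
            ModelSpec(use_attempts=True, fixed_deltas={"delta.Y1.R1": 0.0})

    def test_serialization_round_trip(self):
        spec = ModelSpec(
            fixed_deltas={"delta.Y0.R0": 0.0, "delta.Y1.R1": 0.5},
            y1_family="t",
            y1_df=10,
            use_proxy=True,
        )
        assert ModelSpec.from_dict(spec.to_dict()) == spec
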