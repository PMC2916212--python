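"""Joint selection model for a two-arm trial with missing continuous outcomes.

The model follows the conditional factorization along the trial DAG:
centre X, baseline score Y0, its response indicator R0, randomized arm T,
final score Y1, its response indicator R1, and optionally the carer proxy
score Z with indicator R_Z. Scores are modelled with normal (or scaled-t)
linear regressions and indicators with logistic regressions; each variable is
conditioned on all earlier variables in the list (T is independent of earlier
variables by randomization). Because the selection regressions include the
possibly-unobserved scores as covariates, the model is MNAR in general; the
coefficient of a score A in the regression for B is written ``delta.A.B``
and the outcome-selection coefficients (e.g. ``delta.Y1.R1``) are the
sensitivity parameters.

Score covariates always enter the regressions standardized (observed-data
mean, within-centre pooled SD), so selection coefficients are log-odds per
SD of score.

The repeated-attempts extension replaces the single R1 logistic arc with a
shared-coefficient logistic model for success at each contact attempt m,
whose intercepts alpha_m vary freely with m while every slope is common
across attempts — the "continuum of resistance" identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .data import Standardizer, TrialDataset, TrialRecord

__all__ = [
    "ModelSpec",
    "ModelFrame",
    "ConversionInputs",
    "ImputedRecord",
    "MissingCovariateError",
    "linear_predictor",
    "complete_data_loglik",
    "attempt_success_probability",
    "pattern_mixture_to_selection",
    "selection_to_pattern_mixture",
    "mar_spec",
]

CENTRE_DUMMIES = ("centre2", "centre3", "centre4")


class MissingCovariateError(RuntimeError):
    """A regression covariate is missing and no imputation was supplied."""


@dataclass(frozen=True)
class ModelSpec:
    """Which coefficients are fixed, free or arm-specific, and which model arcs are on.

    Parameters
    ----------
    fixed_deltas
        Map from coefficient name (``delta.A.B`` convention) to the fixed
        value used as a sensitivity constraint, e.g. ``{"delta.Y1.R1": 0.5}``.
    arm_specific_outcome_selection
        Replace ``delta.Y1.R1`` by the pair ``delta.Y1.R1.T`` (intervention)
        and ``delta.Y1.R1.C`` (control).
    y1_family, y1_df
        ``"normal"`` or ``"t"``; for the t family ``y1_df`` fixes the degrees
        of freedom (never estimated) and the scale is calibrated so
        ``sigma2.Y1`` remains the variance.
    use_proxy
        Include the Z and R_Z regressions.
    use_attempts
        Replace the single R1 logistic arc with the repeated-attempts model.
    attempts_arm_interaction
        Include the arm-by-final-score interaction in the attempts model.
    attempts_centre_by_attempt
        Include centre-by-attempt-index dummies, truncated at attempt 3.
    max_attempts
        Largest permitted attempt index (at most 9).
    """

    fixed_deltas: Mapping[str, float] = field(default_factory=dict)
    arm_specific_outcome_selection: bool = False
    y1_family: str = "normal"
    y1_df: float = math.inf
    use_proxy: bool = False
    use_attempts: bool = False
    attempts_arm_interaction: bool = False
    attempts_centre_by_attempt: bool = True
    max_attempts: int = 9

    def __post_init__(self):
        if self.y1_family not in ("normal", "t"):
            raise ValueError("y1_family must be 'normal' or 't'")
        if self.y1_family == "t" and not self.y1_df > 2:
            raise ValueError("t family requires y1_df > 2 for a finite variance")
        if not 1 <= self.max_attempts <= 9:
            raise ValueError("max_attempts must lie in 1..9")
        fixed = dict(self.fixed_deltas)
        if self.arm_specific_outcome_selection and "delta.Y1.R1" in fixed:
            raise ValueError(
                "delta.Y1.R1 cannot be fixed when the outcome-selection "
                "coefficient is arm-specific; fix delta.Y1.R1.T / delta.Y1.R1.C"
            )
        if self.use_attempts and any(
            k in fixed for k in ("delta.Y1.R1", "delta.Y1.R1.T", "delta.Y1.R1.C")
        ):
            raise ValueError(
                "the repeated-attempts model replaces the R1 arc; "
                "fixing delta.Y1.R1 is meaningless under use_attempts"
            )
        object.__setattr__(self, "fixed_deltas", fixed)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fixed_deltas": dict(self.fixed_deltas),
            "arm_specific_outcome_selection": self.arm_specific_outcome_selection,
            "y1_family": self.y1_family,
            "y1_df": None if math.isinf(self.y1_df) else self.y1_df,
            "use_proxy": self.use_proxy,
            "use_attempts": self.use_attempts,
            "attempts_arm_interaction": self.attempts_arm_interaction,
            "attempts_centre_by_attempt": self.attempts_centre_by_attempt,
            "max_attempts": self.max_attempts,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        d = dict(d)
        if d.get("y1_df") is None:
            d["y1_df"] = math.inf
        return cls(**d)

    def with_fixed(self, **deltas: float) -> "ModelSpec":
        """Return a copy with additional fixed coefficients (dotted names use _ for .)."""
        fixed = dict(self.fixed_deltas)
        fixed.update({k.replace("_", "."): v for k, v in deltas.items()})
        return replace(self, fixed_deltas=fixed)


def mar_spec(use_proxy: bool = False) -> ModelSpec:
    """The MAR-constrained specification.

    Scores are conditionally independent of the response indicators:
    delta.Y0.R0 = delta.Y0.R1 = delta.R0.Y1 = delta.Y1.R1 = 0 (and, with
    proxies, every score coefficient in the R_Z regression and every
    indicator coefficient in the score regressions involving Z is 0).
    """
    fixed = {
        "delta.Y0.R0": 0.0,
        "delta.Y0.R1": 0.0,
        "delta.R0.Y1": 0.0,
        "delta.Y1.R1": 0.0,
    }
    if use_proxy:
        fixed.update(
            {
                "delta.R0.Z": 0.0,
                "delta.R1.Z": 0.0,
                "delta.Y0.RZ": 0.0,
                "delta.Y1.RZ": 0.0,
                "delta.Z.RZ": 0.0,
            }
        )
    return ModelSpec(fixed_deltas=fixed, use_proxy=use_proxy)


# -- factor structure ----------------------------------------------------


def _centre_cols(centre: np.ndarray) -> np.ndarray:
    return np.column_stack([(centre == c).astype(float) for c in (2, 3, 4)])


@dataclass(frozen=True)
class ConversionInputs:
    """Inputs of the equal-variance two-pattern normal conversion.

    ``mu_o`` and ``mu_m`` are the observed- and missing-pattern means and
    ``sigma`` the common SD.
    """

    mu_o: float
    mu_m: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


def pattern_mixture_to_selection(c: ConversionInputs) -> tuple[float, float]:
    """Convert a two-pattern normal mean difference to the selection-logit slope.

    Under the equal-variance normal pattern-mixture model the log-odds of
    being observed is linear in y with slope b = (mu_o - mu_m)/sigma^2.
    Returns ``(b, b * sigma)``: the slope per raw unit and per SD of y.
    """
    b = (c.mu_o - c.mu_m) / c.sigma**2
    return b, b * c.sigma


def selection_to_pattern_mixture(
    b: float, sigma: float, response_prob: float | None = None
) -> float:
    """Mean difference mu_o - mu_m implied by a raw-unit selection slope b.

    Inverse of :func:`pattern_mixture_to_selection` under the equal-variance
    two-pattern normal model: mu_o - mu_m = b * sigma^2. The marginal
    response probability is accepted for interface completeness but does not
    enter the equal-variance identity.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    return b * sigma**2


# -- record-level linear predictor ---------------------------------------


@dataclass
class ImputedRecord:
    """A trial record with imputations filled in but original indicators kept."""

    base: TrialRecord
    y0: float | None = None
    y1: float | None = None
    z: float | None = None

    def __post_init__(self):
        if self.y0 is None:
            self.y0 = self.base.y0
        if self.y1 is None:
            self.y1 = self.base.y1
        if self.z is None:
            self.z = self.base.z

    @property
    def centre(self):
        return self.base.centre

    @property
    def arm(self):
        return self.base.arm

    @property
    def r0(self):
        return self.base.r0

    @property
    def r1(self):
        return self.base.r1

    @property
    def rz(self):
        return self.base.rz

    @property
    def attempts(self):
        return self.base.attempts


def _covariate_value(name: str, record, standardizers: Mapping[str, Standardizer]):
    """Value of one named covariate on a record, standardizing scores."""
    if name == "const":
        return 1.0
    if name in CENTRE_DUMMIES:
        return float(record.centre == int(name[-1]))
    if name == "T":
        return float(record.arm)
    if name in ("R0", "R1", "RZ"):
        return float(getattr(record, name.lower()))
    if name in ("Y0", "Y1", "Z"):
        val = getattr(record, name.lower() if name != "Z" else "z")
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise MissingCovariateError(
                f"covariate {name} is missing and no imputation was supplied"
            )
        return float(standardizers[name].transform([val])[0])
    raise KeyError(f"unknown covariate {name!r}")


def linear_predictor(
    coefs: Mapping[str, float],
    record,
    standardizers: Mapping[str, Standardizer],
) -> float:
    """Sum of coefficient times covariate for one record.

    ``coefs`` maps covariate names (``const``, ``centre2..4``, ``T``,
    ``R0``/``R1``/``RZ``, ``Y0``/``Y1``/``Z``) to coefficients; score
    covariates are passed through the frozen standardizers.
    """
    return float(
        sum(
            coef * _covariate_value(name, record, standardizers)
            for name, coef in coefs.items()
        )
    )


# -- vectorized frame ----------------------------------------------------


class ModelFrame:
    """Precomputed arrays and coefficient bookkeeping for a dataset + spec.

    The frame freezes the observed-data standardizers, builds centre dummies
    and (for the attempts model) the long-format attempt arrays, and exposes
    per-factor design matrices as functions of the currently filled score
    vectors. Both the likelihood evaluator and the MCMC sampler are built on
    it, so the model is defined in exactly one place.
    """

    def __init__(self, dataset: TrialDataset, spec: ModelSpec):
        self.dataset = dataset
        self.spec = spec
        n = len(dataset)
        self.n = n
        self.centre = dataset.centre
        self.C = _centre_cols(self.centre)
        self.t = dataset.arm.astype(float)
        self.r0 = dataset.r0.astype(float)
        self.r1 = dataset.r1.astype(float)
        self.rz = dataset.rz.astype(float)
        self.y0_obs = dataset.y0
        self.y1_obs = dataset.y1
        self.z_obs = dataset.z
        self.mis_y0 = np.flatnonzero(np.isnan(self.y0_obs))
        self.mis_y1 = np.flatnonzero(np.isnan(self.y1_obs))
        self.mis_z = np.flatnonzero(np.isnan(self.z_obs)) if spec.use_proxy else np.array([], int)

        self.std = {
            "Y0": Standardizer.from_observed(self.y0_obs, self.centre),
            "Y1": Standardizer.from_observed(self.y1_obs, self.centre),
        }
        if spec.use_proxy:
            if not dataset.has_proxy:
                raise ValueError("spec.use_proxy but the dataset has no proxy scores")
            self.std["Z"] = Standardizer.from_observed(self.z_obs, self.centre)

        if spec.use_attempts:
            if not dataset.has_attempts:
                raise ValueError("spec.use_attempts but the dataset has no attempt records")
            att = dataset.attempts
            pid_to_row = {
                pid: i for i, pid in enumerate(dataset.participants["participant_id"])
            }
            self.att_row = att["participant_id"].map(pid_to_row).to_numpy(int)
            self.att_m = att["m"].to_numpy(int)
            if self.att_m.max() > spec.max_attempts:
                raise ValueError(
                    f"attempt index {self.att_m.max()} exceeds max_attempts={spec.max_attempts}"
                )
            self.att_type = att["attempt_type"].to_numpy(float)
            self.att_success = att["success"].to_numpy(float)
            self.n_alpha = int(self.att_m.max())

        self._coef_names = self._build_coef_names()

    # -- coefficient names ----------------------------------------------

    def _build_coef_names(self) -> dict[str, list[str]]:
        spec = self.spec
        base = ["const", *CENTRE_DUMMIES]
        names: dict[str, list[str]] = {}
        names["Y0"] = [f"beta.Y0.{c}" for c in base]
        names["R0"] = [f"beta.R0.{c}" for c in base] + ["delta.Y0.R0"]
        names["Y1"] = [f"beta.Y1.{c}" for c in base] + [
            "delta.Y0.Y1",
            "delta.R0.Y1",
            "delta.T.Y1",
        ]
        if spec.use_attempts:
            att = [f"alpha.m{m}" for m in range(1, self.n_alpha + 1)]
            att += ["gamma.type", "gamma.centre2", "gamma.centre3", "gamma.centre4"]
            if spec.attempts_centre_by_attempt:
                for m in (2, 3):
                    if m <= self.n_alpha:
                        att += [f"gamma.centre{c}.m{m}" for c in (2, 3, 4)]
            att += ["gamma.T", "gamma.Y0", "delta.Y1.Rstar"]
            if spec.attempts_arm_interaction:
                att += ["delta.T.Y1.Rstar"]
            names["ATT"] = att
        else:
            r1 = [f"beta.R1.{c}" for c in base] + [
                "delta.Y0.R1",
                "delta.R0.R1",
                "delta.T.R1",
            ]
            if spec.arm_specific_outcome_selection:
                r1 += ["delta.Y1.R1.T", "delta.Y1.R1.C"]
            else:
                r1 += ["delta.Y1.R1"]
            names["R1"] = r1
        if spec.use_proxy:
            names["Z"] = [f"beta.Z.{c}" for c in base] + [
                "delta.Y0.Z",
                "delta.R0.Z",
                "delta.T.Z",
                "delta.Y1.Z",
                "delta.R1.Z",
            ]
            names["RZ"] = [f"beta.RZ.{c}" for c in base] + [
                "delta.Y0.RZ",
                "delta.R0.RZ",
                "delta.T.RZ",
                "delta.Y1.RZ",
                "delta.R1.RZ",
                "delta.Z.RZ",
            ]
        return names

    @property
    def factor_names(self) -> list[str]:
        return list(self._coef_names)

    def coef_names(self, factor: str) -> list[str]:
        return list(self._coef_names[factor])

    def all_parameter_names(self) -> list[str]:
        out: list[str] = []
        for f in self.factor_names:
            out.extend(self._coef_names[f])
        out.append("sigma2.Y0")
        out.append("sigma2.Y1")
        if self.spec.use_proxy:
            out.append("sigma2.Z")
        return out

    # -- filled values ---------------------------------------------------

    def fill(
        self,
        y0_mis: np.ndarray | None = None,
        y1_mis: np.ndarray | None = None,
        z_mis: np.ndarray | None = None,
    ) -> dict[str, np.ndarray]:
        """Full-length score vectors with imputations substituted for NaNs."""
        y0 = self.y0_obs.copy()
        y1 = self.y1_obs.copy()
        z = self.z_obs.copy()
        if len(self.mis_y0):
            if y0_mis is None:
                raise MissingCovariateError("y0 imputations required")
            y0[self.mis_y0] = y0_mis
        if len(self.mis_y1):
            if y1_mis is None:
                raise MissingCovariateError("y1 imputations required")
            y1[self.mis_y1] = y1_mis
        if self.spec.use_proxy and len(self.mis_z):
            if z_mis is None:
                raise MissingCovariateError("z imputations required")
            z[self.mis_z] = z_mis
        return {"y0": y0, "y1": y1, "z": z}

    # -- design matrices -------------------------------------------------

    def design(self, factor: str, filled: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """(X, response) for one factor at the current filled score vectors."""
        ys0 = self.std["Y0"].transform(filled["y0"])
        const = np.ones(self.n)
        if factor == "Y0":
            return np.column_stack([const, self.C]), filled["y0"]
        if factor == "R0":
            return np.column_stack([const, self.C, ys0]), self.r0
        if factor == "Y1":
            return (
                np.column_stack([const, self.C, ys0, self.r0, self.t]),
                filled["y1"],
            )
        ys1 = self.std["Y1"].transform(filled["y1"])
        if factor == "R1":
            cols = [const, self.C, ys0, self.r0, self.t]
            if self.spec.arm_specific_outcome_selection:
                cols += [self.t * ys1, (1.0 - self.t) * ys1]
            else:
                cols += [ys1]
            return np.column_stack(cols), self.r1
        if factor == "ATT":
            return self._attempts_design(ys0, ys1), self.att_success
        if factor == "Z":
            X = np.column_stack([const, self.C, ys0, self.r0, self.t, ys1, self.r1])
            return X, filled["z"]
        if factor == "RZ":
            zs = self.std["Z"].transform(filled["z"])
            X = np.column_stack([const, self.C, ys0, self.r0, self.t, ys1, self.r1, zs])
            return X, self.rz
        raise KeyError(f"unknown factor {factor!r}")

    def _attempts_design(self, ys0: np.ndarray, ys1: np.ndarray) -> np.ndarray:
        rows = self.att_row
        m = self.att_m
        cols = [
            (m == k).astype(float) for k in range(1, self.n_alpha + 1)
        ]
        cols.append(self.att_type)
        Crows = self.C[rows]
        cols.extend(Crows.T)
        if self.spec.attempts_centre_by_attempt:
            for k in (2, 3):
                if k <= self.n_alpha:
                    ind = (m == k).astype(float)
                    for j in range(3):
                        cols.append(Crows[:, j] * ind)
        cols.append(self.t[rows])
        cols.append(ys0[rows])
        cols.append(ys1[rows])
        if self.spec.attempts_arm_interaction:
            cols.append(self.t[rows] * ys1[rows])
        return np.column_stack(cols)

    # -- likelihood ------------------------------------------------------

    def factor_loglik(
        self, factor: str, params: Mapping[str, float], filled: Mapping[str, np.ndarray]
    ) -> float:
        X, resp = self.design(factor, filled)
        beta = np.array([params[nm] for nm in self._coef_names[factor]])
        eta = X @ beta
        if factor in ("Y0", "Y1", "Z"):
            sigma2 = params[f"sigma2.{factor}"]
            if not sigma2 > 0:
                raise ValueError(f"sigma2.{factor} must be > 0")
            resid = resp - eta
            if factor == "Y1" and self.spec.y1_family == "t":
                df = self.spec.y1_df
                tau = math.sqrt(sigma2 * (df - 2.0) / df)
                return float(stats.t.logpdf(resid, df, scale=tau).sum())
            return float(
                -0.5 * len(resid) * math.log(2 * math.pi * sigma2)
                - 0.5 * float(resid @ resid) / sigma2
            )
        # Bernoulli-logistic factors (R0, R1, RZ and the attempts rows)
        return float(np.sum(resp * eta - np.logaddexp(0.0, eta)))


def complete_data_loglik(
    params: Mapping[str, float],
    dataset: TrialDataset,
    spec: ModelSpec,
    imputations: Mapping[str, np.ndarray] | None = None,
) -> float:
    """Joint log-likelihood of scores, indicators (and attempts) at filled values.

    ``imputations`` supplies values for the missing score slots as
    ``{"y0": ..., "y1": ..., "z": ...}`` arrays aligned with the missing
    positions (in row order); it may be omitted only when nothing is missing.
    """
    frame = ModelFrame(dataset, spec)
    imputations = imputations or {}
    filled = frame.fill(
        y0_mis=imputations.get("y0"),
        y1_mis=imputations.get("y1"),
        z_mis=imputations.get("z"),
    )
    return sum(frame.factor_loglik(f, params, filled) for f in frame.factor_names)


def attempt_success_probability(
    m: int,
    record,
    params: Mapping[str, float],
    spec: ModelSpec,
    standardizers: Mapping[str, Standardizer],
    attempt_type: int = 0,
) -> float:
    """Probability that contact attempt ``m`` succeeds for one participant.

    The attempt index enters only through the intercept ``alpha.m``; every
    slope (attempt type, centre, centre-by-attempt up to attempt 3, arm,
    standardized baseline and final scores, optional arm-by-final-score
    interaction) is shared across attempts.
    """
    if not 1 <= m <= spec.max_attempts:
        raise ValueError(f"attempt index {m} outside 1..{spec.max_attempts}")
    coefs: dict[str, float] = {}
    eta = params[f"alpha.m{m}"]
    eta += params.get("gamma.type", 0.0) * attempt_type
    for c in (2, 3, 4):
        coefs[f"centre{c}"] = params.get(f"gamma.centre{c}", 0.0)
        if spec.attempts_centre_by_attempt and m in (2, 3):
            coefs[f"centre{c}"] += params.get(f"gamma.centre{c}.m{m}", 0.0)
    coefs["T"] = params.get("gamma.T", 0.0)
    coefs["Y0"] = params.get("gamma.Y0", 0.0)
    coefs["Y1"] = params.get("delta.Y1.Rstar", 0.0)
    eta += linear_predictor(coefs, record, standardizers)
    if spec.attempts_arm_interaction:
        eta += (
            params.get("delta.T.Y1.Rstar", 0.0)
            * record.arm
            * _covariate_value("Y1", record, standardizers)
        )
    return float(1.0 / (1.0 + math.exp(-eta)))
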