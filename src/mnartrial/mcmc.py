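"""Bayesian posterior sampling with data augmentation of missing scores.

The sampler is Metropolis-within-Gibbs over the joint posterior of the model
parameters and the missing scores:

* coefficients of the normal score regressions (Y0, Y1, Z) and their
  variances are updated by conjugate Gibbs draws (the heavy-tailed t family
  for Y1 is handled through its gamma scale-mixture representation, which
  restores conjugacy given latent observation weights);
* coefficients of the logistic selection regressions (R0, R1 or the
  repeated-attempts model, R_Z) are updated by adaptive random-walk
  Metropolis blocks (Haario-style empirical-covariance proposals, adapted
  during burn-in only and frozen afterwards, so the kept draws target the
  exact posterior);
* missing scores are latent variables updated by vectorized scalar
  random-walk Metropolis, one conditionally independent proposal per missing
  value per iteration, with the proposal scale tuned during burn-in.

Coefficients listed in ``ModelSpec.fixed_deltas`` are held at their fixed
value in every draw. Runs are deterministic given the seed: a single seed
fans out to one independent stream per chain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

from .data import TrialDataset
from .model import ModelFrame, ModelSpec
from .results import SelectionResults

__all__ = [
    "UniformPrior",
    "NormalCoefPrior",
    "PriorSpec",
    "McmcConfig",
    "SelectionModel",
    "IdentificationWarning",
]


class IdentificationWarning(UserWarning):
    """The requested model is poorly identified without further constraints."""


@dataclass(frozen=True)
class UniformPrior:
    lo: float = -50.0
    hi: float = 50.0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("uniform prior requires lo < hi")

    def logpdf(self, x: float) -> float:
        return 0.0 if self.lo <= x <= self.hi else -math.inf


@dataclass(frozen=True)
class NormalCoefPrior:
    mean: float
    variance: float

    def __post_init__(self):
        if not self.variance > 0:
            raise ValueError("normal prior requires variance > 0")

    def logpdf(self, x: float) -> float:
        return -0.5 * (x - self.mean) ** 2 / self.variance


@dataclass(frozen=True)
class PriorSpec:
    """Per-coefficient priors plus the gamma prior for the score precisions.

    Coefficients default to uniform(-50, 50) on the standardized scale;
    name-specific overrides (e.g. elicited normal priors for the
    outcome-selection slope) go in ``coef_priors``. Precisions 1/sigma^2 get
    gamma(shape, rate) priors, by default the conventional diffuse
    gamma(0.001, 0.001).
    """

    coef_priors: Mapping[str, UniformPrior | NormalCoefPrior] = field(default_factory=dict)
    default: UniformPrior = UniformPrior()
    precision_shape: float = 0.001
    precision_rate: float = 0.001

    def __post_init__(self):
        if not (self.precision_shape > 0 and self.precision_rate > 0):
            raise ValueError("precision prior shape and rate must be > 0")

    def for_name(self, name: str):
        return self.coef_priors.get(name, self.default)

    def with_normal(self, **priors: tuple) -> "PriorSpec":
        """Copy with normal priors added; keys use _ for . (e.g. delta_Y1_R1)."""
        cp = dict(self.coef_priors)
        for key, (mean, var) in priors.items():
            cp[key.replace("_", ".")] = NormalCoefPrior(mean, var)
        return PriorSpec(
            coef_priors=cp,
            default=self.default,
            precision_shape=self.precision_shape,
            precision_rate=self.precision_rate,
        )


@dataclass(frozen=True)
class McmcConfig:
    """Chain geometry. Defaults are desk-scale; ``paper_scale`` mirrors the
    25000/25000 four-chain runs of the original analysis."""

    n_chains: int = 4
    n_burn: int = 2500
    n_keep: int = 2500
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chains, self.n_burn, self.n_keep, self.thin) < 1:
            raise ValueError("all MCMC dimensions must be positive")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_chains=4, n_burn=25000, n_keep=25000, seed=seed)


OUTCOME_SELECTION_NAMES = (
    "delta.Y1.R1",
    "delta.Y1.R1.T",
    "delta.Y1.R1.C",
)


class SelectionModel:
    """Joint MNAR selection model bound to a dataset, fitted by MCMC.

    Parameters
    ----------
    dataset
        The trial data.
    spec
        Model specification (which arcs, which coefficients fixed); defaults
        to the fully-free single-logistic model with no proxy or attempts.
    priors
        Prior specification; defaults to diffuse uniforms and gamma
        precisions.

    Examples
    --------
    >>> model = SelectionModel(dataset, mar_spec())
    >>> result = model.fit(McmcConfig(seed=1))
    >>> result.treatment_effect_summary()  # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: TrialDataset,
        spec: ModelSpec | None = None,
        priors: PriorSpec | None = None,
    ):
        self.dataset = dataset
        self.spec = spec if spec is not None else ModelSpec()
        self.priors = priors if priors is not None else PriorSpec()
        self.frame = ModelFrame(dataset, self.spec)
        self._check_identification()

    def _check_identification(self) -> None:
        spec = self.spec
        if spec.use_attempts:
            return
        free_outcome = [
            nm
            for nm in OUTCOME_SELECTION_NAMES
            if any(nm in self.frame.coef_names(f) for f in self.frame.factor_names)
            and nm not in spec.fixed_deltas
        ]
        if not free_outcome:
            return
        informative = all(
            isinstance(self.priors.for_name(nm), NormalCoefPrior) for nm in free_outcome
        )
        proxy_identified = spec.use_proxy and "delta.R1.Z" in spec.fixed_deltas
        if not informative and not proxy_identified:
            warnings.warn(
                "outcome-selection coefficient(s) "
                + ", ".join(free_outcome)
                + " are free with diffuse priors and no identifying structure "
                "(no repeated attempts, no fixed proxy constraint); the "
                "unconstrained joint model is known to be poorly identified "
                "and its posterior may be extremely diffuse",
                IdentificationWarning,
            )

    # -- public API ------------------------------------------------------

    def fit(self, mcmc: McmcConfig | None = None) -> SelectionResults:
        mcmc = mcmc or McmcConfig()
        chain_seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
        draws: dict[str, list[np.ndarray]] = {}
        imputations: dict[str, list[np.ndarray]] = {"y0": [], "y1": [], "z": []}
        for seq in chain_seeds:
            sampler = _ChainSampler(self.frame, self.spec, self.priors, mcmc)
            chain_draws, chain_imps = sampler.run(np.random.default_rng(seq))
            for k, v in chain_draws.items():
                draws.setdefault(k, []).append(v)
            for k in imputations:
                imputations[k].append(chain_imps[k])
        stacked = {k: np.stack(v) for k, v in draws.items()}
        imps = {
            k: np.stack(v) for k, v in imputations.items() if v[0].shape[-1] > 0
        }
        return SelectionResults(
            draws=stacked,
            imputations=imps,
            dataset=self.dataset,
            spec=self.spec,
            priors=self.priors,
            mcmc=mcmc,
            frame=self.frame,
        )


# -- the per-chain sampler ------------------------------------------------

_AM_START = 200  # iterations of scalar adaptation before covariance kicks in
_AM_EPS = 1e-8


class _AdaptiveBlock:
    """Adaptive multivariate RWM state for one logistic coefficient block.

    The proposal covariance starts from the inverse Fisher information of the
    block (a normal approximation to its conditional posterior), then adapts
    to the empirical covariance of the draws during burn-in.
    """

    def __init__(self, dim: int, init_cov: np.ndarray | None = None, target: float = 0.234):
        self.dim = dim
        self.target = target if dim > 1 else 0.44
        self.log_scale = math.log(2.38 / math.sqrt(dim))
        self.mean = np.zeros(dim)
        self.emp_cov = np.zeros((dim, dim))
        base = np.eye(dim) if init_cov is None else init_cov
        self.chol = cholesky(base + _AM_EPS * np.eye(dim), lower=True)
        self.count = 0

    def propose(self, beta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        step = self.chol @ rng.standard_normal(self.dim)
        return beta + math.exp(self.log_scale) * step

    def adapt(self, beta: np.ndarray, accepted: bool) -> None:
        self.count += 1
        c = self.count
        delta = beta - self.mean
        self.mean += delta / c
        if c > 1:
            self.emp_cov += (np.outer(delta, beta - self.mean) - self.emp_cov) / c
        self.log_scale += 0.05 * ((1.0 if accepted else 0.0) - self.target)
        if c > _AM_START and c % 25 == 0:
            try:
                self.chol = cholesky(
                    self.emp_cov + _AM_EPS * np.eye(self.dim), lower=True
                )
            except np.linalg.LinAlgError:  # pragma: no cover - cov degenerate
                pass


class _ChainSampler:
    """One chain of the data-augmentation sampler; holds all mutable state."""

    def __init__(self, frame: ModelFrame, spec: ModelSpec, priors: PriorSpec, mcmc: McmcConfig):
        self.frame = frame
        self.spec = spec
        self.priors = priors
        self.mcmc = mcmc
        self.normal_factors = [f for f in frame.factor_names if f in ("Y0", "Y1", "Z")]
        self.logistic_factors = [f for f in frame.factor_names if f not in ("Y0", "Y1", "Z")]
        self.coef_names = {f: frame.coef_names(f) for f in frame.factor_names}
        # free/fixed bookkeeping per factor
        self.free_idx: dict[str, np.ndarray] = {}
        self.fixed_idx: dict[str, np.ndarray] = {}
        for f, names in self.coef_names.items():
            fixed = np.array([nm in spec.fixed_deltas for nm in names])
            self.free_idx[f] = np.flatnonzero(~fixed)
            self.fixed_idx[f] = np.flatnonzero(fixed)
        # logistic blocks: attempts split into intercepts + slopes
        self.blocks: list[tuple[str, np.ndarray]] = []
        for f in self.logistic_factors:
            free = self.free_idx[f]
            if f == "ATT" and len(free) > 10:
                n_alpha = frame.n_alpha
                is_alpha = free < n_alpha
                self.blocks.append((f, free[is_alpha]))
                self.blocks.append((f, free[~is_alpha]))
            elif len(free):
                self.blocks.append((f, free))

    # -- initialization ---------------------------------------------------

    def _init_state(self, rng: np.random.Generator):
        fr = self.frame
        self.y0_mis = np.full(len(fr.mis_y0), np.nan)
        self.y1_mis = np.full(len(fr.mis_y1), np.nan)
        self.z_mis = np.full(len(fr.mis_z), np.nan)
        obs_mean = {
            "y0": np.nanmean(fr.y0_obs) if np.any(~np.isnan(fr.y0_obs)) else 0.0,
            "y1": np.nanmean(fr.y1_obs),
            "z": np.nanmean(fr.z_obs) if self.spec.use_proxy else 0.0,
        }
        obs_sd = {
            "y0": np.nanstd(fr.y0_obs) if np.any(~np.isnan(fr.y0_obs)) else 1.0,
            "y1": np.nanstd(fr.y1_obs),
            "z": np.nanstd(fr.z_obs) if self.spec.use_proxy else 1.0,
        }
        self.y0_mis = obs_mean["y0"] + obs_sd["y0"] * rng.standard_normal(len(fr.mis_y0))
        self.y1_mis = obs_mean["y1"] + obs_sd["y1"] * rng.standard_normal(len(fr.mis_y1))
        self.z_mis = obs_mean["z"] + obs_sd["z"] * rng.standard_normal(len(fr.mis_z))
        filled = fr.fill(self.y0_mis, self.y1_mis, self.z_mis if self.spec.use_proxy else None)
        self.X: dict[str, np.ndarray] = {}
        self.resp: dict[str, np.ndarray] = {}
        for f in fr.factor_names:
            X, resp = fr.design(f, filled)
            self.X[f] = X
            self.resp[f] = resp.astype(float).copy()
        self.filled = filled

        # coefficient vectors (full, fixed values already in place)
        self.beta: dict[str, np.ndarray] = {}
        self.sigma2: dict[str, float] = {}
        for f, names in self.coef_names.items():
            b = np.zeros(len(names))
            for j, nm in enumerate(names):
                if nm in self.spec.fixed_deltas:
                    b[j] = self.spec.fixed_deltas[nm]
            if f in self.normal_factors:
                b[0] = self.resp[f].mean() if "const" in self.coef_names[f][0] else 0.0
                b[self.free_idx[f]] += 0.1 * rng.standard_normal(len(self.free_idx[f]))
                self.sigma2[f] = float(np.var(self.resp[f])) or 1.0
            else:
                p = float(np.clip(self.resp[f].mean(), 0.02, 0.98))
                intercept = math.log(p / (1 - p))
                if f == "ATT":
                    b[: self.frame.n_alpha] = intercept
                else:
                    b[0] = intercept
                b[self.free_idx[f]] += 0.1 * rng.standard_normal(len(self.free_idx[f]))
            self.beta[f] = b

        # latent t weights for Y1
        self.t_family = self.spec.y1_family == "t"
        self.w_y1 = np.ones(self.frame.n)

        # adaptive state: start each block at its inverse Fisher information
        self.am = {}
        for i, (f, idx) in enumerate(self.blocks):
            X, beta = self.X[f], self.beta[f]
            p = 1.0 / (1.0 + np.exp(-(X @ beta)))
            wgt = p * (1.0 - p)
            H = X[:, idx].T @ (wgt[:, None] * X[:, idx]) + 0.05 * np.eye(len(idx))
            for k, j in enumerate(idx):
                pr = self.priors.for_name(self.coef_names[f][j])
                if isinstance(pr, NormalCoefPrior):
                    H[k, k] += 1.0 / pr.variance
            self.am[i] = _AdaptiveBlock(len(idx), init_cov=np.linalg.inv(H))
        self.mis_log_scale = {
            "y0": math.log(max(obs_sd["y0"], 1e-3)),
            "y1": math.log(max(obs_sd["y1"], 1e-3)),
            "z": math.log(max(obs_sd["z"], 1e-3)),
        }
        self._build_score_columns()

    def _build_score_columns(self) -> None:
        """Which X columns of which factor move with each imputed score."""
        fr, names = self.frame, self.coef_names
        t = fr.t
        one = np.ones(fr.n)

        def cols_for(f: str, targets: dict[str, np.ndarray]) -> list[tuple[int, np.ndarray]]:
            out = []
            for j, nm in enumerate(names[f]):
                if nm in targets:
                    out.append((j, targets[nm]))
            return out

        mapping = {
            "y0": {
                "delta.Y0.R0": one, "delta.Y0.Y1": one, "delta.Y0.R1": one,
                "delta.Y0.Z": one, "delta.Y0.RZ": one, "gamma.Y0": one,
            },
            "y1": {
                "delta.Y1.R1": one, "delta.Y1.R1.T": t, "delta.Y1.R1.C": 1.0 - t,
                "delta.Y1.Z": one, "delta.Y1.RZ": one,
                "delta.Y1.Rstar": one, "delta.T.Y1.Rstar": t,
            },
            "z": {"delta.Z.RZ": one},
        }
        self.score_cols: dict[str, dict[str, list[tuple[int, np.ndarray]]]] = {}
        for f in fr.factor_names:
            per_score: dict[str, list[tuple[int, np.ndarray]]] = {}
            for score, targets in mapping.items():
                if f == "ATT":
                    # multipliers live on attempt rows
                    att_targets = {nm: mult[fr.att_row] for nm, mult in targets.items()}
                    per_score[score] = cols_for(f, att_targets)
                else:
                    per_score[score] = cols_for(f, targets)
            self.score_cols[f] = per_score

    # -- likelihood pieces -------------------------------------------------

    def _normal_loglik(self, f: str, beta: np.ndarray) -> float:
        resid = self.resp[f] - self.X[f] @ beta
        s2 = self.sigma2[f]
        if f == "Y1" and self.t_family:
            df = self.spec.y1_df
            tau2 = s2 * (df - 2.0) / df
            w = self.w_y1
            return float(
                -0.5 * np.sum(np.log(2 * math.pi * tau2 / w))
                - 0.5 * float((w * resid) @ resid) / tau2
            )
        n = len(resid)
        return float(-0.5 * n * math.log(2 * math.pi * s2) - 0.5 * float(resid @ resid) / s2)

    def _logistic_loglik(self, f: str, beta: np.ndarray) -> float:
        eta = self.X[f] @ beta
        return float(np.sum(self.resp[f] * eta - np.logaddexp(0.0, eta)))

    def _prior_logpdf(self, f: str, beta: np.ndarray, idx: np.ndarray) -> float:
        total = 0.0
        for j in idx:
            total += self.priors.for_name(self.coef_names[f][j]).logpdf(beta[j])
        return total

    # -- Gibbs updates -----------------------------------------------------

    def _update_t_weights(self, rng: np.random.Generator) -> None:
        if not self.t_family:
            return
        df = self.spec.y1_df
        tau2 = self.sigma2["Y1"] * (df - 2.0) / df
        resid = self.resp["Y1"] - self.X["Y1"] @ self.beta["Y1"]
        shape = (df + 1.0) / 2.0
        rate = (df + resid**2 / tau2) / 2.0
        self.w_y1 = rng.gamma(shape, 1.0 / rate)

    def _gibbs_normal_coefs(self, f: str, rng: np.random.Generator) -> None:
        free = self.free_idx[f]
        if len(free) == 0:
            return
        X, y, beta = self.X[f], self.resp[f], self.beta[f]
        s2 = self.sigma2[f]
        if f == "Y1" and self.t_family:
            df = self.spec.y1_df
            s2 = s2 * (df - 2.0) / df
            w = self.w_y1
        else:
            w = None
        fixed = self.fixed_idx[f]
        y_adj = y - X[:, fixed] @ beta[fixed] if len(fixed) else y
        Xf = X[:, free]
        Xw = Xf if w is None else Xf * w[:, None]
        P = (Xw.T @ Xf) / s2
        rhs = (Xw.T @ y_adj) / s2
        # conjugate normal priors fold in; uniform priors are flat inside bounds
        for k, j in enumerate(free):
            pr = self.priors.for_name(self.coef_names[f][j])
            if isinstance(pr, NormalCoefPrior):
                P[k, k] += 1.0 / pr.variance
                rhs[k] += pr.mean / pr.variance
        c, low = cho_factor(P, lower=True)
        mean = cho_solve((c, low), rhs)
        # draw via the cholesky of the precision: P = L L^T -> x = mean + L^{-T} z
        L = np.tril(c)
        cand = mean
        for _ in range(100):
            z = rng.standard_normal(len(free))
            cand = mean + np.linalg.solve(L.T, z)
            ok = True
            for k, j in enumerate(free):
                pr = self.priors.for_name(self.coef_names[f][j])
                if isinstance(pr, UniformPrior) and not (pr.lo <= cand[k] <= pr.hi):
                    ok = False
                    break
            if ok:
                beta[free] = cand
                return
        beta[free] = np.clip(cand, -1e6, 1e6)  # pragma: no cover - bounds huge

    def _gibbs_variance(self, f: str, rng: np.random.Generator) -> None:
        resid = self.resp[f] - self.X[f] @ self.beta[f]
        n = len(resid)
        if f == "Y1" and self.t_family:
            ss = float((self.w_y1 * resid) @ resid)
        else:
            ss = float(resid @ resid)
        shape = self.priors.precision_shape + 0.5 * n
        rate = self.priors.precision_rate + 0.5 * ss
        lam = rng.gamma(shape, 1.0 / rate)
        scale2 = 1.0 / lam
        if f == "Y1" and self.t_family:
            df = self.spec.y1_df
            scale2 = scale2 * df / (df - 2.0)
        self.sigma2[f] = scale2

    # -- Metropolis updates ------------------------------------------------

    def _update_logistic_block(
        self, block_id: int, adapt: bool, rng: np.random.Generator
    ) -> None:
        f, idx = self.blocks[block_id]
        am = self.am[block_id]
        beta = self.beta[f]
        cur = beta[idx].copy()
        cur_ll = self._logistic_loglik(f, beta) + self._prior_logpdf(f, beta, idx)
        prop = am.propose(cur, rng)
        beta[idx] = prop
        prop_prior = self._prior_logpdf(f, beta, idx)
        if not math.isfinite(prop_prior):
            accepted = False
        else:
            prop_ll = self._logistic_loglik(f, beta) + prop_prior
            accepted = math.log(rng.random()) < prop_ll - cur_ll
        if not accepted:
            beta[idx] = cur
        if adapt:
            am.adapt(beta[idx].copy(), accepted)

    # -- missing-score updates ----------------------------------------------

    def _row_loglik_normal(self, f: str, rows: np.ndarray, resp_rows: np.ndarray) -> np.ndarray:
        eta = self.X[f][rows] @ self.beta[f]
        s2 = self.sigma2[f]
        if f == "Y1" and self.t_family:
            df = self.spec.y1_df
            tau2 = s2 * (df - 2.0) / df
            w = self.w_y1[rows]
            return -0.5 * np.log(2 * math.pi * tau2 / w) - 0.5 * w * (resp_rows - eta) ** 2 / tau2
        return -0.5 * math.log(2 * math.pi * s2) - 0.5 * (resp_rows - eta) ** 2 / s2

    def _logistic_rows(self, f: str, rows: np.ndarray, delta_eta: np.ndarray | float = 0.0) -> np.ndarray:
        eta = self.X[f][rows] @ self.beta[f] + delta_eta
        r = self.resp[f][rows]
        return r * eta - np.logaddexp(0.0, eta)

    def _delta_eta(self, f: str, score: str, rows: np.ndarray, dstd: np.ndarray) -> np.ndarray:
        """Change in the factor's linear predictor at ``rows`` when the
        standardized score changes by ``dstd`` (aligned with rows)."""
        beta = self.beta[f]
        out = np.zeros(len(rows))
        for j, mult in self.score_cols[f][score]:
            out += beta[j] * mult[rows] * dstd
        return out

    def _update_missing(self, score: str, it: int, adapt: bool, rng: np.random.Generator) -> None:
        fr = self.frame
        if score == "y0":
            rows, cur = fr.mis_y0, self.y0_mis
            own_factor, std = "Y0", fr.std["Y0"]
            downstream = [f for f in fr.factor_names if f != "Y0"]
        elif score == "y1":
            rows, cur = fr.mis_y1, self.y1_mis
            own_factor, std = "Y1", fr.std["Y1"]
            downstream = [f for f in ("R1", "ATT", "Z", "RZ") if f in fr.factor_names]
        else:
            rows, cur = fr.mis_z, self.z_mis
            own_factor, std = "Z", fr.std["Z"] if self.spec.use_proxy else None
            downstream = [f for f in ("RZ",) if f in fr.factor_names]
        if len(rows) == 0:
            return
        scale = math.exp(self.mis_log_scale[score])
        prop = cur + scale * rng.standard_normal(len(rows))
        dstd = (prop - cur) / std.pooled_sd

        logratio = self._row_loglik_normal(own_factor, rows, prop) - self._row_loglik_normal(
            own_factor, rows, cur
        )
        for f in downstream:
            if not self.score_cols[f][score]:
                continue
            if f == "ATT":
                att_rows, pos = self._att_rows_for(score)
                if len(att_rows) == 0:
                    continue
                d_eta = self._delta_eta(f, score, att_rows, dstd[pos])
                diff = self._logistic_rows(f, att_rows, d_eta) - self._logistic_rows(f, att_rows)
                logratio += np.bincount(pos, weights=diff, minlength=len(rows))
            else:
                d_eta = self._delta_eta(f, score, rows, dstd)
                if f in ("Y1", "Z"):  # normal factor: eta shift changes the residual
                    logratio += self._row_loglik_shift_normal(f, rows, d_eta)
                else:
                    logratio += self._logistic_rows(f, rows, d_eta) - self._logistic_rows(f, rows)

        accept = np.log(rng.random(len(rows))) < logratio
        if np.any(accept):
            acc_rows = rows[accept]
            cur[accept] = prop[accept]
            self.resp[own_factor][acc_rows] = prop[accept]
            self.filled[score][acc_rows] = prop[accept]
            d_acc = dstd[accept]
            for f in fr.factor_names:
                for j, mult in self.score_cols[f][score]:
                    if f == "ATT":
                        att_rows, pos = self._att_rows_for(score)
                        sel = accept[pos]
                        self.X[f][att_rows[sel], j] += mult[att_rows[sel]] * dstd[pos][sel]
                    else:
                        self.X[f][acc_rows, j] += mult[acc_rows] * d_acc
        if adapt:
            rate = np.mean(accept) if len(accept) else 0.44
            self.mis_log_scale[score] += 0.05 * (rate - 0.44)

    def _row_loglik_shift_normal(self, f: str, rows: np.ndarray, d_eta: np.ndarray) -> np.ndarray:
        """Log-density change of a normal factor when eta shifts by d_eta."""
        eta = self.X[f][rows] @ self.beta[f]
        resid = self.resp[f][rows] - eta
        s2 = self.sigma2[f]
        if f == "Y1" and self.t_family:
            df = self.spec.y1_df
            tau2 = s2 * (df - 2.0) / df
            w = self.w_y1[rows]
            return (-0.5 * w * (resid - d_eta) ** 2 + 0.5 * w * resid**2) / tau2
        return (-0.5 * (resid - d_eta) ** 2 + 0.5 * resid**2) / s2

    def _att_rows_for(self, score: str) -> tuple[np.ndarray, np.ndarray]:
        return self._att_cache[score]

    # -- main loop -----------------------------------------------------------

    def run(self, rng: np.random.Generator) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        mc = self.mcmc
        self._init_state(rng)
        fr = self.frame

        self._att_cache = {}
        for score, rows in (("y0", fr.mis_y0), ("y1", fr.mis_y1), ("z", fr.mis_z)):
            if self.spec.use_attempts and len(rows):
                mask = np.isin(fr.att_row, rows)
                att_rows = np.flatnonzero(mask)
                pos = np.searchsorted(rows, fr.att_row[att_rows])
                self._att_cache[score] = (att_rows, pos)
            else:
                self._att_cache[score] = (np.array([], int), np.array([], int))

        monitored = self._monitored_names()
        n_out = mc.n_keep // mc.thin
        out = {nm: np.empty(n_out) for nm in monitored}
        imp_out = {
            "y0": np.empty((n_out, len(fr.mis_y0))),
            "y1": np.empty((n_out, len(fr.mis_y1))),
            "z": np.empty((n_out, len(fr.mis_z))),
        }
        total = mc.n_burn + mc.n_keep
        k = 0
        for it in range(total):
            adapt = it < mc.n_burn
            self._update_t_weights(rng)
            for f in self.normal_factors:
                self._gibbs_normal_coefs(f, rng)
                self._gibbs_variance(f, rng)
            for _rep in range(2):
                for b in range(len(self.blocks)):
                    self._update_logistic_block(b, adapt, rng)
            for score in ("y0", "y1", "z"):
                self._update_missing(score, it, adapt, rng)
            if it >= mc.n_burn and (it - mc.n_burn) % mc.thin == 0 and k < n_out:
                for f, names in self.coef_names.items():
                    b = self.beta[f]
                    for j in range(len(names)):  # fixed coefs recorded as constants
                        out[names[j]][k] = b[j]
                for f in self.normal_factors:
                    out[f"sigma2.{f}"][k] = self.sigma2[f]
                imp_out["y0"][k] = self.y0_mis
                imp_out["y1"][k] = self.y1_mis
                imp_out["z"][k] = self.z_mis
                k += 1
        return out, imp_out

    def _monitored_names(self) -> list[str]:
        names = []
        for cn in self.coef_names.values():
            names.extend(cn)
        names.extend(f"sigma2.{f}" for f in self.normal_factors)
        return names
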