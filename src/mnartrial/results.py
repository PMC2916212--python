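"""Posterior results: summaries, convergence diagnostics, export.

The key trial-level summaries are the treatment effect (the coefficient of
arm in the final-score regression) and Delta(Y1, arm): the posterior mean of
the imputed missing final scores minus the mean of the observed final scores
in that arm, a per-draw measure of how far the fitted missingness mechanism
departs from missingness completely at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .mcmc import McmcConfig, PriorSpec
    from .model import ModelFrame, ModelSpec
    from .data import TrialDataset

__all__ = ["SelectionResults", "gelman_rubin", "TREATMENT_EFFECT"]

TREATMENT_EFFECT = "delta.T.Y1"


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_samples). Classic between/within
    formulation: with W the mean within-chain variance and B/n the
    between-chain variance of the chain means, the pooled variance estimate
    is (n-1)/n W + B/n and the statistic is the square root of its ratio to
    W. Requires at least two chains.
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin requires draws from at least two chains")
    m, n = chains.shape
    if n < 2:
        raise ValueError("need at least two draws per chain")
    means = chains.mean(axis=1)
    W = float(chains.var(axis=1, ddof=1).mean())
    B = n * float(means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class SelectionResults:
    """Posterior draws and summaries from :meth:`SelectionModel.fit`.

    ``draws`` maps parameter names to arrays of shape
    (n_chains, n_kept); ``imputations`` maps score names (y0/y1/z) to arrays
    of shape (n_chains, n_kept, n_missing).
    """

    draws: Mapping[str, np.ndarray]
    imputations: Mapping[str, np.ndarray]
    dataset: "TrialDataset"
    spec: "ModelSpec"
    priors: "PriorSpec"
    mcmc: "McmcConfig"
    frame: "ModelFrame"

    # -- basic access ----------------------------------------------------

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws)

    def stacked(self, name: str) -> np.ndarray:
        """All kept draws of one parameter pooled across chains."""
        return np.asarray(self.draws[name]).reshape(-1)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.draws.values()))
        return int(np.prod(np.asarray(first).shape))

    # -- summaries -------------------------------------------------------

    def summary(self, credible_mass: float = 0.95) -> pd.DataFrame:
        """Posterior mean, SD, equal-tailed credible interval and PSRF per parameter."""
        lo_q = 100 * (1 - credible_mass) / 2
        rows = []
        for name, arr in self.draws.items():
            pooled = np.asarray(arr).reshape(-1)
            lo, hi = np.percentile(pooled, [lo_q, 100 - lo_q])
            rhat = gelman_rubin(arr) if np.asarray(arr).shape[0] >= 2 else np.nan
            rows.append(
                {
                    "parameter": name,
                    "mean": pooled.mean(),
                    "sd": pooled.std(ddof=1),
                    f"{lo_q:g}%": lo,
                    f"{100 - lo_q:g}%": hi,
                    "rhat": rhat,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def treatment_effect_summary(self, credible_mass: float = 0.95) -> dict:
        """Posterior mean, SD and equal-tailed credible interval of the treatment effect."""
        pooled = self.stacked(TREATMENT_EFFECT)
        lo_q = 100 * (1 - credible_mass) / 2
        lo, hi = np.percentile(pooled, [lo_q, 100 - lo_q])
        return {
            "mean": float(pooled.mean()),
            "sd": float(pooled.std(ddof=1)),
            "ci": (float(lo), float(hi)),
        }

    def delta_missing_minus_observed(self, arm: int) -> dict:
        """Posterior mean and SD of mean(imputed missing y1) - mean(observed y1) in one arm.

        The observed-arm mean is a fixed data quantity; the imputed mean
        varies by draw.
        """
        y1 = self.dataset.y1
        arm_arr = self.dataset.arm
        mis = self.frame.mis_y1
        mis_in_arm = np.flatnonzero(arm_arr[mis] == arm)
        if len(mis_in_arm) == 0:
            raise ValueError(f"no missing final scores in arm {arm}")
        obs_mask = (arm_arr == arm) & ~np.isnan(y1)
        obs_mean = float(y1[obs_mask].mean())
        imp = np.asarray(self.imputations["y1"])[:, :, mis_in_arm]
        per_draw = imp.mean(axis=2).reshape(-1) - obs_mean
        return {"mean": float(per_draw.mean()), "sd": float(per_draw.std(ddof=1))}

    # -- convergence -----------------------------------------------------

    def gelman_rubin(self) -> pd.Series:
        """PSRF per monitored parameter (requires >= 2 chains)."""
        return pd.Series(
            {name: gelman_rubin(arr) for name, arr in self.draws.items()},
            name="rhat",
        )

    def convergence_report(self, threshold: float = 1.05) -> dict:
        """PSRF values with a flag for parameters above ``threshold``."""
        rhat = self.gelman_rubin()
        flagged = rhat[rhat > threshold]
        return {
            "threshold": threshold,
            "converged": bool(len(flagged) == 0),
            "rhat": {k: float(v) for k, v in rhat.items()},
            "flagged": {k: float(v) for k, v in flagged.items()},
        }

    # -- export ----------------------------------------------------------

    def draws_frame(self) -> pd.DataFrame:
        """One row per kept draw, one column per parameter, plus chain id."""
        n_chains = np.asarray(next(iter(self.draws.values()))).shape[0]
        cols = {name: self.stacked(name) for name in self.draws}
        n_per = len(next(iter(cols.values()))) // n_chains
        cols["chain"] = np.repeat(np.arange(n_chains), n_per)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.draws_frame().to_csv(path, index=False)

    def convergence_to_json(self, path, threshold: float = 1.05) -> None:
        with open(path, "w") as fh:
            json.dump(self.convergence_report(threshold), fh, indent=2)
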