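"""Expert-opinion elicitation arithmetic for informative-missingness priors.

Experts distribute a weight of 100 over nine ordered categories describing how
the mean outcome of nonresponders compares with that of responders (lower by
>=13, 9-12, 5-8, 1-4 points; the same; higher by 1-4, 5-8, 9-12, >=13),
stated relative to a responder distribution with mean 40 and SD 10. The
module pools expert tables with a linear opinion pool, extracts moments via
category midpoints, interprets the conditional "revised guess" question as a
between-arm belief correlation, and converts the pooled pattern-mixture
belief (a distribution for mu_m - mu_o) into a normal prior for the per-SD
outcome-selection slope of the corresponding selection model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ElicitationTable",
    "CategoryMidpoints",
    "DEFAULT_MIDPOINTS",
    "pool_opinions",
    "moments_from_weights",
    "correlation_from_anchors",
    "prior_for_delta",
    "combine_arms",
    "read_elicitation_tables",
]

N_CATEGORIES = 9

CATEGORY_LABELS = [
    "lower_ge13",
    "lower_9_12",
    "lower_5_8",
    "lower_1_4",
    "same",
    "higher_1_4",
    "higher_5_8",
    "higher_9_12",
    "higher_ge13",
]

ANCHOR_COLUMNS = ["avg_diff_intervention", "max_diff_intervention", "revised_guess"]

WEIGHT_TOL = 1e-6


@dataclass(frozen=True)
class CategoryMidpoints:
    """Representative values for the nine categories (14.5 for the extremes)."""

    values: tuple = (-14.5, -10.5, -6.5, -2.5, 0.0, 2.5, 6.5, 10.5, 14.5)

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if len(v) != N_CATEGORIES or not np.all(np.diff(v) > 0):
            raise ValueError("midpoints must be 9 strictly increasing values")


DEFAULT_MIDPOINTS = CategoryMidpoints()


@dataclass
class ElicitationTable:
    """One expert's weight vector plus the correlation-anchor answers.

    ``correlation_anchor`` is (average difference in the intervention arm,
    maximum difference in the intervention arm, revised guess after being
    told the control-arm difference was at its maximum).
    """

    expert_id: str
    weights: np.ndarray
    correlation_anchor: tuple[float, float, float] | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.shape != (N_CATEGORIES,):
            raise ValueError(f"weights must have length {N_CATEGORIES}")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 100.0) > WEIGHT_TOL:
            raise ValueError(f"weights must sum to 100, got {w.sum()!r}")
        self.weights = w


def pool_opinions(tables: list[ElicitationTable]) -> np.ndarray:
    """Linear opinion pool: the unweighted mean of the expert weight vectors."""
    if not tables:
        raise ValueError("cannot pool an empty list of elicitation tables")
    return np.mean([t.weights for t in tables], axis=0)


def moments_from_weights(
    weights: np.ndarray, midpoints: CategoryMidpoints = DEFAULT_MIDPOINTS
) -> tuple[float, float]:
    """Mean and SD of the discrete midpoint distribution implied by a weight vector."""
    w = np.asarray(weights, float)
    if w.shape != (N_CATEGORIES,) or np.any(w < 0) or abs(w.sum() - 100.0) > WEIGHT_TOL:
        raise ValueError("weights must be 9 non-negative values summing to 100")
    p = w / w.sum()
    mids = np.asarray(midpoints.values, float)
    mean = float(p @ mids)
    var = float(p @ (mids - mean) ** 2)
    return mean, float(np.sqrt(var))


def correlation_from_anchors(
    avg_diff: float, max_diff: float, revised_guess: float
) -> float:
    """Between-arm belief correlation by linear interpolation of the revised guess.

    An expert who keeps their average difference after hearing the control-arm
    difference was at its maximum has uncorrelated beliefs (0); one who moves
    all the way to their maximum difference has perfectly correlated beliefs
    (1); intermediate answers interpolate linearly. The result is clipped to
    [0, 1].
    """
    if max_diff == avg_diff:
        raise ValueError(
            "correlation undefined when the expert's maximum equals their average"
        )
    rho = (revised_guess - avg_diff) / (max_diff - avg_diff)
    return float(np.clip(rho, 0.0, 1.0))


@dataclass(frozen=True)
class NormalPrior:
    """A normal prior, reported as (mean, variance)."""

    mean: float
    variance: float

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def prior_for_delta(mean_diff: float, var_diff: float, sigma: float) -> NormalPrior:
    """Convert a pattern-mixture belief into a prior for the per-SD selection slope.

    Beliefs about ``mu_m - mu_o`` (nonresponder minus responder mean) elicited
    at reference SD ``sigma`` rescale to the selection scale via
    delta ~ N(-mean_diff/sigma, var_diff/sigma^2), using the equal-variance
    normal pattern-mixture/selection-model identity (mu_o - mu_m)/sigma ~= delta.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    if not var_diff > 0:
        raise ValueError("var_diff must be > 0")
    return NormalPrior(mean=-mean_diff / sigma, variance=var_diff / sigma**2)


def combine_arms(
    intervention: tuple[float, float],
    control: tuple[float, float],
    *,
    round_variance_to: int | None = None,
) -> dict:
    """Average the two arm-specific elicited (mean, SD) pairs into one prior.

    The pooled mean is the average of the arm means and the pooled SD the
    average of the arm SDs; the variance is that SD squared, optionally
    rounded to ``round_variance_to`` decimals (reported alongside the exact
    value either way).
    """
    mi, si = intervention
    mc, sc = control
    if not (si > 0 and sc > 0):
        raise ValueError("arm SDs must be > 0")
    mean = (mi + mc) / 2.0
    sd = (si + sc) / 2.0
    variance = sd**2
    out = {"mean": mean, "sd": sd, "variance": variance}
    if round_variance_to is not None:
        out["variance_rounded"] = round(variance, round_variance_to)
    return out


def read_elicitation_tables(path, *, sep: str = ",") -> list[ElicitationTable]:
    """Read expert tables from CSV: expert_id, nine weight columns, three anchors."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ["expert_id", *CATEGORY_LABELS] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    has_anchor = all(c in df.columns for c in ANCHOR_COLUMNS)
    tables = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        anchor = (
            tuple(float(d[c]) for c in ANCHOR_COLUMNS) if has_anchor else None
        )
        tables.append(
            ElicitationTable(
                expert_id=str(d["expert_id"]),
                weights=np.array([d[c] for c in CATEGORY_LABELS], float),
                correlation_anchor=anchor,
            )
        )
    return tables
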