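"""Analysis suites: MAR fit, delta-grid sensitivity, elicited priors, proxies, attempts.

Each suite fits a sequence of constrained selection models and collects, per
model, the treatment effect, Delta(Y1, intervention) and Delta(Y1, control)
(posterior mean and SD each) plus a convergence flag. The default delta grid
mirrors the classic sensitivity layout: the outcome-selection slopes fixed at
0, 0.5 and 1 per SD, including the arm-specific "worst case" pairs (0, 1)
and (1, 0).

Every suite derives one sub-seed per fit from the single seed in the MCMC
configuration, so a whole suite is reproducible as a unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import TrialDataset
from .mcmc import McmcConfig, NormalCoefPrior, PriorSpec, SelectionModel
from .model import ModelSpec, mar_spec
from .results import SelectionResults

__all__ = [
    "SensitivityCell",
    "run_mar",
    "run_delta_grid",
    "run_elicited",
    "run_proxy_suite",
    "run_attempts_suite",
    "default_delta_grid",
    "default_proxy_variants",
    "render_report",
    "report_frame",
]


@dataclass
class SensitivityCell:
    """One fitted model of a sensitivity suite."""

    label: str
    fixed: Mapping[str, float]
    delta_t: tuple[float, float]  # Delta(Y1, intervention): mean, SD
    delta_c: tuple[float, float]  # Delta(Y1, control): mean, SD
    effect: tuple[float, float]  # treatment effect: mean, SD
    converged: bool
    extra: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    result: SelectionResults | None = None

    def __post_init__(self):
        for pair in (self.delta_t, self.delta_c, self.effect):
            if pair[1] < 0:
                raise ValueError("posterior SDs must be non-negative")


def _sub_seeds(mcmc: McmcConfig, n: int) -> list[int]:
    children = np.random.SeedSequence(mcmc.seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _fit_cell(
    dataset: TrialDataset,
    spec: ModelSpec,
    priors: PriorSpec,
    mcmc: McmcConfig,
    label: str,
    extra_params: Sequence[str] = (),
    keep_result: bool = True,
) -> SensitivityCell:
    result = SelectionModel(dataset, spec, priors).fit(mcmc)
    eff = result.treatment_effect_summary()
    dt = result.delta_missing_minus_observed(arm=1)
    dc = result.delta_missing_minus_observed(arm=0)
    report = result.convergence_report()
    extra = {}
    for name in extra_params:
        if name in result.draws:
            pooled = result.stacked(name)
            extra[name] = (float(pooled.mean()), float(pooled.std(ddof=1)))
    return SensitivityCell(
        label=label,
        fixed=dict(spec.fixed_deltas),
        delta_t=(dt["mean"], dt["sd"]),
        delta_c=(dc["mean"], dc["sd"]),
        effect=(eff["mean"], eff["sd"]),
        converged=report["converged"],
        extra=extra,
        result=result if keep_result else None,
    )


def run_mar(
    dataset: TrialDataset,
    mcmc: McmcConfig | None = None,
    priors: PriorSpec | None = None,
) -> SensitivityCell:
    """Fit the MAR-constrained model (scores independent of indicators)."""
    mcmc = mcmc or McmcConfig()
    return _fit_cell(dataset, mar_spec(), priors or PriorSpec(), mcmc, label="MAR")


def default_delta_grid() -> list[dict]:
    """The seven-model grid over (delta.Y0.R0, delta.Y1.R1) incl. arm-specific pairs."""
    return [
        {"label": "A", "delta.Y0.R0": 0.0, "delta.Y1.R1": 0.0},
        {"label": "B", "delta.Y0.R0": 0.5, "delta.Y1.R1": 0.0},
        {"label": "C", "delta.Y0.R0": 1.0, "delta.Y1.R1": 0.0},
        {"label": "D", "delta.Y0.R0": 0.0, "delta.Y1.R1": 0.5},
        {"label": "E", "delta.Y0.R0": 0.0, "delta.Y1.R1": 1.0},
        {"label": "F", "delta.Y0.R0": 0.0, "delta.Y1.R1.T": 0.0, "delta.Y1.R1.C": 1.0},
        {"label": "G", "delta.Y0.R0": 0.0, "delta.Y1.R1.T": 1.0, "delta.Y1.R1.C": 0.0},
    ]


def _grid_spec(point: Mapping[str, float], use_proxy: bool = False) -> ModelSpec:
    fixed = {k: float(v) for k, v in point.items() if k != "label"}
    arm_specific = "delta.Y1.R1.T" in fixed or "delta.Y1.R1.C" in fixed
    if arm_specific:
        for nm in ("delta.Y1.R1.T", "delta.Y1.R1.C"):
            if nm not in fixed:
                raise ValueError(f"grid point does not identify the model: {nm} is free")
    elif "delta.Y1.R1" not in fixed:
        raise ValueError("grid point does not identify the model: delta.Y1.R1 is free")
    if use_proxy and "delta.Z.RZ" not in fixed:
        raise ValueError("grid point does not identify the model: delta.Z.RZ is free")
    return ModelSpec(
        fixed_deltas=fixed,
        arm_specific_outcome_selection=arm_specific,
        use_proxy=use_proxy,
    )


def run_delta_grid(
    dataset: TrialDataset,
    grid: Sequence[Mapping[str, float]] | None = None,
    mcmc: McmcConfig | None = None,
    priors: PriorSpec | None = None,
) -> list[SensitivityCell]:
    """Fit one constrained model per grid point, in input order."""
    mcmc = mcmc or McmcConfig()
    priors = priors or PriorSpec()
    if grid is None:
        grid = default_delta_grid()
    cells = []
    seeds = _sub_seeds(mcmc, max(len(grid), 1))
    for point, seed in zip(grid, seeds):
        spec = _grid_spec(point)
        label = str(point.get("label", len(cells)))
        cells.append(
            _fit_cell(dataset, spec, priors, replace(mcmc, seed=seed), label)
        )
    return cells


def run_elicited(
    dataset: TrialDataset,
    prior_mode: str,
    elicited: Mapping,
    mcmc: McmcConfig | None = None,
) -> SensitivityCell:
    """Fit with elicited normal prior(s) on the outcome-selection slope.

    ``prior_mode`` is ``"common"`` (one slope, ``elicited`` carries
    ``mean``/``variance``) or ``"arm_specific"`` (``elicited`` carries
    ``intervention`` and ``control`` entries, each with mean/variance).
    Baseline scores are assumed missing at random (delta.Y0.R0 = 0).
    """
    mcmc = mcmc or McmcConfig()
    if prior_mode == "common":
        spec = ModelSpec(fixed_deltas={"delta.Y0.R0": 0.0})
        priors = PriorSpec(
            coef_priors={
                "delta.Y1.R1": NormalCoefPrior(
                    float(elicited["mean"]), float(elicited["variance"])
                )
            }
        )
        extra = ["delta.Y1.R1"]
    elif prior_mode == "arm_specific":
        spec = ModelSpec(
            fixed_deltas={"delta.Y0.R0": 0.0}, arm_specific_outcome_selection=True
        )
        priors = PriorSpec(
            coef_priors={
                "delta.Y1.R1.T": NormalCoefPrior(
                    float(elicited["intervention"]["mean"]),
                    float(elicited["intervention"]["variance"]),
                ),
                "delta.Y1.R1.C": NormalCoefPrior(
                    float(elicited["control"]["mean"]),
                    float(elicited["control"]["variance"]),
                ),
            }
        )
        extra = ["delta.Y1.R1.T", "delta.Y1.R1.C"]
    else:
        raise ValueError("prior_mode must be 'common' or 'arm_specific'")
    return _fit_cell(dataset, spec, priors, mcmc, label=prior_mode, extra_params=extra)


def default_proxy_variants() -> list[dict]:
    """Proxy-MAR, the proxy delta grid, and the identification-via-proxy pair."""
    variants: list[dict] = [{"label": "proxy-MAR", "kind": "mar"}]
    grid = [
        {"label": "A", "delta.Y1.R1": 0.0, "delta.Z.RZ": 0.0},
        {"label": "B", "delta.Y1.R1": 0.0, "delta.Z.RZ": 0.5},
        {"label": "C", "delta.Y1.R1": 0.0, "delta.Z.RZ": 1.0},
        {"label": "D", "delta.Y1.R1": 0.5, "delta.Z.RZ": 0.0},
        {"label": "E", "delta.Y1.R1": 1.0, "delta.Z.RZ": 0.0},
        {
            "label": "F",
            "delta.Y1.R1.T": 0.0,
            "delta.Y1.R1.C": 1.0,
            "delta.Z.RZ": 0.0,
        },
        {
            "label": "G",
            "delta.Y1.R1.T": 1.0,
            "delta.Y1.R1.C": 0.0,
            "delta.Z.RZ": 0.0,
        },
    ]
    for g in grid:
        g = dict(g)
        g["delta.Y0.R0"] = 0.0
        variants.append({"label": f"grid-{g['label']}", "kind": "grid", "point": g})
    for val in (0.0, 1.0):
        variants.append(
            {"label": f"identify-dR1Z={val:g}", "kind": "identify", "delta_r1_z": val}
        )
    return variants


def run_proxy_suite(
    dataset: TrialDataset,
    variants: Sequence[Mapping] | None = None,
    mcmc: McmcConfig | None = None,
    priors: PriorSpec | None = None,
) -> list[SensitivityCell]:
    """Run the proxy-outcome analyses.

    Variants: ``mar`` (proxy-extended MAR), ``grid`` (fixed delta pairs as in
    the proxy sensitivity table) and ``identify`` (fix ``delta.R1.Z`` and
    leave the outcome-selection slope free, identified through the proxy).
    A poorly-mixing identify fit surfaces as ``converged=False``.
    """
    if variants is None:
        variants = default_proxy_variants()
    if not dataset.has_proxy:
        raise ValueError("dataset has no proxy scores")
    mcmc = mcmc or McmcConfig()
    priors = priors or PriorSpec()
    cells = []
    seeds = _sub_seeds(mcmc, max(len(variants), 1))
    for variant, seed in zip(variants, seeds):
        kind = variant["kind"]
        extra: list[str] = []
        if kind == "mar":
            spec = mar_spec(use_proxy=True)
        elif kind == "grid":
            spec = _grid_spec(variant["point"], use_proxy=True)
        elif kind == "identify":
            spec = ModelSpec(
                use_proxy=True,
                fixed_deltas={
                    "delta.Y0.R0": 0.0,
                    "delta.Z.RZ": 0.0,
                    "delta.R1.Z": float(variant["delta_r1_z"]),
                },
            )
            extra = ["delta.Y1.R1"]
        else:
            raise ValueError(f"unknown proxy variant kind {kind!r}")
        cells.append(
            _fit_cell(
                dataset,
                spec,
                priors,
                replace(mcmc, seed=seed),
                str(variant["label"]),
                extra_params=extra,
            )
        )
    return cells


def run_attempts_suite(
    dataset: TrialDataset,
    specs: Sequence[str] | None = None,
    mcmc: McmcConfig | None = None,
    priors: PriorSpec | None = None,
) -> list[SensitivityCell]:
    """Fit the repeated-attempts models.

    ``specs`` selects from ``"A"`` (no arm-by-outcome interaction), ``"B"``
    (with the interaction) and ``"C"`` (B plus proxies with
    delta.Y0.R0 = delta.Z.RZ = 0). Baseline scores are assumed missing at
    random throughout. Cells carry the outcome-slope (and interaction)
    posteriors in ``extra``.
    """
    if not dataset.has_attempts:
        raise ValueError("dataset has no attempt records")
    if specs is None:
        specs = ["A", "B", "C"] if dataset.has_proxy else ["A", "B"]
    mcmc = mcmc or McmcConfig()
    priors = priors or PriorSpec()
    cells = []
    seeds = _sub_seeds(mcmc, max(len(specs), 1))
    for label, seed in zip(specs, seeds):
        fixed = {"delta.Y0.R0": 0.0}
        if label == "A":
            spec = ModelSpec(
                use_attempts=True, attempts_arm_interaction=False, fixed_deltas=fixed
            )
        elif label == "B":
            spec = ModelSpec(
                use_attempts=True, attempts_arm_interaction=True, fixed_deltas=fixed
            )
        elif label == "C":
            fixed["delta.Z.RZ"] = 0.0
            spec = ModelSpec(
                use_attempts=True,
                attempts_arm_interaction=True,
                use_proxy=True,
                fixed_deltas=fixed,
            )
        else:
            raise ValueError(f"unknown attempts model {label!r}")
        cells.append(
            _fit_cell(
                dataset,
                spec,
                priors,
                replace(mcmc, seed=seed),
                label,
                extra_params=["delta.Y1.Rstar", "delta.T.Y1.Rstar"],
            )
        )
    return cells


# -- reporting ------------------------------------------------------------


def report_frame(cells: Sequence[SensitivityCell]) -> pd.DataFrame:
    """Machine-readable twin of the report table (one row per cell)."""
    rows = []
    for c in cells:
        row: dict = {
            "model": c.label,
            "fixed": ";".join(f"{k}={v:g}" for k, v in sorted(c.fixed.items())),
            "delta_t_mean": c.delta_t[0],
            "delta_t_sd": c.delta_t[1],
            "delta_c_mean": c.delta_c[0],
            "delta_c_sd": c.delta_c[1],
            "effect_mean": c.effect[0],
            "effect_sd": c.effect[1],
            "converged": c.converged,
        }
        for name, (m, s) in c.extra.items():
            row[f"{name}_mean"] = m
            row[f"{name}_sd"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(cells: Sequence[SensitivityCell], csv_path=None) -> str:
    """Fixed-width text table (SDs in parentheses) with an optional CSV twin."""
    header = f"{'Model':<14}{'Fixed deltas':<36}{'D(Y1,T) (SD)':<18}{'D(Y1,C) (SD)':<18}{'Effect (SD)':<18}"
    lines = [header, "-" * len(header)]
    for c in cells:
        fixed = ";".join(f"{k}={v:g}" for k, v in sorted(c.fixed.items())) or "-"
        dt = f"{c.delta_t[0]:.2f} ({c.delta_t[1]:.2f})"
        dc = f"{c.delta_c[0]:.2f} ({c.delta_c[1]:.2f})"
        ef = f"{c.effect[0]:.2f} ({c.effect[1]:.2f})"
        lines.append(f"{c.label:<14}{fixed:<36}{dt:<18}{dc:<18}{ef:<18}")
    if csv_path is not None:
        report_frame(cells).to_csv(csv_path, index=False)
    return "\n".join(lines)
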