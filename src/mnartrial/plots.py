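"""Optional plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np

from .results import SelectionResults

__all__ = ["plot_imputations"]


def plot_imputations(result: SelectionResults, ax=None, credible_mass: float = 0.95):
    """Final vs baseline score scatter with posterior summaries of imputed scores.

    Open circles: participants with both scores observed. Filled circles:
    participants with at least one score replaced by its posterior mean, with
    vertical bars giving the equal-tailed credible interval for an imputed
    final score.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ds = result.dataset
    frame = result.frame
    y0, y1 = ds.y0.copy(), ds.y1.copy()
    lo_q = 100 * (1 - credible_mass) / 2

    has_imp = {k: np.asarray(v).reshape(-1, v.shape[-1]) for k, v in result.imputations.items()}
    y0_bars = y1_bars = None
    if "y0" in has_imp and len(frame.mis_y0):
        y0[frame.mis_y0] = has_imp["y0"].mean(axis=0)
    if "y1" in has_imp and len(frame.mis_y1):
        draws = has_imp["y1"]
        y1[frame.mis_y1] = draws.mean(axis=0)
        y1_bars = np.percentile(draws, [lo_q, 100 - lo_q], axis=0)

    imputed = np.zeros(len(ds), bool)
    imputed[frame.mis_y0] = True
    imputed[frame.mis_y1] = True
    ax.scatter(
        y0[~imputed], y1[~imputed], facecolors="none", edgecolors="k", s=18,
        label="both observed",
    )
    ax.scatter(y0[imputed], y1[imputed], color="k", s=18, label="imputed (posterior mean)")
    if y1_bars is not None:
        ax.vlines(y0[frame.mis_y1], y1_bars[0], y1_bars[1], color="k", lw=0.6, alpha=0.6)
    ax.set_xlabel("baseline score")
    ax.set_ylabel("final score")
    ax.legend(frameon=False)
    return ax
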