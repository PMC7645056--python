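"""Small plotting helpers for cohort-average DVH curves."""

from __future__ import annotations

import numpy as np

from .dvh import PlanRecord, resample_cumulative

__all__ = ["plot_mean_dvh"]


def plot_mean_dvh(plans: list[PlanRecord], structure: str, ax=None, grid_top=55.0):
    """Plot the per-modality mean cumulative DVH of one structure.

    Curves are resampled to a common 0.1-GyE grid and averaged over
    patients within each modality.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.round(np.linspace(0.0, grid_top, int(grid_top * 10) + 1), 10)
    by_mod: dict[str, list[np.ndarray]] = {}
    for plan in plans:
        if structure not in plan.dvhs:
            continue
        cum = resample_cumulative(plan[structure].as_unit("percent"), grid)
        by_mod.setdefault(plan.modality, []).append(cum.values)
    for modality, curves in by_mod.items():
        ax.plot(grid, np.mean(curves, axis=0), label=modality)
    ax.set_xlabel("dose (GyE)")
    ax.set_ylabel("volume (%)")
    ax.set_title(structure)
    ax.legend()
    return ax
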