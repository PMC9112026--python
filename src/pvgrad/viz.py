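"""Band-profile plots: metric value against distance from the ventricles."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_band_profile"]


def plot_band_profile(
    metrics: pd.DataFrame,
    metric: str = "mean_abs_z_above_tau",
    tau: float = 2.0,
    compartment: str = "NAWM",
    ax=None,
    label: str | None = None,
):
    """Plot the cohort-mean per-band profile of one metric with ±2 SE bars.

    ``metrics`` is a (possibly multi-subject) table from
    ``compute_band_metrics``; excluded bands are skipped.
    """
    import matplotlib.pyplot as plt

    sel = metrics[
        (metrics["compartment"] == compartment)
        & (metrics["tau"] == float(tau))
        & ~metrics["band_excluded"]
    ]
    grouped = sel.groupby("band")[metric]
    mean = grouped.mean()
    se = grouped.std(ddof=1) / np.sqrt(grouped.count().clip(lower=1))
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(mean.index, mean.to_numpy(), yerr=2 * se.to_numpy(),
                fmt="o-", capsize=2, label=label)
    ax.set_xlabel("distance from ventricles (mm band)")
    ax.set_ylabel(f"{metric} ({compartment}, tau={tau:g})")
    if label:
        ax.legend()
    return ax
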