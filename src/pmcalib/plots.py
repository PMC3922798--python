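"""Forest plot of city-specific calibration coefficients."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["forest_plot"]


def forest_plot(city_df, pooled=None, ax=None, title=None):
    """Forest plot of per-city calibration coefficients.

    ``city_df`` is the frame from
    :func:`pmcalib.heterogeneity.city_specific_fits`; marker area is
    proportional to the precision (inverse variance) of each coefficient.
    ``pooled`` optionally draws the pooled estimate as a vertical line.
    """
    ok = city_df[city_df["ok"]].reset_index(drop=True)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * max(len(ok), 4) + 1.5))
    y = np.arange(len(ok))[::-1]
    w = ok["weight"].to_numpy(float)
    size = 200.0 * w / np.nanmax(w) if len(w) and np.nanmax(w) > 0 else 40.0
    ax.hlines(y, ok["ci_low"], ok["ci_high"], color="0.4", lw=1.2)
    ax.scatter(ok["estimate"], y, s=size, color="C0", zorder=3)
    ax.axvline(1.0, color="0.7", ls=":", lw=1)
    if pooled is not None:
        ax.axvline(pooled, color="C3", ls="--", lw=1.2, label="pooled")
        ax.legend(loc="best", frameon=False)
    ax.set_yticks(y)
    ax.set_yticklabels(ok["city_id"])
    ax.set_xlabel("calibration coefficient $\\gamma_{1i}$ (95% CI)")
    if title:
        ax.set_title(title)
    excluded = city_df[~city_df["ok"]]
    if len(excluded):
        ax.annotate(
            "excluded: " + ", ".join(excluded["city_id"].astype(str)),
            xy=(0, -0.12), xycoords="axes fraction", fontsize=7, color="0.4",
        )
    ax.figure.tight_layout()
    return ax
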