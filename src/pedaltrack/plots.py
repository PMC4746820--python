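"""Bland–Altman plot rendering (difference vs pair mean)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import BlandAltmanResult, PairsLike, differences


def bland_altman_plot(
    pairs: PairsLike,
    result: BlandAltmanResult,
    path: str | Path,
    title: str | None = None,
) -> None:
    """Scatter of difference against pair mean with bias line (solid),
    95 % limits of agreement (dashed) and the fitted regression (dotted)."""
    df = differences(pairs)
    mean = ((df["criterion"] + df["test"]) / 2.0).to_numpy()
    d = df["diff"].to_numpy()

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(mean, d, s=12, alpha=0.6, edgecolors="none")
    ax.axhline(result.bias, color="k", linestyle="-", label="bias")
    ax.axhline(result.loa_low, color="k", linestyle="--", label="95% LoA")
    ax.axhline(result.loa_high, color="k", linestyle="--")
    if np.isfinite(result.slope) and mean.size > 1:
        xs = np.linspace(mean.min(), mean.max(), 50)
        intercept = d.mean() - result.slope * mean.mean()
        ax.plot(xs, intercept + result.slope * xs, "k:", label="regression")
    ax.set_xlabel("Mean of methods (RPM)")
    ax.set_ylabel("Difference, criterion − test (RPM)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
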