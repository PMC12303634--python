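"""Minimal diagnostic plots: per-SNP scatter with fitted estimator lines."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .harmonize import HarmonizedPairs


def scatter_plot(pairs: HarmonizedPairs, estimates, path: str | Path) -> None:
    """SNP effects on exposure vs outcome, with one fitted line per method.

    Lines pass through the origin except MR-Egger, which keeps its intercept.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        pairs.gamma, pairs.Gamma,
        xerr=pairs.se_gamma, yerr=pairs.se_Gamma,
        fmt="o", ms=3, lw=0.6, color="0.4", ecolor="0.75", zorder=2,
    )
    xs = [min(0.0, pairs.gamma.min()), max(0.0, pairs.gamma.max())]
    for e in estimates:
        icpt = e.intercept if e.intercept is not None else 0.0
        ax.plot(xs, [icpt + e.beta * x for x in xs], lw=1.2, label=e.method, zorder=3)
    ax.axhline(0, color="0.85", lw=0.8, zorder=1)
    ax.axvline(0, color="0.85", lw=0.8, zorder=1)
    ax.set_xlabel(f"SNP effect on {pairs.exposure_id}")
    ax.set_ylabel(f"SNP effect on {pairs.outcome_id}")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
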