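"""Optional figure outputs: cargo-load histograms and brightness-rank plots.

Figures are descriptive outputs only; no computation reads them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .vesicles import GaussianFit, NullDistribution

__all__ = ["plot_load_histogram", "plot_rank_diagnostic"]


def plot_load_histogram(
    loads: np.ndarray,
    null: NullDistribution,
    fit: GaussianFit | None = None,
    n_bins: int = 50,
    out_path: str | Path | None = None,
):
    """Cargo-load frequency distribution with the offset-background
    distribution and the 95th-percentile cutoff (dotted line)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(loads, bins=n_bins, histtype="step", color="crimson",
            label="cargo load (in register)")
    ax2 = ax.twinx()
    ax2.hist(null.background_intensities, bins=n_bins, histtype="step",
             color="black", label="offset background")
    ax2.set_yticks([])
    ax.axvline(null.cutoff, linestyle=":", color="grey",
               label=f"{null.percentile:g}th pct cutoff")
    if fit is not None and fit.converged:
        x = np.linspace(float(np.min(loads)), float(np.max(loads)), 300)
        ax.plot(x, fit.amplitude * np.exp(-0.5 * ((x - fit.mu) / fit.sigma) ** 2),
                color="dimgrey", label="Gaussian fit")
    ax.set_xlabel("mean cargo intensity per vesicle")
    ax.set_ylabel("frequency")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_rank_diagnostic(rank_table, cutoff: float, out_path: str | Path | None = None):
    """Per-vesicle cargo load against defining-channel brightness rank,
    with the cutoff line separating cargo-negative calls."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(rank_table["rank"], rank_table["cargo_load"], s=4,
               c=np.where(rank_table["is_positive"], "crimson", "grey"))
    ax.axhline(cutoff, linestyle=":", color="black")
    ax.set_xlabel("vesicle rank (bright → dim defining channel)")
    ax.set_ylabel("mean cargo intensity")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
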