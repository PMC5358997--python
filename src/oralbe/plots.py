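"""Plotting helpers for trial results (mean with 5th/95th percentile bands)."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .trial_engine import TrialResult

__all__ = ["trial_bands", "plot_trial_profiles"]


def trial_bands(result: TrialResult, lo: float = 5.0, hi: float = 95.0):
    """(times, mean, lower, upper) percentile envelope across subjects."""
    conc = np.vstack([s.concentrations for s in result.subjects])
    times = result.subjects[0].times
    return (times, conc.mean(axis=0),
            np.percentile(conc, lo, axis=0), np.percentile(conc, hi, axis=0))


def plot_trial_profiles(
    results: Sequence[TrialResult],
    labels: Optional[Sequence[str]] = None,
    path: Optional[str] = None,
    title: str = "",
):
    """Mean plasma profiles with 5th/95th percentile bands, one per arm.

    Saves to ``path`` (PNG/SVG by extension) if given, else returns the
    matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    labels = labels or [f"arm {i + 1}" for i in range(len(results))]
    for i, (res, label) in enumerate(zip(results, labels)):
        t, mean, lo, hi = trial_bands(res)
        c = colors[i % len(colors)]
        ax.plot(t, mean, color=c, label=label)
        ax.fill_between(t, lo, hi, color=c, alpha=0.15)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
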