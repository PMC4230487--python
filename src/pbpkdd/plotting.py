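"""Concentration-time plotting helpers."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_mean_profile"]


def plot_mean_profile(
    t: np.ndarray,
    concentrations: np.ndarray,
    path: str | Path,
    label: str = "simulated",
    ylabel: str = "plasma concentration (ng/mL)",
    logy: bool = False,
) -> Path:
    """Plot the across-subject mean +/- SE concentration-time course.

    ``concentrations`` has one row per subject on the common grid ``t``.
    Returns the written file path.
    """
    c = np.atleast_2d(np.asarray(concentrations, dtype=float))
    mean = c.mean(axis=0)
    se = c.std(axis=0, ddof=1) / np.sqrt(c.shape[0]) if c.shape[0] > 1 else np.zeros_like(mean)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t, mean, color="black", lw=1.5, label=label)
    if se.any():
        ax.fill_between(t, mean - se, mean + se, color="grey", alpha=0.4)
    ax.set_xlabel("time (h)")
    ax.set_ylabel(ylabel)
    if logy:
        ax.set_yscale("log")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
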