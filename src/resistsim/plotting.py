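"""Plotting helpers: resistance trajectories and the decision plane.

Purely presentational; no computed values originate here.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .sensitivity import DecisionLine, compare_strategies

__all__ = ["plot_trajectory", "plot_decision_plane"]


def plot_trajectory(trajectory: pd.DataFrame, path, log_scale: bool = True) -> Path:
    """Sex-averaged R-allele frequencies and LD over generations."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    gen = trajectory["generation"]
    q1 = (trajectory["freq_R1_m"] + trajectory["freq_R1_f"]) / 2
    q2 = (trajectory["freq_R2_m"] + trajectory["freq_R2_f"]) / 2
    ax.plot(gen, q1, label="R allele, locus 1", color="tab:blue")
    ax.plot(gen, q2, label="R allele, locus 2", color="tab:orange")
    ax.plot(gen, trajectory["LD"].abs(), label="|LD|", color="tab:grey", ls="--")
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("generation")
    ax.set_ylabel("frequency")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_decision_plane(
    records: pd.DataFrame,
    line: DecisionLine | None,
    path,
    pair: str = "adaptive",
) -> Path:
    """Exposure vs summed effectiveness, coloured by the difference in
    time to resistance between the mixture-type and sequential strategies,
    with the fitted decision line overlaid (omitted when None)."""
    labelled = compare_strategies(records, line.margin if line else 0.0, pair=pair)
    fig, ax = plt.subplots(figsize=(7, 5))
    sc = ax.scatter(
        labelled["exposure"],
        labelled["effectiveness_sum"],
        c=labelled["time_diff"],
        cmap="RdYlGn",
        s=8,
        alpha=0.7,
    )
    fig.colorbar(sc, ax=ax, label="time difference (generations)")
    if line is not None:
        x = np.linspace(labelled["exposure"].min(), labelled["exposure"].max(), 50)
        ax.plot(x, line.intercept + line.slope * x, color="red", lw=2, label="decision line")
        ax.legend()
    ax.set_xlim(labelled["exposure"].min() - 0.02, labelled["exposure"].max() + 0.02)
    ax.set_ylim(
        labelled["effectiveness_sum"].min() - 0.05,
        labelled["effectiveness_sum"].max() + 0.05,
    )
    ax.set_xlabel("exposure")
    ax.set_ylabel("summed effectiveness")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
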