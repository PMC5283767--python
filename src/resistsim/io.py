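"""CSV writers/readers for trajectories, outcome summaries and
sensitivity records.

Column order is deterministic and values round-trip exactly (pandas
writes shortest-round-trip float representations).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .deployment import StrategyOutcome

__all__ = [
    "TRAJECTORY_COLUMNS",
    "write_trajectory",
    "read_trajectory",
    "write_outcome_summary",
    "write_records",
    "read_records",
]

TRAJECTORY_COLUMNS = [
    "generation",
    "freq_R1_m",
    "freq_R1_f",
    "freq_R2_m",
    "freq_R2_f",
    "LD",
    "mean_fitness",
    "deployment_label",
]

SUMMARY_COLUMNS = [
    "strategy",
    "t_first",
    "t_both",
    "censored",
    "cross_locus1",
    "cross_locus2",
]


def write_trajectory(outcome: StrategyOutcome, path) -> Path:
    """One row per generation, including generation 0."""
    if outcome.trajectory is None:
        frame = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    else:
        frame = outcome.trajectory[TRAJECTORY_COLUMNS]
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_outcome_summary(outcomes, path) -> Path:
    """Per-strategy summary: times to threshold, censoring, per-insecticide
    crossing generations."""
    rows = [o.summary() for o in outcomes]
    path = Path(path)
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)
    return path


def write_records(records: pd.DataFrame, path) -> Path:
    """Sensitivity-analysis records, one row per run."""
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)
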