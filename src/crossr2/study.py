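"""Orchestration of the simulation study: grid x replications -> summaries.

A grid cell is a :class:`~crossr2.simulate.SimulationConfig`; for each
replication a dataset is generated and all six indices computed.  The
per-replication seed is derived from the cell's master seed by a counter
scheme (``default_rng([seed, replication])``), so results are a
deterministic function of (grid, seed) and independent of execution order.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from .comparators import INDEX_NAMES, all_indices
from .simulate import SimulationConfig, generate_dataset

_CELL_KEYS = (
    "covariate_law", "beta", "event_law", "censoring_law",
    "target_censoring", "n",
)


def run_cell(config: SimulationConfig, long: bool = False):
    """Run one grid cell: per-index mean, standard error and quartiles.

    Replications that fail (degenerate draws) are excluded and counted in
    ``n_failed``.  With ``long=True`` also returns the per-replication
    long-format table.
    """
    rows = []
    n_failed = 0
    for rep in range(config.replications):
        seed = np.random.default_rng([config.seed, rep])
        try:
            data, _ = generate_dataset(config, seed=seed)
            rows.append(all_indices(data, "z"))
        except ValueError:
            n_failed += 1
    values = pd.DataFrame(rows, columns=list(INDEX_NAMES))
    summary = {k: getattr(config, k) for k in _CELL_KEYS}
    summary.update(seed=config.seed, replications=len(values), n_failed=n_failed)
    for name in INDEX_NAMES:
        v = values[name].dropna()
        summary[f"{name}_mean"] = v.mean()
        summary[f"{name}_se"] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
        summary[f"{name}_q25"] = v.quantile(0.25)
        summary[f"{name}_q50"] = v.quantile(0.50)
        summary[f"{name}_q75"] = v.quantile(0.75)
    if not long:
        return summary
    long_df = values.reset_index(names="replication").melt(
        id_vars="replication", var_name="index", value_name="value"
    )
    for k in _CELL_KEYS:
        long_df[k] = getattr(config, k)
    return summary, long_df


def expand_grid(grid: dict) -> list[SimulationConfig]:
    """Expand a grid mapping (lists per SimulationConfig field) into cells.

    Scalar values are broadcast; ``e_beta`` may be given instead of
    ``beta`` and is converted by ``beta = log(e_beta)``.
    """
    grid = dict(grid)
    reps = grid.pop("replications", 1000)
    seed = grid.pop("seed", 0)
    if "e_beta" in grid:
        eb = grid.pop("e_beta")
        grid["beta"] = [float(np.log(v)) for v in np.atleast_1d(eb)]
    keys = list(grid)
    lists = [np.atleast_1d(grid[k]).tolist() for k in keys]
    cells = []
    for combo in itertools.product(*lists):
        kwargs = dict(zip(keys, combo))
        kwargs.setdefault("replications", reps)
        kwargs.setdefault("seed", seed)
        cells.append(SimulationConfig(**kwargs))
    return cells


def run_grid(
    grid: dict | list[SimulationConfig],
    replications: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every cell of a grid; returns (summary table, long table)."""
    cells = expand_grid(grid) if isinstance(grid, dict) else list(grid)
    if replications is not None:
        cells = [dataclasses.replace(c, replications=replications) for c in cells]
    summaries, longs = [], []
    for cell in cells:
        summary, long_df = run_cell(cell, long=True)
        summaries.append(summary)
        longs.append(long_df)
    return pd.DataFrame(summaries), pd.concat(longs, ignore_index=True)


def plot_boxplots(long_df: pd.DataFrame, path: str | Path) -> None:
    """Boxplots of index distributions by effect size and censoring level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pcs = sorted(long_df["target_censoring"].unique())
    names = [n for n in INDEX_NAMES if n in long_df["index"].unique()]
    fig, axes = plt.subplots(
        len(pcs), len(names), figsize=(3 * len(names), 2.5 * len(pcs)),
        squeeze=False, sharey=True,
    )
    for i, pc in enumerate(pcs):
        for j, name in enumerate(names):
            sub = long_df[
                (long_df["target_censoring"] == pc) & (long_df["index"] == name)
            ]
            betas = sorted(sub["beta"].unique())
            axes[i][j].boxplot(
                [sub[sub["beta"] == b]["value"].dropna() for b in betas],
                tick_labels=[f"{np.exp(b):.0f}" for b in betas],
                flierprops={"markersize": 2},
            )
            if i == 0:
                axes[i][j].set_title(name)
            if j == 0:
                axes[i][j].set_ylabel(f"p_c = {pc:.0%}")
            if i == len(pcs) - 1:
                axes[i][j].set_xlabel("e^beta")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
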