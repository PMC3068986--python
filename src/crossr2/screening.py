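"""Genome-wide marker screening: rank markers by separability indices.

Mirrors the workflow used to screen transcriptomic markers for crossing
prognostic effects: score every row of a markers-by-samples expression
matrix against a shared survival outcome, rank by index value, take a
fixed top-N, compare the selections of different indices, and inspect a
candidate pair of markers through median dichotomisation, group
Kaplan-Meier curves and Cox hazard ratios against the worst-prognosis
reference group.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .comparators import (
    all_indices,
    allison_r2,
    cox_fit_univariate,
)
from .datasets import SurvivalDataset
from .index import index_matrix

_INDEX_ALIASES = {"d0": "D0", "dph": "D_PH"}
_CHUNK_ROWS = 4096


def _canonical(indices) -> list[str]:
    return [_INDEX_ALIASES.get(str(i).lower(), str(i)) for i in indices]


def screen_markers(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame | SurvivalDataset,
    indices=("d0", "dph"),
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Score and rank every marker row of an expression matrix.

    ``matrix`` is markers x samples (index = marker id); ``metadata`` is a
    per-sample table with time/event columns whose index matches the
    matrix columns.  Markers are scored independently (flat markers score
    0); larger-than-memory matrices are handled exactly by row chunking
    since scores are row-separable.  Returns a table with one row per
    marker: index values and dense ranks (1 = best), ties broken by marker
    id.
    """
    if isinstance(metadata, SurvivalDataset):
        time, event = metadata.time, metadata.event
        if matrix.shape[1] != time.shape[0]:
            raise ValueError("matrix/metadata misalignment")
    else:
        if not matrix.columns.isin(metadata.index).all():
            raise ValueError("matrix/metadata misalignment")
        meta = metadata.loc[matrix.columns]
        time = meta[time_col].to_numpy(dtype=float)
        event = meta[event_col].to_numpy()
    if np.asarray(event).sum() == 0:
        raise ValueError("no observed failures")

    names = _canonical(indices)
    out = pd.DataFrame(index=matrix.index.copy())
    fast = {"D0": "crossing", "D_PH": "proportional"}
    for name in names:
        if name in fast:
            vals = np.concatenate(
                [
                    index_matrix(time, event, matrix.iloc[i : i + _CHUNK_ROWS].to_numpy(),
                                 mode=fast[name])
                    for i in range(0, matrix.shape[0], _CHUNK_ROWS)
                ]
            )
        elif name == "allison":
            vals = np.empty(matrix.shape[0])
            for i in range(matrix.shape[0]):
                row = matrix.iloc[i].to_numpy(dtype=float)
                ds = SurvivalDataset(time, event, pd.DataFrame({"z": row}))
                vals[i] = allison_r2(cox_fit_univariate(ds, "z"), ds.n)
        else:
            raise ValueError(f"unknown index {name!r}")
        out[name] = vals
    # rank descending by value, ties broken deterministically by marker id
    for name in names:
        order = np.lexsort((out.index.to_numpy(), -out[name].to_numpy()))
        ranks = np.empty(len(out), dtype=np.int64)
        ranks[order] = np.arange(1, len(out) + 1)
        out[f"{name}_rank"] = ranks
    return out


def top_n(table: pd.DataFrame, index_name: str, n: int) -> pd.Index:
    """Marker ids of the top-N selection for one index."""
    name = _canonical([index_name])[0]
    return table.index[table[f"{name}_rank"] <= n]


def top_n_overlap(
    table: pd.DataFrame, index_a: str, index_b: str, n: int
) -> tuple[float, pd.Index, pd.Index]:
    """Fraction of shared markers between two indices' top-N selections."""
    if n > len(table):
        raise ValueError("cutoff exceeds marker count")
    sel_a = top_n(table, index_a, n)
    sel_b = top_n(table, index_b, n)
    return len(sel_a.intersection(sel_b)) / n, sel_a, sel_b


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Four-group dichotomisation report for a pair of markers."""

    groups: pd.DataFrame  # per group: label, n, n_events, HR, CI
    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # group -> KM curve
    flags: list[str]


def dichotomize_and_compare(
    data: SurvivalDataset, marker_a: str, marker_b: str
) -> GroupComparison:
    """Median-dichotomise two markers and compare the four groups.

    "High" means strictly above the sample median (exact-median ties go to
    "low").  The low/low group is the reference; the other groups get a
    Cox hazard ratio with 95% CI versus the reference, plus a
    Kaplan-Meier curve each.  Empty groups are flagged and their HR
    omitted.
    """
    from lifelines import KaplanMeierFitter

    za = data.marker(marker_a)
    zb = data.marker(marker_b)
    flags: list[str] = []
    if np.all(za == za[0]) or np.all(zb == zb[0]):
        raise ValueError("cannot dichotomize a constant marker")
    high_a = za > np.median(za)
    high_b = zb > np.median(zb)
    labels = {
        (False, False): "low/low",
        (True, False): "high/low",
        (False, True): "low/high",
        (True, True): "high/high",
    }
    group = np.array([labels[(a, b)] for a, b in zip(high_a, high_b)])
    ref_mask = group == "low/low"
    if ref_mask.sum() == 0:
        flags.append("empty reference group low/low")
    rows = []
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label in labels.values():
        mask = group == label
        n_g = int(mask.sum())
        row = {
            "group": label,
            "n": n_g,
            "n_events": int(data.event[mask].sum()),
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
        if n_g == 0:
            flags.append(f"empty group {label}")
            rows.append(row)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(data.time[mask], event_observed=data.event[mask])
        times = np.unique(data.time[mask])
        curves[label] = (times, np.atleast_1d(kmf.predict(times).to_numpy(dtype=float)))
        if label != "low/low" and ref_mask.sum() > 0:
            sel = mask | ref_mask
            contrast = mask[sel].astype(float)
            sub = SurvivalDataset(
                data.time[sel], data.event[sel], pd.DataFrame({"g": contrast})
            )
            if sub.event.sum() > 0:
                fit = cox_fit_univariate(sub, "g")
                if np.isfinite(fit.se_beta):
                    row["hr"] = float(np.exp(fit.beta_hat))
                    row["ci_low"] = float(np.exp(fit.beta_hat - 1.96 * fit.se_beta))
                    row["ci_high"] = float(np.exp(fit.beta_hat + 1.96 * fit.se_beta))
        rows.append(row)
    return GroupComparison(groups=pd.DataFrame(rows), curves=curves, flags=flags)
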