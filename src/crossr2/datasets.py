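"""Subject-level survival data and risk-set construction.

The central container is :class:`SurvivalDataset`: per-subject follow-up
time ``T_i = min(X_i, C_i)``, event indicator ``delta_i`` (1 = failure
observed, 0 = censored), and one or more marker columns ``Z_i``.  From it we
build a :class:`RiskSetTable` — the scaffold on the grid of distinct
observed times that every index computation consumes: at-risk counts
``n(t)``, event counts ``d(t)``, risk-set covariate means ``Ebar(t)``, and
the left-continuous Nelson–Aalen cumulative hazard.

Conventions
-----------
* Ties between failures and censorings at the same time are resolved by
  keeping the censored subjects in the risk set at that time (censoring
  happens "after" failure).
* Times are compared with exact floating-point equality; near-ties are the
  caller's responsibility.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class SurvivalDataset:
    """Validated per-subject survival data.

    Parameters
    ----------
    time : array of positive follow-up times, one per subject.
    event : array of 0/1 event indicators (1 = failure observed).
    markers : DataFrame of marker values, one column per marker, one row
        per subject.  May be empty for purely nonparametric estimates.
    """

    time: np.ndarray
    event: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("invalid follow-up time")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("invalid event indicator")
        if len(self.markers) not in (0, len(time)):
            raise ValueError("marker column length must equal time column length")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int64))

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def marker(self, name: str | None = None) -> np.ndarray:
        """Return one marker column as a float array.

        With ``name=None`` the dataset must contain exactly one marker.
        """
        if name is None:
            if self.markers.shape[1] != 1:
                raise ValueError(
                    "dataset has %d marker columns; specify one by name"
                    % self.markers.shape[1]
                )
            name = self.markers.columns[0]
        return self.markers[name].to_numpy(dtype=float)

    def marker_names(self) -> list[str]:
        return list(self.markers.columns)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"time": self.time, "event": self.event})
        return pd.concat([frame, self.markers.reset_index(drop=True)], axis=1)


@dataclasses.dataclass(frozen=True)
class RiskSetTable:
    """Risk-set quantities on the grid of distinct observed times.

    ``at_risk[j]`` counts subjects with ``T_i >= distinct_times[j]``,
    ``events[j]`` counts failures exactly at that time, ``cumhaz_left[j]``
    is the left-continuous Nelson–Aalen value ``Lambda(t-)`` and
    ``covariate_mean[j]`` the risk-set mean of the marker (when one was
    supplied).  ``k`` is the number of distinct uncensored failure times.
    """

    distinct_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    cumhaz_left: np.ndarray
    covariate_mean: np.ndarray | None
    k: int

    def event_rows(self) -> np.ndarray:
        """Boolean mask of rows at which at least one failure occurs."""
        return self.events > 0

    def to_frame(self, survival: np.ndarray | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "time": self.distinct_times,
                "n_risk": self.at_risk,
                "n_event": self.events,
                "cumhaz_left": self.cumhaz_left,
            }
        )
        if self.covariate_mean is not None:
            frame["covariate_mean"] = self.covariate_mean
        if survival is not None:
            frame["survival"] = survival
        return frame


def validate_dataset(
    table: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    marker_cols: list[str] | None = None,
) -> SurvivalDataset:
    """Validate a raw delimited-text table into a :class:`SurvivalDataset`.

    Rows violating the invariants are rejected, never coerced: non-positive
    or missing times raise ``invalid follow-up time``, event values outside
    {0, 1} raise ``invalid event indicator`` and a table without a single
    observed failure raises ``no observed failures``.
    """
    for col in (time_col, event_col):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    time = pd.to_numeric(table[time_col], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("invalid follow-up time")
    event_raw = pd.to_numeric(table[event_col], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(event_raw)) or not np.isin(event_raw, (0.0, 1.0)).all():
        raise ValueError("invalid event indicator")
    event = event_raw.astype(np.int64)
    if event.sum() == 0:
        raise ValueError("no observed failures")
    if marker_cols is None:
        marker_cols = [c for c in table.columns if c not in (time_col, event_col)]
    markers = table[marker_cols].astype(float).reset_index(drop=True)
    return SurvivalDataset(time=time, event=event, markers=markers)


def read_survival_table(
    path: str | Path,
    time_col: str = "time",
    event_col: str = "event",
    marker_cols: list[str] | None = None,
) -> SurvivalDataset:
    """Read a CSV/TSV survival table (delimiter auto-detected by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return validate_dataset(
        pd.read_csv(path, sep=sep), time_col=time_col, event_col=event_col,
        marker_cols=marker_cols,
    )


def build_risk_table(
    data: SurvivalDataset, marker: str | np.ndarray | None = None
) -> RiskSetTable:
    """Build the distinct-time risk-set table.

    ``marker`` may be a column name, an explicit per-subject array, or
    ``None`` (no covariate means).
    """
    time = data.time
    event = data.event
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    distinct = np.unique(t_sorted)
    # subjects with T >= t remain at risk (failure/censoring ties kept in)
    at_risk = data.n - np.searchsorted(t_sorted, distinct, side="left")
    d = np.zeros(distinct.shape[0], dtype=np.int64)
    event_times = time[event == 1]
    idx = np.searchsorted(distinct, event_times)
    np.add.at(d, idx, 1)
    # left-continuous Nelson-Aalen: sum of d/n over distinct times strictly before t
    increments = d / at_risk
    cumhaz_left = np.concatenate(([0.0], np.cumsum(increments)[:-1]))
    cov_mean = None
    if marker is not None:
        z = data.marker(marker) if isinstance(marker, str) else np.asarray(marker, float)
        z_sorted = z[order]
        # suffix sums give risk-set covariate totals
        suffix = np.concatenate((np.cumsum(z_sorted[::-1])[::-1], [0.0]))
        start = np.searchsorted(t_sorted, distinct, side="left")
        cov_mean = suffix[start] / at_risk
    elif data.markers.shape[1] == 1:
        return build_risk_table(data, data.markers.columns[0])
    return RiskSetTable(
        distinct_times=distinct,
        at_risk=at_risk,
        events=d,
        cumhaz_left=cumhaz_left,
        covariate_mean=cov_mean,
        k=int((d > 0).sum()),
    )


def nelson_aalen_left(data: SurvivalDataset) -> tuple[np.ndarray, np.ndarray]:
    """Left-continuous Nelson–Aalen values ``Lambda(t-)`` at distinct times.

    ``Lambda(t-) = sum_{t_j < t} d(t_j) / n(t_j)``; the value at the
    earliest distinct time is 0.  Returns ``(distinct_times, values)``.
    """
    table = build_risk_table(SurvivalDataset(data.time, data.event, pd.DataFrame()))
    return table.distinct_times, table.cumhaz_left


def kaplan_meier(data: SurvivalDataset) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous product-limit survival estimate at distinct times.

    Returns ``(distinct_times, S_hat)`` with ``S_hat(0) = 1`` implicit
    (values are the post-jump estimates at each distinct observed time).
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=data.event)
    table = build_risk_table(SurvivalDataset(data.time, data.event, pd.DataFrame()))
    surv = kmf.predict(table.distinct_times).to_numpy(dtype=float)
    return table.distinct_times, np.atleast_1d(surv)


def count_distinct_event_times(data: SurvivalDataset) -> int:
    """Number of distinct times with at least one observed failure (``k``)."""
    if data.n_events == 0:
        raise ValueError("no observed failures")
    return int(np.unique(data.time[data.event == 1]).shape[0])


def write_risk_table(data: SurvivalDataset, path: str | Path) -> None:
    """Write the risk table with survival curve as TSV."""
    table = build_risk_table(data)
    _, surv = kaplan_meier(data)
    table.to_frame(survival=surv).to_csv(path, sep="\t", index=False)
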