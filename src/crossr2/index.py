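"""The crossing-hazards pseudo-R2 index D0 and its proportional-hazards twin.

The index is built from the score function of the crossing-hazards model
evaluated at beta = 0.  Each failing subject contributes a weighted score

    U_i = omega(t_i) * delta_i * (Z_i - Ebar(t_i)),

where ``Ebar(t)`` is the risk-set mean of the marker and the weight is
``omega(s) = 1 + log Lambda0(s)`` under the crossing model (the
proportional-hazards variant simply sets ``omega = 1``).  ``Lambda0`` is
plugged in as the left-continuous Nelson–Aalen estimate.

Because the U_i are not independent, the index uses the robust
(Lin–Wei-type) score residuals

    W_i = U_i - sum_{event times t_j <= T_i} omega(t_j) (Z_i - Ebar(t_j)) d(t_j)/n(t_j),

whose sum equals the sum of the U_i exactly (the compensator sums to zero
over the risk sets).  The index is the robust score statistic divided by
the number of distinct uncensored failure times k:

    D0 = (sum_i W_i)^2 / (k * sum_i W_i^2),

interpreted as a percentage of separability over time between subjects
experiencing the event and those experiencing it later.  The value lies
in [0, 1] throughout the regimes the index is meant for (untied or
finely-resolved failure times, moderate censoring); heavily tied times
shrink k below the event count and can push the ratio above 1 — see the
methods notes.  No regression coefficient is estimated at any point, so
the index is cheap enough for genome-wide screens.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datasets import RiskSetTable, SurvivalDataset


@dataclasses.dataclass(frozen=True)
class IndexResult:
    """An index value in [0, 1] together with its audit components."""

    value: float
    sum_U: float
    sum_W: float
    sum_W_sq: float
    k: int
    mode: str
    per_subject_W: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "sum_U": self.sum_U,
            "sum_W": self.sum_W,
            "sum_W_sq": self.sum_W_sq,
            "k": self.k,
            "mode": self.mode,
        }


def _omega_from_parts(
    cumhaz_left_events: np.ndarray,
    first_increment: float,
    mode: str,
    first_event_weight: str,
) -> np.ndarray:
    if mode == "proportional":
        return np.ones_like(cumhaz_left_events)
    if mode != "crossing":
        raise ValueError(f"unknown weight mode {mode!r}")
    lam = cumhaz_left_events.copy()
    if lam.size and lam[0] == 0.0:
        if first_event_weight == "right_continuous":
            # Lambda(t1-) = 0 makes log diverge; use the right-continuous
            # value d1/n1 for the earliest event time only.
            lam[0] = first_increment
        elif first_event_weight == "drop_term":
            lam[0] = np.nan  # marked; weight zeroed below
        else:
            raise ValueError(f"unknown first_event_weight {first_event_weight!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 + np.log(lam)
    return np.nan_to_num(w, nan=0.0)


def omega_weights(
    risk_table: RiskSetTable,
    mode: str = "crossing",
    first_event_weight: str = "right_continuous",
) -> np.ndarray:
    """Weight ``omega`` at each distinct event time.

    Crossing mode: ``1 + log Lambda(t-)`` with the left-continuous
    Nelson–Aalen plug-in; the earliest event time, where the left limit is
    0, uses the right-continuous value ``d1/n1`` inside the log
    (``first_event_weight="right_continuous"``) or is dropped entirely
    (``"drop_term"``).  Proportional mode returns 1 at every event time.
    """
    ev = risk_table.event_rows()
    cumhaz_ev = risk_table.cumhaz_left[ev]
    d = risk_table.events[ev]
    n = risk_table.at_risk[ev]
    first_inc = float(d[0] / n[0]) if d.size else 0.0
    return _omega_from_parts(cumhaz_ev, first_inc, mode, first_event_weight)


def _score_matrix(
    time: np.ndarray,
    event: np.ndarray,
    Z: np.ndarray,
    mode: str,
    first_event_weight: str,
):
    """Score components for an (m, n) marker matrix in one vectorised pass.

    Returns ``(U, W, k)`` where ``U`` and ``W`` are (m, n) per-subject
    contribution matrices.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    # centring is neutral (risk-set means absorb any shift) but keeps the
    # suffix-sum arithmetic well conditioned; flat markers are zeroed
    # outright so they cannot accumulate rounding noise
    Z = np.where(
        (np.ptp(Z, axis=1) == 0)[:, None], 0.0, Z - Z.mean(axis=1, keepdims=True)
    )
    n = time.shape[0]
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]

    distinct = np.unique(t_sorted)
    start = np.searchsorted(t_sorted, distinct, side="left")
    at_risk = n - start
    d = np.zeros(distinct.shape[0], dtype=np.int64)
    np.add.at(d, np.searchsorted(distinct, time[event == 1]), 1)

    ev = d > 0
    t_ev = distinct[ev]
    d_ev = d[ev].astype(float)
    n_ev = at_risk[ev].astype(float)
    k = int(ev.sum())
    if k == 0:
        raise ValueError("no observed failures")

    # risk-set covariate means at event times, per marker
    Z_sorted = Z[:, order]
    suffix = np.concatenate(
        (np.cumsum(Z_sorted[:, ::-1], axis=1)[:, ::-1], np.zeros((Z.shape[0], 1))),
        axis=1,
    )
    ebar = suffix[:, start[ev]] / n_ev  # (m, k)

    increments = d_ev / n_ev
    cumhaz_left_ev = np.concatenate(([0.0], np.cumsum(increments)[:-1]))
    # a censored observation before the first failure keeps Lambda(t1-) at 0
    omega = _omega_from_parts(cumhaz_left_ev, increments[0], mode, first_event_weight)

    # U_i: failing subjects only
    U = np.zeros_like(Z)
    fail = event == 1
    j_fail = np.searchsorted(t_ev, time[fail])
    U[:, fail] = omega[j_fail] * (Z[:, fail] - ebar[:, j_fail])

    # compensator: sum over event times t_j <= T_i of omega_j (Z_i - ebar_j) d_j/n_j
    a = np.concatenate(([0.0], np.cumsum(omega * increments)))
    b = np.concatenate(
        (np.zeros((Z.shape[0], 1)), np.cumsum(omega * increments * ebar, axis=1)),
        axis=1,
    )
    j_upto = np.searchsorted(t_ev, time, side="right")
    W = U - (Z * a[j_upto] - b[:, j_upto])
    return U, W, k


def score_contributions_U(
    data: SurvivalDataset,
    marker: str | np.ndarray | None = None,
    mode: str = "crossing",
    first_event_weight: str = "right_continuous",
) -> np.ndarray:
    """Per-subject weighted score contributions ``U_i`` (0 for censored)."""
    z = data.marker(marker) if marker is None or isinstance(marker, str) else np.asarray(marker, float)
    U, _, _ = _score_matrix(data.time, data.event, z, mode, first_event_weight)
    return U[0]


def robust_scores_W(
    data: SurvivalDataset,
    marker: str | np.ndarray | None = None,
    mode: str = "crossing",
    first_event_weight: str = "right_continuous",
) -> np.ndarray:
    """Per-subject robust score residuals ``W_i`` (defined for every subject)."""
    z = data.marker(marker) if marker is None or isinstance(marker, str) else np.asarray(marker, float)
    _, W, _ = _score_matrix(data.time, data.event, z, mode, first_event_weight)
    return W[0]


def _index(
    data: SurvivalDataset,
    marker,
    mode: str,
    first_event_weight: str,
    keep_W: bool,
) -> IndexResult:
    z = data.marker(marker) if marker is None or isinstance(marker, str) else np.asarray(marker, float)
    U, W, k = _score_matrix(data.time, data.event, z, mode, first_event_weight)
    sum_U = float(U.sum())
    sum_W = float(W.sum())
    sum_W_sq = float((W**2).sum())
    # a flat marker has no dispersion anywhere: separability 0 by convention
    value = sum_W**2 / (k * sum_W_sq) if sum_W_sq > 0 else 0.0
    return IndexResult(
        value=value,
        sum_U=sum_U,
        sum_W=sum_W,
        sum_W_sq=sum_W_sq,
        k=k,
        mode=mode,
        per_subject_W=W[0] if keep_W else None,
    )


def d0_index(
    data: SurvivalDataset,
    marker: str | np.ndarray | None = None,
    first_event_weight: str = "right_continuous",
    keep_W: bool = False,
) -> IndexResult:
    """The crossing-hazards separability index D0 for one marker.

    Deterministic and requiring no estimation of the regression
    coefficient of the crossing model; in [0, 1] whenever failure times
    are not heavily tied (see module notes).
    """
    return _index(data, marker, "crossing", first_event_weight, keep_W)


def d_ph_index(
    data: SurvivalDataset,
    marker: str | np.ndarray | None = None,
    keep_W: bool = False,
) -> IndexResult:
    """The proportional-hazards counterpart of D0 (``omega = 1``)."""
    return _index(data, marker, "proportional", "right_continuous", keep_W)


def index_matrix(
    time: np.ndarray,
    event: np.ndarray,
    Z: np.ndarray,
    mode: str = "crossing",
    first_event_weight: str = "right_continuous",
) -> np.ndarray:
    """Index values for all rows of an (m, n) marker matrix at once.

    Used by the screening pipeline; identical to calling :func:`d0_index`
    (or :func:`d_ph_index`) row by row.
    """
    _, W, k = _score_matrix(
        np.asarray(time, float), np.asarray(event), Z, mode, first_event_weight
    )
    sum_W = W.sum(axis=1)
    sum_W_sq = (W**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = sum_W**2 / (k * sum_W_sq)
    return np.where(sum_W_sq > 0, vals, 0.0)
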