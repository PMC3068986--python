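"""Closed-form crossing-hazards models.

Two constructions are implemented.

1. The semi-parametric crossing model for a single covariate ``Z``:

       S(t | Z) = exp(-Lambda0(t) ** exp(beta * Z))

   For binary ``Z`` the hazard ratio of group 1 versus group 0 is
   ``exp(beta) * Lambda0(t) ** (exp(beta) - 1)``, which is monotone in ``t``
   and equals 1 at a single crossing time ``tau`` whenever ``beta != 0`` —
   the hazards of the two groups cross there.

2. The modulating-effect (effect-modification) model for a pair of binary
   markers ``(Z1, Z2)``: conditional on both markers the hazard is
   proportional, ``lambda0(t) * exp(gamma*Z2 + alpha*Z1*Z2)``, i.e. ``Z1``
   acts only when ``Z2 = 1``.  Marginalising over a hidden ``Z2`` induces
   crossing hazards for ``Z1`` — the mechanism that motivates screening for
   crossing effects in genomic data.

Baseline cumulative hazards are restricted to named parametric families
(identity and power/Weibull) so that the crossing-time solvers stay in
closed form or on a safe bracket.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq


@dataclasses.dataclass(frozen=True)
class BaselineCumhaz:
    """A named parametric baseline cumulative hazard ``Lambda0``.

    family ``identity``: ``Lambda0(t) = t`` (unit exponential baseline).
    family ``power``: ``Lambda0(t) = (t / eta) ** shape`` (Weibull baseline).
    """

    family: str = "identity"
    shape: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("identity", "power"):
            raise ValueError(f"unknown baseline family {self.family!r}")
        if self.shape <= 0 or self.eta <= 0:
            raise ValueError("baseline parameters must be positive")

    def cumhaz(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "identity":
            return t
        return (t / self.eta) ** self.shape

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "identity":
            return np.ones_like(t)
        return (self.shape / self.eta) * (t / self.eta) ** (self.shape - 1.0)

    def inverse(self, u):
        u = np.asarray(u, dtype=float)
        if self.family == "identity":
            return u
        return self.eta * u ** (1.0 / self.shape)

    def survival(self, t):
        return np.exp(-self.cumhaz(t))


IDENTITY = BaselineCumhaz("identity")


@dataclasses.dataclass(frozen=True)
class CrossingModelSpec:
    """Semi-parametric crossing model: ``S(t|z) = exp(-Lambda0(t)^exp(beta*z))``."""

    beta: float
    baseline_cumhaz: BaselineCumhaz = IDENTITY


@dataclasses.dataclass(frozen=True)
class ModulatingModelSpec:
    """Effect-modification model for two binary markers.

    ``joint_probs[z1, z2]`` is ``P(Z1 = z1, Z2 = z2)``; ``alpha`` is the
    interaction coefficient (effect of Z1 present only when Z2 = 1) and
    ``gamma`` the main effect of Z2.
    """

    alpha: float
    gamma: float
    joint_probs: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full((2, 2), 0.25)
    )
    baseline_cumhaz: BaselineCumhaz = IDENTITY

    def __post_init__(self) -> None:
        p = np.asarray(self.joint_probs, dtype=float)
        if p.shape != (2, 2) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("joint_probs must be a 2x2 non-negative table summing to 1")
        if np.any(np.isclose(p.sum(axis=1), 0)) or np.any(np.isclose(p.sum(axis=0), 0)):
            raise ValueError("both marginals of joint_probs must be non-degenerate")
        object.__setattr__(self, "joint_probs", p)

    def cell_log_hazard_ratio(self, z1: int, z2: int) -> float:
        """log hazard multiplier ``gamma*z2 + alpha*z1*z2`` for one cell."""
        return self.gamma * z2 + self.alpha * z1 * z2


def crossing_survival(spec: CrossingModelSpec, t, z):
    """``S(t | z) = exp(-Lambda0(t) ** exp(beta z))``, in (0, 1]."""
    lam = spec.baseline_cumhaz.cumhaz(t)
    return np.exp(-np.power(lam, np.exp(spec.beta * np.asarray(z, float))))


def crossing_hazard(spec: CrossingModelSpec, t, z):
    """Hazard ``exp(beta z) * lambda0(t) * Lambda0(t)^(exp(beta z) - 1)``.

    Diverges (returns ``inf``) at ``t = 0`` when ``exp(beta z) < 1``.
    """
    t = np.asarray(t, dtype=float)
    theta = np.exp(spec.beta * np.asarray(z, float))
    lam = spec.baseline_cumhaz.cumhaz(t)
    with np.errstate(divide="ignore"):
        out = theta * spec.baseline_cumhaz.hazard(t) * np.power(lam, theta - 1.0)
    return out


def hazard_ratio_binary(spec: CrossingModelSpec, t):
    """Hazard ratio of group Z=1 vs Z=0: ``exp(beta) Lambda0(t)^(exp(beta)-1)``."""
    eb = np.exp(spec.beta)
    lam = spec.baseline_cumhaz.cumhaz(t)
    with np.errstate(divide="ignore"):
        return eb * np.power(lam, eb - 1.0)


def crossing_time(spec: CrossingModelSpec) -> float:
    """The time ``tau`` at which the binary-group hazard ratio equals 1.

    Closed form: ``Lambda0(tau) = exp(-beta / (exp(beta) - 1))``.
    Raises for ``beta = 0`` (proportional null: the ratio is identically 1).
    """
    if spec.beta == 0:
        raise ValueError("no crossing (proportional null)")
    eb = np.exp(spec.beta)
    lam_tau = np.exp(-spec.beta / (eb - 1.0))
    return float(spec.baseline_cumhaz.inverse(lam_tau))


def crossing_survival_at_tau(spec: CrossingModelSpec) -> float:
    """Survival of the Z=1 group evaluated at the hazard-crossing time."""
    return float(crossing_survival(spec, crossing_time(spec), 1.0))


def _mixture_terms(spec: ModulatingModelSpec, t, z1: int):
    """Conditional mixture weights and cell hazard multipliers given Z1."""
    p = spec.joint_probs[z1]
    cond = p / p.sum()
    mult = np.array(
        [np.exp(spec.cell_log_hazard_ratio(z1, z2)) for z2 in (0, 1)]
    )
    lam = spec.baseline_cumhaz.cumhaz(t)
    cell_surv = np.exp(-np.multiply.outer(np.asarray(lam, float), mult))
    return cond, mult, cell_surv


def marginal_survival_z1(spec: ModulatingModelSpec, t, z1: int):
    """Survival given Z1 only, mixing over the hidden partner Z2.

    ``S(t|z1) = sum_z2 P(Z2=z2|Z1=z1) * exp(-Lambda0(t) e^{gamma z2 + alpha z1 z2})``.
    """
    cond, _, cell_surv = _mixture_terms(spec, t, z1)
    return cell_surv @ cond


def marginal_hazard_z1(spec: ModulatingModelSpec, t, z1: int):
    """Marginal hazard of the Z1=z1 group: mixture hazard weighted by the
    probability of still being at risk in each hidden Z2 cell."""
    cond, mult, cell_surv = _mixture_terms(spec, t, z1)
    lam0 = spec.baseline_cumhaz.hazard(t)
    num = cell_surv @ (cond * mult)
    den = cell_surv @ cond
    return lam0 * num / den


def marginal_hazard_ratio(spec: ModulatingModelSpec, t):
    """Hazard ratio of the Z1=1 vs Z1=0 groups after marginalising Z2."""
    return marginal_hazard_z1(spec, t, 1) / marginal_hazard_z1(spec, t, 0)


def marginal_crossing_time(
    spec: ModulatingModelSpec, bracket: tuple[float, float] = (1e-6, 50.0)
) -> float:
    """Time at which the marginal hazard ratio of Z1 crosses 1.

    Found by sign-change bracketing plus Brent root-finding on
    ``log marginal_hazard_ratio``.  Raises if no sign change exists on the
    bracket (e.g. ``alpha = 0``, where the ratio is identically 1).
    """

    def f(t: float) -> float:
        return float(np.log(marginal_hazard_ratio(spec, t)))

    grid = np.geomspace(bracket[0], bracket[1], 400)
    vals = np.array([f(t) for t in grid])
    sign = np.sign(vals)
    sign[sign == 0] = 1
    flips = np.nonzero(np.diff(sign))[0]
    flips = flips[np.abs(vals[flips]) > 1e-12]
    if flips.size == 0:
        raise ValueError("no crossing detected in bracket")
    i = flips[0]
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-14))
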