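"""Simulators for the crossing-hazards study conditions.

The generators reproduce the simulation scheme the index was designed for:

* covariates that are Bernoulli(0.5), log-normal or uniform, all
  standardised to variance 1/4;
* event times from the semi-parametric crossing model with identity
  baseline (equivalently a Weibull with scale 1 and shape ``exp(beta Z)``),
  or from a log-normal with log-scale standard deviation ``exp(-beta Z)``;
* uniform or exponential censoring, with the distribution parameter
  calibrated so that the expected overall censoring fraction hits a target
  ``p_c`` in {0, 0.25, 0.5};
* the two-marker modulating-effect model (conditionally proportional
  hazards, marginally crossing), and
* a planted-marker screening fixture emulating a genome-wide expression
  matrix in which a block of markers tracks a latent pair with an
  effect-modification (hence crossing) signal.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .datasets import SurvivalDataset
from .models import ModulatingModelSpec

COVARIATE_LAWS = ("bernoulli_half", "lognormal", "uniform")
EVENT_LAWS = ("weibull_crossing", "lognormal_scale")
CENSORING_LAWS = ("none", "uniform", "exponential")

#: target covariate variance shared by all three laws (anchored at Bernoulli(0.5))
_TARGET_VAR = 0.25
_LOGNORMAL_SIGMA = 0.5  # log-scale sd: "variance 1/4" on the log scale


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid."""

    covariate_law: str = "bernoulli_half"
    beta: float = 0.0
    event_law: str = "weibull_crossing"
    censoring_law: str = "none"
    target_censoring: float = 0.0
    n: int = 100
    replications: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariate_law not in COVARIATE_LAWS:
            raise ValueError(f"unknown covariate law {self.covariate_law!r}")
        if self.event_law not in EVENT_LAWS:
            raise ValueError(f"unknown event-time law {self.event_law!r}")
        if self.censoring_law not in CENSORING_LAWS:
            raise ValueError(f"unknown censoring law {self.censoring_law!r}")
        if not 0.0 <= self.target_censoring < 1.0:
            raise ValueError("target_censoring must be in [0, 1)")
        if self.target_censoring > 0 and self.censoring_law == "none":
            raise ValueError("target_censoring > 0 requires a censoring law")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.replications < 1:
            raise ValueError("replications must be at least 1")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_covariate(law: str, n: int, seed) -> np.ndarray:
    """Draw a covariate vector standardised to variance 1/4.

    Bernoulli(0.5) is used as-is (variance exactly 1/4); the log-normal
    (log-scale sd 0.5) and the symmetric uniform are affinely standardised
    to mean 0, variance 1/4 using their exact moments.
    """
    rng = _rng(seed)
    if law == "bernoulli_half":
        return rng.integers(0, 2, n).astype(float)
    if law == "lognormal":
        raw = np.exp(_LOGNORMAL_SIGMA * rng.standard_normal(n))
        m = math.exp(_LOGNORMAL_SIGMA**2 / 2.0)
        v = (math.exp(_LOGNORMAL_SIGMA**2) - 1.0) * math.exp(_LOGNORMAL_SIGMA**2)
        return (raw - m) * math.sqrt(_TARGET_VAR / v)
    if law == "uniform":
        half_width = math.sqrt(3.0 * _TARGET_VAR)
        return rng.uniform(-half_width, half_width, n)
    raise ValueError(f"unknown covariate law {law!r}")


def draw_event_times_weibull(z: np.ndarray, beta: float, seed) -> np.ndarray:
    """Event times from the crossing model with identity baseline.

    ``S(t|z) = exp(-t ** exp(beta z))`` inverted against uniform draws:
    ``X = (-log U) ** exp(-beta z)``.  Subjects with ``z = 0`` are unit
    exponential.
    """
    rng = _rng(seed)
    u = rng.uniform(size=np.shape(z))
    return (-np.log(u)) ** np.exp(-beta * np.asarray(z, float))


def draw_event_times_lognormal(z: np.ndarray, beta: float, seed) -> np.ndarray:
    """Log-normal event times with log-scale sd ``exp(-beta z)`` (median 1)."""
    rng = _rng(seed)
    eps = rng.standard_normal(np.shape(z))
    return np.exp(np.exp(-beta * np.asarray(z, float)) * eps)


def _event_survival(c: float, z: float, event_law: str, beta: float) -> float:
    """P(X > c | Z = z) for the two event-time laws."""
    if c <= 0.0:
        return 1.0
    if event_law == "weibull_crossing":
        log_cumhaz = math.exp(beta * z) * math.log(c)  # log(c ** e^{beta z})
        if log_cumhaz > 700.0:
            return 0.0
        return math.exp(-math.exp(log_cumhaz))
    sigma = math.exp(-beta * z)
    return float(stats.norm.sf(math.log(c) / sigma))


def _covariate_nodes(law: str, n_nodes: int = 24):
    """Quadrature nodes and weights representing the covariate law."""
    if law == "bernoulli_half":
        return np.array([0.0, 1.0]), np.array([0.5, 0.5])
    if law == "uniform":
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        half_width = math.sqrt(3.0 * _TARGET_VAR)
        return x * half_width, w / 2.0
    if law == "lognormal":
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        eps = math.sqrt(2.0) * x
        raw = np.exp(_LOGNORMAL_SIGMA * eps)
        m = math.exp(_LOGNORMAL_SIGMA**2 / 2.0)
        v = (math.exp(_LOGNORMAL_SIGMA**2) - 1.0) * math.exp(_LOGNORMAL_SIGMA**2)
        return (raw - m) * math.sqrt(_TARGET_VAR / v), w / math.sqrt(math.pi)
    raise ValueError(f"unknown covariate law {law!r}")


def _censoring_probability(
    param: float, censoring_law: str, covariate_law: str, event_law: str, beta: float
) -> float:
    """P(C < X) for a given censoring parameter, mixing over the covariate."""
    nodes, weights = _covariate_nodes(covariate_law)
    total = 0.0
    for z, w in zip(nodes, weights):
        if censoring_law == "uniform":
            val, _ = integrate.quad(
                lambda c: _event_survival(c, z, event_law, beta), 0.0, param,
                limit=200,
            )
            total += w * val / param
        else:  # exponential with rate `param`
            val, _ = integrate.quad(
                lambda c: param * math.exp(-param * c)
                * _event_survival(c, z, event_law, beta),
                0.0, np.inf, limit=200,
            )
            total += w * val
    return total


@functools.lru_cache(maxsize=None)
def calibrate_censoring(
    censoring_law: str,
    target_censoring: float,
    event_law: str = "weibull_crossing",
    covariate_law: str = "bernoulli_half",
    beta: float = 0.0,
) -> float | None:
    """Censoring parameter achieving an expected censoring fraction ``p_c``.

    Solves ``P(C < X) = p_c`` by Brent root-finding on the numerically
    integrated censoring probability, mixing over the covariate law
    (exact enumeration for Bernoulli, Gaussian quadrature otherwise).
    Returns the uniform upper bound ``r`` or the exponential rate; ``None``
    is the no-censoring sentinel for ``p_c = 0``.
    """
    if target_censoring == 0.0:
        return None
    if not 0.0 < target_censoring < 1.0:
        raise ValueError("target censoring must be in [0, 1)")
    if censoring_law not in ("uniform", "exponential"):
        raise ValueError(f"unknown censoring law {censoring_law!r}")

    def objective(param: float) -> float:
        return (
            _censoring_probability(param, censoring_law, covariate_law, event_law, beta)
            - target_censoring
        )

    # uniform: P(C < X) decreases from 1 to 0 as r grows;
    # exponential: increases from 0 to 1 with the rate.
    lo, hi = 1e-8, 1.0
    for _ in range(60):
        if objective(lo) * objective(hi) <= 0:
            break
        hi *= 2.0
    else:
        raise ValueError("calibration failed")
    return float(optimize.brentq(objective, lo, hi, xtol=1e-10, rtol=1e-12))


def draw_censoring(
    censoring_law: str, param: float | None, n: int, seed
) -> np.ndarray:
    """Censoring times; infinite when no censoring applies."""
    rng = _rng(seed)
    if param is None or censoring_law == "none":
        return np.full(n, np.inf)
    if censoring_law == "uniform":
        return rng.uniform(0.0, param, n)
    if censoring_law == "exponential":
        return rng.exponential(1.0 / param, n)
    raise ValueError(f"unknown censoring law {censoring_law!r}")


def generate_dataset(
    config: SimulationConfig, seed=None
) -> tuple[SurvivalDataset, dict]:
    """One dataset from a grid cell, plus the truth record that produced it.

    Per subject: draw ``Z``, then ``X | Z`` from the event-time law, an
    independent censoring time ``C``, and report ``T = min(X, C)`` with
    ``delta = 1(X <= C)``.
    """
    rng = _rng(config.seed if seed is None else seed)
    z = draw_covariate(config.covariate_law, config.n, rng)
    if config.event_law == "weibull_crossing":
        x = draw_event_times_weibull(z, config.beta, rng)
    else:
        x = draw_event_times_lognormal(z, config.beta, rng)
    param = calibrate_censoring(
        config.censoring_law if config.target_censoring > 0 else "uniform",
        config.target_censoring,
        config.event_law,
        config.covariate_law,
        config.beta,
    )
    c = draw_censoring(config.censoring_law, param, config.n, rng)
    time = np.minimum(x, c)
    event = (x <= c).astype(np.int64)
    truth = {
        "beta": config.beta,
        "covariate_law": config.covariate_law,
        "event_law": config.event_law,
        "censoring_law": config.censoring_law,
        "target_censoring": config.target_censoring,
        "censoring_param": param,
        "n": config.n,
    }
    return SurvivalDataset(time, event, pd.DataFrame({"z": z})), truth


def generate_modulating_dataset(
    spec: ModulatingModelSpec,
    n: int,
    censoring: tuple[str, float] | None = None,
    seed=None,
) -> SurvivalDataset:
    """Dataset from the two-marker modulating-effect model.

    ``(Z1, Z2)`` is drawn from ``spec.joint_probs``; conditional on the
    cell, the hazard is ``lambda0(t) * exp(gamma Z2 + alpha Z1 Z2)`` so the
    event time is ``Lambda0^{-1}(E / multiplier)`` with ``E ~ Exp(1)``.
    Both marker columns are kept so marginal analyses can hide ``Z2``.
    ``censoring`` is ``None`` or ``(law, parameter)``.
    """
    rng = _rng(seed)
    p = spec.joint_probs.ravel()
    cells = rng.choice(4, size=n, p=p)
    z1 = (cells // 2).astype(float)
    z2 = (cells % 2).astype(float)
    mult = np.exp(spec.gamma * z2 + spec.alpha * z1 * z2)
    e_std = rng.exponential(1.0, n)
    x = spec.baseline_cumhaz.inverse(e_std / mult)
    if censoring is None:
        c = np.full(n, np.inf)
    else:
        c = draw_censoring(censoring[0], censoring[1], n, rng)
    time = np.minimum(x, c)
    event = (x <= c).astype(np.int64)
    return SurvivalDataset(time, event, pd.DataFrame({"z1": z1, "z2": z2}))


def generate_screening_fixture(
    n_markers: int = 2000,
    n_crossing: int = 20,
    n_ph: int = 20,
    n_samples: int = 100,
    alpha: float = 2.5,
    gamma: float = 2.5,
    beta_ph: float = math.log(3.0),
    marker_noise_sd: float = 0.3,
    censoring_rate: float = 0.1,
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A marker-expression matrix with planted prognostic markers.

    The survival outcome is driven by a hidden binary pair ``(L1, L2)``
    with a modulating effect (coefficients ``alpha``, ``gamma``) — so
    ``L1`` has a marginally crossing effect — and by an independent
    binary driver ``P`` with a proportional effect ``beta_ph``.  The
    latent drivers are assigned to exactly half the samples each
    (stratified randomisation, keeping every cell of the design
    populated).  Planted "crossing" markers are noisy copies of ``L1``,
    planted "ph" markers noisy copies of ``P`` and the rest independent
    Gaussian noise, emulating co-expressed gene modules around latent
    drivers.  Light exponential censoring keeps the late follow-up —
    where the hazard reversal is visible — informative.

    Returns ``(matrix, metadata, truth)``: a markers-by-samples matrix
    (index = marker id), a per-sample time/event table, and per-marker
    truth labels.
    """
    if n_crossing + n_ph > n_markers:
        raise ValueError("planted markers exceed matrix size")
    rng = _rng(seed)

    def half_assignment() -> np.ndarray:
        v = np.zeros(n_samples)
        v[: n_samples // 2] = 1.0
        return rng.permutation(v)

    l1 = half_assignment()
    l2 = half_assignment()
    p_drv = half_assignment()
    mult = np.exp(gamma * l2 + alpha * l1 * l2 + beta_ph * p_drv)
    x = rng.exponential(1.0, n_samples) / mult
    c = (
        rng.exponential(1.0 / censoring_rate, n_samples)
        if censoring_rate > 0
        else np.full(n_samples, np.inf)
    )
    time = np.minimum(x, c)
    event = (x <= c).astype(np.int64)

    matrix = rng.standard_normal((n_markers, n_samples))
    labels = np.array(["null"] * n_markers, dtype=object)
    matrix[:n_crossing] = l1 + marker_noise_sd * rng.standard_normal(
        (n_crossing, n_samples)
    )
    labels[:n_crossing] = "crossing"
    matrix[n_crossing : n_crossing + n_ph] = p_drv + marker_noise_sd * rng.standard_normal(
        (n_ph, n_samples)
    )
    labels[n_crossing : n_crossing + n_ph] = "ph"

    marker_ids = [f"m{i:05d}" for i in range(n_markers)]
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    matrix_df = pd.DataFrame(matrix, index=marker_ids, columns=sample_ids)
    matrix_df.index.name = "marker"
    meta = pd.DataFrame({"time": time, "event": event}, index=sample_ids)
    meta.index.name = "sample"
    truth = pd.DataFrame({"label": labels}, index=marker_ids)
    truth.index.name = "marker"
    return matrix_df, meta, truth


def write_fixture(
    out_dir: str | Path,
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> None:
    """Write a screening fixture as TSV files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "matrix.tsv", sep="\t")
    meta.to_csv(out / "metadata.tsv", sep="\t")
    if truth is not None:
        truth.to_csv(out / "truth.tsv", sep="\t")
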