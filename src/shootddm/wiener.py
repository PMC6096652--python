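"""Two-boundary drift-diffusion (Wiener) first-passage computations.

This module is the computational core of the package: the first-passage-time
density of the drift-diffusion process, the implied choice probabilities,
an Euler-Maruyama trial simulator, and deadline-aware trial log-likelihoods.

The decision process accumulates evidence from a start point ``z = beta *
alpha`` between absorbing boundaries at 0 ("Don't Shoot") and ``alpha``
("Shoot") with drift ``delta`` and unit diffusion coefficient.  Observed
response times are the decision time plus a non-decision time, ``rt = t_d +
ndt``.  Time is handled in seconds internally and in milliseconds at the
trial-record level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _wfpt

__all__ = [
    "DDMParams",
    "TrialOutcome",
    "ParameterError",
    "wfpt_density",
    "wfpt_logpdf",
    "choice_probability",
    "decision_cdf",
    "survivor_probability",
    "simulate_trial",
    "simulate_trials",
    "trial_loglik",
    "UPPER",
    "LOWER",
]

UPPER = "upper"
LOWER = "lower"

#: default series truncation tolerance for the density
DEFAULT_TOL = 1e-7
#: default Euler step in seconds (0.25 ms)
DEFAULT_STEP = 0.00025


class ParameterError(ValueError):
    """Raised when drift-diffusion parameters are outside their domain."""


@dataclass(frozen=True)
class DDMParams:
    """One subject-condition's process parameters.

    Parameters
    ----------
    beta : float
        Relative start point, fraction of the threshold separation
        (0 < beta < 1).  Values above .5 bias the "Shoot" boundary.
    alpha : float
        Threshold separation in evidence units (alpha > 0).
    delta : float
        Drift rate in evidence units per second; positive values point at
        the "Shoot" (upper) boundary.
    ndt : float
        Non-decision time in seconds (ndt >= 0).
    """

    beta: float
    alpha: float
    delta: float
    ndt: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0.0) or not math.isfinite(self.alpha):
            raise ParameterError(f"alpha must be positive, got {self.alpha}")
        if not (0.0 < self.beta < 1.0):
            raise ParameterError(f"beta must lie strictly in (0, 1), got {self.beta}")
        if not (self.ndt >= 0.0) or not math.isfinite(self.ndt):
            raise ParameterError(f"ndt must be non-negative, got {self.ndt}")
        if not math.isfinite(self.delta):
            raise ParameterError(f"delta must be finite, got {self.delta}")

    @property
    def z(self) -> float:
        """Absolute start point ``z = beta * alpha`` (0 < z < alpha)."""
        return self.beta * self.alpha


@dataclass(frozen=True)
class TrialOutcome:
    """The observable outcome of one trial.

    ``boundary`` is ``"upper"`` ("Shoot"), ``"lower"`` ("Don't Shoot") or
    ``None`` for a censored trial; ``rt_ms`` is the total response time in
    milliseconds and is present iff the trial is not censored.
    """

    boundary: Optional[str]
    rt_ms: Optional[float]

    def __post_init__(self) -> None:
        if self.censored:
            if self.rt_ms is not None or self.boundary is not None:
                raise ValueError("censored outcomes carry no boundary or rt")
        else:
            if self.boundary not in (UPPER, LOWER):
                raise ValueError(f"boundary must be 'upper' or 'lower', got {self.boundary}")
            if self.rt_ms is None or not self.rt_ms > 0:
                raise ValueError("observed outcomes need a positive rt_ms")

    @property
    def censored(self) -> bool:
        return self.boundary is None and self.rt_ms is None


def _check_boundary(boundary: str) -> bool:
    if boundary == UPPER:
        return True
    if boundary == LOWER:
        return False
    raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")


def wfpt_logpdf(t: float, boundary: str, params: DDMParams, tol: float = DEFAULT_TOL) -> float:
    """Log first-passage density at decision time ``t`` (seconds, NDT excluded)."""
    if not tol > 0:
        raise ValueError("tol must be positive")
    upper = _check_boundary(boundary)
    return _wfpt.logpdf(float(t), upper, params.alpha, params.delta, params.beta, tol)


def wfpt_density(t: float, boundary: str, params: DDMParams, tol: float = DEFAULT_TOL) -> float:
    """First-passage density (per second) at decision time ``t``; 0 for t <= 0."""
    lp = wfpt_logpdf(t, boundary, params, tol)
    return 0.0 if lp == -np.inf else math.exp(lp)


def choice_probability(params: DDMParams) -> float:
    """Probability that the process is absorbed at the upper ("Shoot") boundary."""
    return _wfpt.prob_upper(params.alpha, params.delta, params.beta)


def survivor_probability(t: float, params: DDMParams) -> float:
    """P(neither boundary has been reached by decision time ``t``)."""
    return _wfpt.survivor(float(t), params.alpha, params.delta, params.beta)


def decision_cdf(t: float, boundary: str, params: DDMParams) -> float:
    """P(absorbed at ``boundary`` at a decision time <= ``t``)."""
    upper = _check_boundary(boundary)
    if upper:
        return _wfpt.cdf_lower(float(t), params.alpha, -params.delta, 1.0 - params.beta)
    return _wfpt.cdf_lower(float(t), params.alpha, params.delta, params.beta)


def _window_seconds(window_ms: Optional[float]) -> float:
    if window_ms is None:
        return math.inf
    if not window_ms > 0:
        raise ValueError("window must be positive (ms) or None")
    return window_ms / 1000.0


def simulate_trials(
    n: int,
    params: DDMParams,
    window_ms: Optional[float] = None,
    step: float = DEFAULT_STEP,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` trials by Euler-Maruyama with step ``step`` seconds.

    Returns ``(choice, rt_ms)`` where choice is 1 for upper, 0 for lower and
    -1 for censored (rt_ms NaN).  A trial is censored iff its total response
    time would exceed the response window.
    """
    if not step > 0:
        raise ValueError("step must be positive")
    rng = np.random.default_rng() if rng is None else rng
    seed = int(rng.integers(0, 2**31 - 1))
    choice, rt_s = _wfpt.simulate_batch(
        int(n), params.alpha, params.delta, params.beta, params.ndt, step,
        _window_seconds(window_ms), seed,
    )
    return choice, rt_s * 1000.0


def simulate_trial(
    params: DDMParams,
    window_ms: Optional[float] = None,
    step: float = DEFAULT_STEP,
    rng: Optional[np.random.Generator] = None,
) -> TrialOutcome:
    """Simulate a single trial; see :func:`simulate_trials`."""
    choice, rt_ms = simulate_trials(1, params, window_ms, step, rng)
    if choice[0] < 0:
        return TrialOutcome(boundary=None, rt_ms=None)
    return TrialOutcome(boundary=UPPER if choice[0] == 1 else LOWER, rt_ms=float(rt_ms[0]))


def trial_loglik(
    outcome: TrialOutcome,
    params: DDMParams,
    window_ms: Optional[float] = None,
    tol: float = DEFAULT_TOL,
) -> float:
    """Censoring-aware log-likelihood of one trial.

    Observed trials contribute the first-passage log-density at
    ``rt/1000 - ndt``; a response faster than the non-decision time has
    zero probability.  Censored trials contribute the log survivor mass
    beyond the window, ``log(1 - F_upper(w) - F_lower(w))`` with
    ``w = window/1000 - ndt``; with an unbounded window a censored trial is
    a zero-probability event.
    """
    if outcome.censored:
        if window_ms is None:
            return -np.inf
        w = _window_seconds(window_ms) - params.ndt
        s = _wfpt.survivor(w, params.alpha, params.delta, params.beta)
        # w <= 0 means the deadline precedes any possible decision: mass 1
        return math.log(s) if s > 0.0 else -np.inf
    t_dec = outcome.rt_ms / 1000.0 - params.ndt
    if t_dec <= 0.0:
        return -np.inf
    return wfpt_logpdf(t_dec, outcome.boundary, params, tol)
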