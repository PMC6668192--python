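"""Partial-likelihood fitters for a single binary treatment covariate.

Both the cause-specific (Cox) and the subdistribution (Fine–Gray) models are
fitted from first principles by maximising a one-parameter partial likelihood

    l(b) = sum_j [ b * z_j - log( n0(t_j) + n1(t_j) * e^b ) ],

where the sum runs over events of the modelled type and ``n0``/``n1`` count
the control/treated members of the model's risk set at that event time:

* cause-specific: subjects with ``T >= t`` (the competing event censors);
* subdistribution: subjects with ``T >= t`` *plus* subjects whose competing
  event already happened (they remain in the risk set forever).

In the absence of censoring the usual inverse-probability-of-censoring
weights of the Fine–Gray fit are identically 1, so the subdistribution fit
is an exact partial likelihood too, not a weighted approximation.  Ties (a
measure-zero event with continuous times, but possible after file
round-tripping) are handled with Breslow's approximation.  Optimisation is
Newton–Raphson from 0 with step-halving; the standard error is the inverse
square root of the observed information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hazards import EventData
from .population import Population

__all__ = [
    "DegenerateDataError",
    "NonIdentifiableError",
    "SurvivalSample",
    "EstimateResult",
    "cox_cause_specific",
    "fine_gray",
]

_SCORE_TOL = 1e-9
_STEP_TOL = 1e-10
_MAX_ITER = 50


class DegenerateDataError(ValueError):
    """No events of the modelled type: the partial likelihood is empty."""


class NonIdentifiableError(ValueError):
    """Only one treatment arm present: the log hazard ratio is unidentified."""


@dataclass
class SurvivalSample:
    """Analysis dataset: time, event type, and treatment (confounder unseen)."""

    t: np.ndarray
    delta: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.delta = np.asarray(self.delta, dtype=np.int8)
        self.z = np.asarray(self.z, dtype=np.int8)
        if not (self.t.shape == self.delta.shape == self.z.shape) or self.t.ndim != 1:
            raise ValueError("t, delta and z must be 1-d arrays of equal length")
        if np.isnan(self.t).any():
            raise ValueError("missing event times")
        if not np.isin(self.delta, (1, 2)).all():
            raise ValueError("delta must contain only 1 and 2")
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z must contain only 0 and 1")

    @classmethod
    def from_simulation(cls, pop: Population, events: EventData) -> "SurvivalSample":
        return cls(t=events.t, delta=events.delta, z=pop.z)


@dataclass
class EstimateResult:
    """A fitted log hazard ratio with its model-based standard error."""

    coef: float
    se: float
    converged: bool
    n_events: int
    iterations: int


def _check_event(event: int) -> None:
    if event not in (1, 2):
        raise ValueError(f"event must be 1 or 2, got {event!r}")


def _validate(data: SurvivalSample, event: int) -> None:
    _check_event(event)
    if not np.any(data.delta == event):
        raise DegenerateDataError(f"no events of type {event} in the data")
    if data.z.min() == data.z.max():
        raise NonIdentifiableError(
            "treatment indicator is constant; the hazard ratio is not identifiable"
        )


def _event_table(data: SurvivalSample, event: int):
    """Distinct modelled-event times with event counts per arm (Breslow ties)."""
    mask = data.delta == event
    times, inv = np.unique(data.t[mask], return_inverse=True)
    d = np.bincount(inv, minlength=times.size).astype(float)
    d1 = np.bincount(inv, weights=data.z[mask].astype(float), minlength=times.size)
    return times, d, d1


def _risk_counts_cause_specific(data: SurvivalSample, times: np.ndarray):
    """Per arm, subjects still event-free (T >= t) at each event time."""
    n0, n1 = [], []
    for arm in (0, 1):
        sorted_t = np.sort(data.t[data.z == arm])
        at_risk = sorted_t.size - np.searchsorted(sorted_t, times, side="left")
        (n0 if arm == 0 else n1).append(at_risk)
    return n0[0].astype(float), n1[0].astype(float)


def _risk_counts_fine_gray(data: SurvivalSample, times: np.ndarray, event: int):
    """Per arm, everyone except prior modelled-type events (competing-event
    subjects stay at risk forever)."""
    n0, n1 = [], []
    for arm in (0, 1):
        arm_mask = data.z == arm
        sorted_ev = np.sort(data.t[arm_mask & (data.delta == event)])
        removed = np.searchsorted(sorted_ev, times, side="left")
        (n0 if arm == 0 else n1).append(arm_mask.sum() - removed)
    return n0[0].astype(float), n1[0].astype(float)


def _newton_binary(d: np.ndarray, d1: np.ndarray, n0: np.ndarray, n1: np.ndarray) -> EstimateResult:
    """Maximise the aggregated binary-covariate partial likelihood."""

    def loglik(b: float) -> float:
        return float(b * d1.sum() - d @ np.log(n0 + n1 * np.exp(b)))

    def score_info(b: float) -> tuple[float, float]:
        eb = np.exp(b)
        denom = n0 + n1 * eb
        frac = n1 * eb / denom
        score = float(d1.sum() - d @ frac)
        info = float(d @ (frac * (1.0 - frac)))
        return score, info

    b = 0.0
    ll = loglik(b)
    converged = False
    iterations = 0
    for iterations in range(1, _MAX_ITER + 1):
        score, info = score_info(b)
        if abs(score) < _SCORE_TOL:
            converged = True
            break
        if info <= 0.0:
            break
        step = score / info
        # step-halving safeguard: the 1-d partial log-likelihood is concave,
        # but guard against overshoot at extreme starting configurations
        new_b = b + step
        new_ll = loglik(new_b)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_b = b + step
            new_ll = loglik(new_b)
            halvings += 1
        if abs(step) < _STEP_TOL:
            b, ll = new_b, new_ll
            converged = True
            break
        b, ll = new_b, new_ll
    score, info = score_info(b)
    if abs(score) < _SCORE_TOL:
        converged = True
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    return EstimateResult(
        coef=float(b),
        se=se,
        converged=converged,
        n_events=int(round(d.sum())),
        iterations=iterations,
    )


def cox_cause_specific(data: SurvivalSample, event: int) -> EstimateResult:
    """Cause-specific proportional-hazards fit for one event type.

    The other event type is treated as censoring at its time; the risk set at
    each modelled event time is every subject with ``T >= t``.
    """
    _validate(data, event)
    times, d, d1 = _event_table(data, event)
    n0, n1 = _risk_counts_cause_specific(data, times)
    res = _newton_binary(d, d1, n0, n1)
    return res


def fine_gray(data: SurvivalSample, event: int) -> EstimateResult:
    """Subdistribution proportional-hazards (Fine–Gray) fit for one event type.

    Subjects who experienced the competing event remain in the risk set at all
    later times.  With no censoring in the design, the subdistribution partial
    likelihood is exact (all weights are 1).
    """
    _validate(data, event)
    times, d, d1 = _event_table(data, event)
    n0, n1 = _risk_counts_fine_gray(data, times, event)
    res = _newton_binary(d, d1, n0, n1)
    return res


def fit_record(data: SurvivalSample, model: str, event: int) -> dict:
    """One fit as a plain JSON-serialisable record."""
    fitter = {"cox": cox_cause_specific, "fine-gray": fine_gray}.get(model)
    if fitter is None:
        raise ValueError(f"model must be 'cox' or 'fine-gray', got {model!r}")
    res = fitter(data, event)
    return {
        "model": model,
        "event": event,
        "coef": res.coef,
        "se": res.se,
        "n": int(data.t.size),
        "n_events": res.n_events,
        "converged": res.converged,
        "iterations": res.iterations,
    }
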