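"""Kaplan-Meier estimation and the Weibull adequacy diagnostic.

Under a Weibull survival function S(t) = exp(-lambda t^p),

    log(-log S(t)) = log(lambda) + p * log(t)

so plotting the complementary log-log of a nonparametric survival estimate
against log time should be close to a straight line whose slope estimates
the shape p and whose intercept estimates log(lambda).  The ordinary
least-squares R-squared of that line is reported as the adequacy statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Dataset
from .fitting import EventDefinition


@dataclass
class StepSurvival:
    """Kaplan-Meier step function with risk-set bookkeeping.

    ``times`` are the distinct event times (ascending); ``survival`` the
    product-limit estimate just after each, ``at_risk``/``events`` the
    risk-set size and event count at each time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly ascending")
        if np.any(np.diff(self.survival) > 1e-15):
            raise ValueError("survival values must be nonincreasing")

    def survival_at(self, t: float) -> float:
        """S(t): 1 before the first event time, stepwise thereafter."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(
    dataset: Dataset, event_definition: EventDefinition = "cause-1-only"
) -> StepSurvival:
    """Product-limit estimator of survival for the chosen event definition.

    ``"cause-1-only"`` treats cause-1 deaths as events with competing
    deaths censored; ``"any-death"`` pools all causes.  Standard tie
    convention: subjects censored at an event time remain at risk for it.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    t = dataset.times
    d = dataset.events
    if event_definition == "cause-1-only":
        delta = d == 1
    elif event_definition == "any-death":
        delta = d > 0
    else:
        raise ValueError(f"unknown event definition {event_definition!r}")
    if not delta.any():
        raise ValueError("no events under this event definition")

    event_times = np.unique(t[delta])
    n = len(t)
    at_risk = np.empty(len(event_times), dtype=int)
    n_events = np.empty(len(event_times), dtype=int)
    for i, et in enumerate(event_times):
        at_risk[i] = int((t >= et).sum())
        n_events[i] = int(((t == et) & delta).sum())
    survival = np.cumprod(1.0 - n_events / at_risk)
    return StepSurvival(times=event_times, survival=survival,
                        at_risk=at_risk, events=n_events)


def cloglog_points(surv: StepSurvival) -> np.ndarray:
    """(log t, log(-log S(t))) pairs at event times with 0 < S < 1.

    Steps where S is exactly 1 or 0 are dropped (the transform is
    undefined there).  Returns an array of shape (m, 2); raises if fewer
    than two usable points remain.
    """
    mask = (surv.survival > 0.0) & (surv.survival < 1.0) & (surv.times > 0.0)
    if mask.sum() < 2:
        raise ValueError("need at least 2 points with 0 < S < 1")
    logt = np.log(surv.times[mask])
    cll = np.log(-np.log(surv.survival[mask]))
    return np.column_stack([logt, cll])


def weibull_linearity(points: np.ndarray) -> tuple[float, float, float]:
    """OLS line through cloglog points: (slope, intercept, R-squared).

    The slope estimates the Weibull shape p, the intercept log(lambda);
    R-squared near 1 supports the Weibull form.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points")
    x, y = points[:, 0], points[:, 1]
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx < 1e-14:
        raise ValueError("degenerate x-variance")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    syy = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if syy < 1e-300 else float(1.0 - np.sum(resid**2) / syy)
    return slope, intercept, r2
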