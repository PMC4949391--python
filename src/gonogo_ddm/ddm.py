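"""Drift-diffusion decision model for the saccadic Go/No-Go task.

The task is modelled as a two-alternative diffusion between an upper (Go)
and an implicit lower (No-Go) boundary: evidence accumulates with drift
``v_go`` on Go trials and ``v_nogo`` on No-Go trials from a starting point
``a*z`` until it is absorbed.  An upper-boundary absorption produces a
saccade with latency = first-passage time + non-decision time ``Ter``;
a lower-boundary absorption withholds the response.  The diffusion scale
``s`` is fixed (1 by convention) and all parameter magnitudes are read on
that scale.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels


class Boundary(enum.Enum):
    UPPER = "upper"  # Go decision
    LOWER = "lower"  # No-Go decision


GO = "GO"
NOGO = "NOGO"


@dataclass(frozen=True)
class DDMParams:
    """Per-participant decision parameters.

    a : boundary separation (> 0, evidence units)
    z : relative starting point in (0, 1); start level is a*z
    v_go, v_nogo : drift rates (evidence / s) in the two conditions
    ter : non-decision time, seconds (>= 0)
    s : diffusion scale (evidence / sqrt(s)); fixed constant, default 1
    """

    a: float
    z: float
    v_go: float
    v_nogo: float
    ter: float
    s: float = 1.0

    def __post_init__(self):
        if not (self.a > 0.0 and math.isfinite(self.a)):
            raise ValueError(f"boundary separation a must be positive, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative starting point z must be in (0,1), got {self.z}")
        if not (self.ter >= 0.0 and math.isfinite(self.ter)):
            raise ValueError(f"non-decision time ter must be >= 0, got {self.ter}")
        if not (self.s > 0.0):
            raise ValueError(f"diffusion scale s must be positive, got {self.s}")

    def drift(self, condition: str) -> float:
        return self.v_go if condition == GO else self.v_nogo


def _scaled(params: DDMParams, drift: float) -> tuple[float, float, float]:
    """Reduce to unit diffusion scale: (v/s, a/s, z)."""
    return drift / params.s, params.a / params.s, params.z


def wfpt_density(t, params: DDMParams, drift: float, boundary: Boundary):
    """Wiener first-passage-time density at decision time ``t`` (seconds,
    non-decision time excluded) at the given boundary.

    Accepts a scalar or an array of times; returns 0 for t <= 0.
    """
    v, a, z = _scaled(params, drift)
    ts = np.asarray(t, dtype=float)
    out = np.empty(ts.shape, dtype=float)
    it = np.nditer([ts, out], op_flags=[["readonly"], ["writeonly"]])
    for x, y in it:
        if boundary is Boundary.UPPER:
            y[...] = _kernels.wfpt_upper(float(x), v, a, z)
        else:
            y[...] = _kernels.wfpt_lower(float(x), v, a, z)
    return out[()] if out.ndim == 0 else out


def choice_probability(params: DDMParams, drift: float, boundary: Boundary) -> float:
    """Probability that the diffusion is absorbed at ``boundary`` (ever)."""
    v, a, z = _scaled(params, drift)
    p_up = _kernels.prob_upper(v, a, z)
    return p_up if boundary is Boundary.UPPER else 1.0 - p_up


def mean_decision_time(params: DDMParams, drift: float) -> float:
    """Unconditional mean first-passage time (either boundary).

    From optional stopping of the de-drifted martingale:
    E[T] = (a * P(upper) - a*z) / v for v != 0, and for v = 0 the classical
    a^2 z (1 - z) / s^2.
    """
    v, a, z = _scaled(params, drift)
    if abs(v) < 1e-12:
        return a * a * z * (1.0 - z)
    return (a * _kernels.prob_upper(v, a, z) - a * z) / v


def trial_loglik(trial, params: DDMParams) -> float:
    """Log-likelihood of one Go/No-Go trial.

    A responded trial contributes the upper-boundary FPT density at
    latency - ter; a withheld trial contributes the lower-boundary
    absorption probability.  Latency <= ter yields -inf, not an error.
    """
    drift = params.drift(trial.condition)
    if trial.responded:
        if trial.latency_ms is None:
            raise ValueError("responded trial without a latency")
        t = trial.latency_ms / 1000.0 - params.ter
        d = wfpt_density(t, params, drift, Boundary.UPPER)
        return math.log(d) if d > 0.0 else -math.inf
    p = choice_probability(params, drift, Boundary.LOWER)
    return math.log(p) if p > 0.0 else -math.inf


def sample_fpt(params: DDMParams, drift: float, n: int, seed: int,
               dt: float = 1e-4, max_time: float = 50.0,
               correct_boundaries: bool = True):
    """Euler-Maruyama first-passage simulation: (times, hit_upper) arrays.

    This is the brute-force oracle used to validate the analytic density;
    the trial generator reuses it at a coarser step.  The boundary
    continuity correction (on by default) removes the leading O(sqrt(dt))
    overshoot bias of discretely monitored absorption.
    """
    v, a, z = _scaled(params, drift)
    return _kernels.simulate_fpt(int(n), v, a, z, dt, max_time,
                                 int(seed) % (2 ** 31), correct_boundaries)


def sample_trials(params: DDMParams, condition: str, n: int, deadline_s: float,
                  seed: int, dt: float = 2e-4):
    """Simulate ``n`` Go or No-Go trials by forward diffusion.

    Upper-boundary absorption -> responded with latency FPT + ter; lower
    absorption -> withheld; a response that would land past the deadline is
    censored into a withheld trial.  Deterministic given the seed.
    Returns a list of TrialRecord with empty participant/group fields filled
    by the caller.
    """
    from .io import TrialRecord  # local import to avoid a cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    times, up = sample_fpt(params, params.drift(condition), n, seed, dt=dt)
    out = []
    for i in range(n):
        lat = times[i] + params.ter
        if up[i] == 1 and lat <= deadline_s:
            out.append(TrialRecord(participant_id="", group="", condition=condition,
                                   responded=True, latency_ms=lat * 1000.0))
        else:
            out.append(TrialRecord(participant_id="", group="", condition=condition,
                                   responded=False, latency_ms=None))
    return out


def with_params(params: DDMParams, **kw) -> DDMParams:
    return replace(params, **kw)
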