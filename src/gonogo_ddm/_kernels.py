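"""Numba kernels for Wiener first-passage-time computations.

All kernels work on a diffusion with unit scale (s = 1); callers rescale
drift and boundary by s beforehand.  Times are decision times in seconds,
i.e. non-decision time has already been subtracted.
"""
import math

import numpy as np
from numba import njit

# absolute truncation error of the FPT series
SERIES_EPS = 1e-10


@njit(fastmath=False)
def wfpt_lower(t, v, a, w):
    """First-passage density at the LOWER boundary at decision time t.

    v: drift, a: boundary separation, w: relative start measured from the
    lower boundary.  Switches between the small-time and large-time series
    expansion by comparing the number of terms each needs for SERIES_EPS.
    Returns 0 for t <= 0.
    """
    if t <= 0.0 or not np.isfinite(t):
        return 0.0
    tau = t / (a * a)
    # terms needed by the large-time expansion
    if math.pi * tau * SERIES_EPS < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tau * SERIES_EPS) / (math.pi * math.pi * tau))
        kl_floor = 1.0 / (math.pi * math.sqrt(tau))
        if kl < kl_floor:
            kl = kl_floor
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))
    # terms needed by the small-time expansion
    arg = 2.0 * math.sqrt(2.0 * math.pi * tau) * SERIES_EPS
    if arg < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(arg))
        ks_floor = math.sqrt(tau) + 1.0
        if ks < ks_floor:
            ks = ks_floor
    else:
        ks = 2.0
    if ks < kl:  # small-time series
        K = int(math.ceil(ks))
        kmin = -int(math.floor((K - 1) / 2.0))
        kmax = int(math.ceil((K - 1) / 2.0))
        f = 0.0
        for k in range(kmin, kmax + 1):
            x = w + 2.0 * k
            f += x * math.exp(-x * x / (2.0 * tau))
        f /= math.sqrt(2.0 * math.pi * tau * tau * tau)
    else:  # large-time series
        K = int(math.ceil(kl))
        f = 0.0
        for k in range(1, K + 1):
            f += k * math.exp(-k * k * math.pi * math.pi * tau / 2.0) * math.sin(k * math.pi * w)
        f *= math.pi
    dens = f * math.exp(-v * a * w - v * v * t / 2.0) / (a * a)
    if dens > 0.0:
        return dens
    return 0.0


@njit(fastmath=False)
def wfpt_upper(t, v, a, z):
    """First-passage density at the UPPER boundary; z is the relative start
    measured from the lower boundary (mirror symmetry of the lower density)."""
    return wfpt_lower(t, -v, a, 1.0 - z)


@njit(fastmath=False)
def prob_upper(v, a, z):
    """Probability of absorption at the upper boundary before the lower one."""
    x = -2.0 * v * a
    if abs(x) < 1e-12:
        return z
    # (1 - exp(-2 v a z)) / (1 - exp(-2 v a)), written stably
    num = math.expm1(x * z)
    den = math.expm1(x)
    p = num / den
    if p < 0.0:
        return 0.0
    if p > 1.0:
        return 1.0
    return p


@njit(fastmath=False)
def participant_loglik(rt_go, rt_nogo, n_withheld_go, n_withheld_nogo,
                       a, z, v_go, v_nogo, ter):
    """Censored Go/No-Go log-likelihood for one participant.

    rt_go / rt_nogo: latencies (s) of responded trials in each condition.
    Responded trials contribute the upper-boundary FPT density at t - ter;
    withheld trials contribute the lower-boundary absorption probability.
    A latency at or below ter gives -inf (never an exception) so a sampler
    can move away from the region.
    """
    ll = 0.0
    for i in range(rt_go.shape[0]):
        t = rt_go[i] - ter
        if t <= 0.0:
            return -np.inf
        d = wfpt_upper(t, v_go, a, z)
        if d <= 0.0:
            return -np.inf
        ll += math.log(d)
    for i in range(rt_nogo.shape[0]):
        t = rt_nogo[i] - ter
        if t <= 0.0:
            return -np.inf
        d = wfpt_upper(t, v_nogo, a, z)
        if d <= 0.0:
            return -np.inf
        ll += math.log(d)
    if n_withheld_go > 0:
        p = 1.0 - prob_upper(v_go, a, z)
        if p <= 0.0:
            return -np.inf
        ll += n_withheld_go * math.log(p)
    if n_withheld_nogo > 0:
        p = 1.0 - prob_upper(v_nogo, a, z)
        if p <= 0.0:
            return -np.inf
        ll += n_withheld_nogo * math.log(p)
    return ll


# Broadie-Glasserman-Kou continuity-correction constant zeta(1/2)/sqrt(2*pi):
# a discretely monitored path overshoots a continuous barrier by about
# 0.5826 * sqrt(dt) on average; shrinking both boundaries inward by that
# amount removes the leading O(sqrt(dt)) first-passage bias.
_BGK = 0.5826


@njit(fastmath=False)
def simulate_fpt(n, v, a, z, dt, max_time, seed, correct_boundaries):
    """Euler-Maruyama first-passage simulation of n paths.

    Returns (times, upper) where upper[i] is 1 if path i was absorbed at the
    upper boundary, 0 at the lower one.  A path not absorbed within max_time
    gets time = max_time and upper = 0 (it can never produce a response).
    With ``correct_boundaries`` the boundaries are shrunk inward by
    0.5826*sqrt(dt) (skipped when the start would fall outside them).
    """
    np.random.seed(seed)
    times = np.empty(n)
    upper = np.zeros(n, dtype=np.uint8)
    sq = math.sqrt(dt)
    lo = 0.0
    hi = a
    x0 = z * a
    if correct_boundaries:
        shift = _BGK * sq
        if shift < x0 and x0 < a - shift:
            lo = shift
            hi = a - shift
    max_steps = int(max_time / dt)
    nbuf = 16384
    buf = np.random.standard_normal(nbuf)
    bi = 0
    for i in range(n):
        x = x0
        t = 0.0
        hit = 0
        for _ in range(max_steps):
            if bi == nbuf:
                buf = np.random.standard_normal(nbuf)
                bi = 0
            x += v * dt + sq * buf[bi]
            bi += 1
            t += dt
            if x >= hi:
                hit = 1
                break
            if x <= lo:
                hit = 2
                break
        times[i] = t
        if hit == 1:
            upper[i] = 1
    return times, upper
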