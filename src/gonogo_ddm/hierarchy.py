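"""Hierarchical Bayesian estimation of the Go/No-Go diffusion model.

Each base parameter (boundary separation a, starting point on the logit
scale, drift rates, non-decision time) carries one group-level normal
distribution per diagnostic group (mean mu, spread sigma); participant
parameters are drawn from their group's distribution.  The joint posterior
is sampled with component-wise random-walk Metropolis whose step sizes are
adapted during burn-in only (target acceptance 0.2-0.5) and frozen
afterwards, supplemented by a per-participant joint random-walk proposal
whose covariance is learned from the burn-in samples (equally frozen) to
cut through the strong a-v-z posterior correlations; chains are
reproducible bit-exactly under a fixed seed.

Priors are weakly informative and configurable; they cover published
diffusion-model ranges rather than encoding any cohort-specific knowledge:

* group means -- a: N(1.5, 1.5^2) on (0.1, 10); logit z: N(0, 1.5^2);
  v_go, v_nogo: N(0, 4^2); Ter: N(0.2, 0.2^2) on (0, the 1.5 s deadline)
* group spreads -- half-normal with unit-order scales.

The starting point is modelled on the logit scale at both levels so the
hierarchy respects (0, 1).  Per-participant non-decision proposals are
capped at that participant's minimum valid latency minus 1 ms; beyond it
the likelihood is -inf anyway, so the cap only spares wasted proposals.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from ._kernels import participant_loglik
from .io import GROUPS, StudyDataset

# mean, sd, lower, upper of the truncated-normal prior on each group mean.
# The ter ceiling is the response deadline: it only keeps the prior proper.
# (Truncating the group mean at the minimum observed latency instead would
# let one fast-biased participant cap every group's mean.)
MU_PRIOR = {
    "a": (1.5, 1.5, 0.1, 10.0),
    "z_logit": (0.0, 1.5, -8.0, 8.0),
    "v": (0.0, 4.0, -30.0, 30.0),
    "v_go": (0.0, 4.0, -30.0, 30.0),
    "v_nogo": (0.0, 4.0, -30.0, 30.0),
    "ter": (0.2, 0.2, 1e-4, 1.5),
}
# scale of the half-normal prior on each group spread
SIGMA_SCALE = {"a": 1.0, "z_logit": 1.0, "v": 2.0, "v_go": 2.0, "v_nogo": 2.0, "ter": 0.1}
# support of individual-level parameters
IND_DOMAIN = {
    "a": (0.05, 12.0),
    "z_logit": (-8.0, 8.0),
    "v": (-30.0, 30.0),
    "v_go": (-30.0, 30.0),
    "v_nogo": (-30.0, 30.0),
    "ter": (1e-3, None),  # upper bound is per participant
}
_INIT_STEP = {"a": 0.10, "z_logit": 0.10, "v": 0.25, "v_go": 0.25, "v_nogo": 0.25, "ter": 0.01}


class InitializationError(RuntimeError):
    pass


@dataclass(frozen=True)
class McmcConfig:
    """MCMC settings; defaults are 15,000 samples with the first 5,000
    discarded as burn-in."""

    n_samples: int = 15000
    n_burnin: int = 5000
    adapt_interval: int = 25
    target_accept: float = 0.35

    def __post_init__(self):
        if not 0 <= self.n_burnin < self.n_samples:
            raise ValueError("need 0 <= n_burnin < n_samples")


@dataclass
class GroupHyperParams:
    """Posterior-mean group-level (mu, sigma) per parameter per group."""

    mu: dict
    sigma: dict

    @classmethod
    def from_fit(cls, fit: "PosteriorFit") -> "GroupHyperParams":
        mu, sigma = {}, {}
        for name, chain in fit.chains.items():
            parts = name.split(":")
            if parts[0] == "mu":
                mu[(parts[1], parts[2])] = float(np.mean(chain))
            elif parts[0] == "sigma":
                sigma[(parts[1], parts[2])] = float(np.mean(chain))
        return cls(mu=mu, sigma=sigma)


@dataclass
class PosteriorFit:
    """Retained MCMC samples plus deviance bookkeeping.

    ``chains`` maps quantity names to 1-D arrays of length
    n_samples - n_burnin.  Naming: "mu:<param>:<group>",
    "sigma:<param>:<group>" for the hierarchy and "<param>:<pid>" for
    individual parameters on their natural scale (a, z, v_go, v_nogo, ter).
    """

    chains: dict
    n_samples: int
    n_burnin: int
    deviance: np.ndarray
    deviance_by_group: dict
    dhat: float
    dhat_by_group: dict
    participants: list
    model: object
    seed: int
    acceptance: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_samples - self.n_burnin

    def chain(self, name: str) -> np.ndarray:
        if name not in self.chains:
            raise KeyError(f"unknown quantity {name!r}")
        return self.chains[name]

    def point_estimates(self) -> pd.DataFrame:
        """Posterior-mean individual parameters, one row per participant."""
        rows = []
        for pid, grp in self.participants:
            rows.append({
                "participant_id": pid, "group": grp,
                **{p: float(np.mean(self.chains[f"{p}:{pid}"]))
                   for p in ("a", "z", "v_go", "v_nogo", "ter")}})
        return pd.DataFrame(rows)


def export_chains(fit: PosteriorFit, path) -> None:
    """Tidy CSV of all chains: quantity, group/participant, iteration, value."""
    frames = []
    for name, chain in fit.chains.items():
        parts = name.split(":")
        unit = parts[-1]
        frames.append(pd.DataFrame({
            "quantity": name, "unit": unit,
            "iteration": np.arange(chain.size), "value": chain}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# data preparation


class _PData:
    """Per-participant trial arrays entering the likelihood."""

    __slots__ = ("pid", "gi", "rt_go", "rt_nogo", "n_wgo", "n_wnogo", "tmin")

    def __init__(self, pid, gi, rt_go, rt_nogo, n_wgo, n_wnogo, tmin):
        self.pid, self.gi = pid, gi
        self.rt_go, self.rt_nogo = rt_go, rt_nogo
        self.n_wgo, self.n_wnogo = n_wgo, n_wnogo
        self.tmin = tmin

    def loglik(self, a, z, v_go, v_nogo, ter) -> float:
        return participant_loglik(self.rt_go, self.rt_nogo, self.n_wgo,
                                  self.n_wnogo, a, z, v_go, v_nogo, ter)


def _prepare(data: StudyDataset, groups, allow_empty: bool):
    pdata = []
    gidx = {g: i for i, g in enumerate(groups)}
    by_pid: dict = {pid: [] for pid, _ in data.participants}
    for t in data.trials:
        if t.valid:
            by_pid[t.participant_id].append(t)
    for pid, grp in data.participants:
        tr = by_pid[pid]
        rt_go = np.array([t.latency_ms / 1000.0 for t in tr
                          if t.condition == "GO" and t.responded], dtype=float)
        rt_nogo = np.array([t.latency_ms / 1000.0 for t in tr
                            if t.condition == "NOGO" and t.responded], dtype=float)
        n_wgo = sum(1 for t in tr if t.condition == "GO" and not t.responded)
        n_wnogo = sum(1 for t in tr if t.condition == "NOGO" and not t.responded)
        if not allow_empty:
            if rt_go.size + n_wgo == 0 or rt_nogo.size + n_wnogo == 0:
                raise ValueError(f"participant {pid} lacks valid trials in one condition")
        rts = np.concatenate([rt_go, rt_nogo])
        tmin = float(rts.min()) if rts.size else 1.5
        pdata.append(_PData(pid, gidx[grp], rt_go, rt_nogo, n_wgo, n_wnogo, tmin))
    return pdata


# ---------------------------------------------------------------------------
# the sampler


def _quantities(spec) -> list:
    q = ["a"]
    if spec.z_free:
        q.append("z_logit")
    q.append("v" if spec.drift_symmetric else "v_go")
    if not spec.drift_symmetric:
        q.append("v_nogo")
    q.append("ter")
    return q


def _natural(spec, vals: dict, p: int):
    a = vals["a"][p]
    z = expit(vals["z_logit"][p]) if spec.z_free else 0.5
    if spec.drift_symmetric:
        v_go, v_nogo = vals["v"][p], -vals["v"][p]
    else:
        v_go, v_nogo = vals["v_go"][p], vals["v_nogo"][p]
    return a, z, v_go, v_nogo, vals["ter"][p]


def sample_mu_prior(q: str, n: int, rng, ter_upper: float = 1.5) -> np.ndarray:
    """Draw from the prior on a group mean (used by prior-recovery tests)."""
    m, s, lo, hi = MU_PRIOR[q]
    if hi is None:
        hi = ter_upper
    return truncnorm.rvs((lo - m) / s, (hi - m) / s, loc=m, scale=s,
                         size=n, random_state=rng)


def fit_hierarchical(data: StudyDataset, spec, config: McmcConfig | None = None,
                     seed: int = 0, allow_empty: bool = False) -> PosteriorFit:
    """Sample the joint posterior of the hierarchical Go/No-Go diffusion model.

    ``spec`` is a ModelSpec (which parameters are constrained); ``config``
    holds chain length and burn-in.  Deterministic given ``seed``.  With
    ``allow_empty`` participants without valid trials contribute likelihood
    one, so the fit returns the prior (useful for prior-recovery checks).
    """
    cfg = config or McmcConfig()
    rng = np.random.default_rng(int(seed))
    groups = [g for g in GROUPS if any(grp == g for _, grp in data.participants)]
    if not groups:
        groups = list(GROUPS[:1])
    pdata = _prepare(data, groups, allow_empty)
    n_p, n_g = len(pdata), len(groups)
    qs = _quantities(spec)
    tmin_global = min((pd_.tmin for pd_ in pdata), default=1.5)

    # ---- initial state -----------------------------------------------------
    ind = {}
    for q in qs:
        if q == "a":
            ind[q] = np.full(n_p, 1.5)
        elif q == "z_logit":
            ind[q] = np.full(n_p, 0.2)
        elif q in ("v", "v_go"):
            ind[q] = np.full(n_p, 1.5)
        elif q == "v_nogo":
            ind[q] = np.full(n_p, -1.5)
        else:
            # true ter sits just below the fastest response
            ind[q] = np.array([max(0.03, min(0.6 * pd_.tmin, pd_.tmin - 0.06))
                               for pd_ in pdata])
    ll = np.empty(n_p)
    for p, pd_ in enumerate(pdata):
        ok = False
        for _ in range(8):
            ll[p] = pd_.loglik(*_natural(spec, ind, p))
            if np.isfinite(ll[p]):
                ok = True
                break
            ind["ter"][p] *= 0.5
        if not ok:
            raise InitializationError(
                f"non-finite likelihood at initialization for participant {pd_.pid}")
    mu = {q: np.array([float(np.mean(ind[q][[pd_.gi == g for pd_ in pdata]]))
                       if any(pd_.gi == g for pd_ in pdata) else MU_PRIOR[q][0]
                       for g in range(n_g)]) for q in qs}
    sig = {q: np.full(n_g, 0.5 * SIGMA_SCALE[q] if q != "ter" else 0.05) for q in qs}
    gi = np.array([pd_.gi for pd_ in pdata])
    members = [np.flatnonzero(gi == g) for g in range(n_g)]

    # ---- proposal bookkeeping ----------------------------------------------
    step_ind = {q: np.full(n_p, _INIT_STEP[q]) for q in qs}
    step_sig = {q: np.full(n_g, 0.4) for q in qs}  # log-scale walk
    acc = {k: 0 for k in ("ind", "mu", "sigma")}
    att = {k: 0 for k in ("ind", "mu", "sigma")}
    a_ind = {q: np.zeros(n_p) for q in qs}
    n_ind = {q: np.zeros(n_p) for q in qs}
    a_mu = {q: np.zeros(n_g) for q in qs}
    a_sig = {q: np.zeros(n_g) for q in qs}
    n_hyp = {q: np.zeros(n_g) for q in qs}

    def ind_bounds(q, p):
        lo, hi = IND_DOMAIN[q]
        if q == "ter":
            hi = pdata[p].tmin - 1e-3
        return lo, hi

    mu_bounds = {}
    for q in qs:
        m0, s0, lo, hi = MU_PRIOR[q]
        mu_bounds[q] = (lo, tmin_global if hi is None else hi, m0, s0)

    # per-participant joint proposal: empirical covariance accumulated over
    # the second half of burn-in (Welford), Cholesky refreshed during
    # adaptation and frozen with everything else at the end of burn-in
    d = len(qs)
    cov_start = cfg.n_burnin // 2
    w_count = 0
    w_mean = np.zeros((n_p, d))
    w_m2 = np.zeros((n_p, d, d))
    joint_chol = [None] * n_p
    joint_scale = np.full(n_p, 2.38 / math.sqrt(d))
    a_joint = np.zeros(n_p)
    n_joint = np.zeros(n_p)

    def _refresh_chol():
        if w_count < max(2 * d, 20):
            return
        for p in range(n_p):
            cov = w_m2[p] / (w_count - 1)
            cov[np.diag_indices(d)] += 1e-8 + 1e-3 * np.diag(cov)
            try:
                joint_chol[p] = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                joint_chol[p] = None

    n_ret = cfg.n_samples - cfg.n_burnin
    cols_ind = {q: i for i, q in enumerate(qs)}
    width = n_p * len(qs) + 2 * n_g * len(qs)
    out = np.empty((n_ret, width))
    dev = np.empty(n_ret)
    dev_g = np.empty((n_ret, n_g))

    log = math.log
    for it in range(cfg.n_samples):
        # individual-level updates
        for p in range(n_p):
            pd_ = pdata[p]
            g = pd_.gi
            for q in qs:
                old = ind[q][p]
                new = old + step_ind[q][p] * rng.standard_normal()
                n_ind[q][p] += 1
                lo, hi = ind_bounds(q, p)
                if not (lo < new < hi):
                    continue
                mq, sq = mu[q][g], sig[q][g]
                dprior = ((old - mq) ** 2 - (new - mq) ** 2) / (2.0 * sq * sq)
                ind[q][p] = new
                ll_new = pd_.loglik(*_natural(spec, ind, p))
                if ll_new == -np.inf:
                    ind[q][p] = old
                    continue
                if log(rng.random()) < dprior + ll_new - ll[p]:
                    ll[p] = ll_new
                    a_ind[q][p] += 1
                else:
                    ind[q][p] = old
            # joint correlated proposal across this participant's parameters
            if joint_chol[p] is not None:
                step = joint_scale[p] * (joint_chol[p] @ rng.standard_normal(d))
                n_joint[p] += 1
                old_vec = np.array([ind[q][p] for q in qs])
                new_vec = old_vec + step
                ok = True
                dprior = 0.0
                for j, q in enumerate(qs):
                    lo, hi = ind_bounds(q, p)
                    if not (lo < new_vec[j] < hi):
                        ok = False
                        break
                    mq, sq = mu[q][g], sig[q][g]
                    dprior += ((old_vec[j] - mq) ** 2
                               - (new_vec[j] - mq) ** 2) / (2.0 * sq * sq)
                if ok:
                    for j, q in enumerate(qs):
                        ind[q][p] = new_vec[j]
                    ll_new = pd_.loglik(*_natural(spec, ind, p))
                    if ll_new > -np.inf and log(rng.random()) < dprior + ll_new - ll[p]:
                        ll[p] = ll_new
                        a_joint[p] += 1
                    else:
                        for j, q in enumerate(qs):
                            ind[q][p] = old_vec[j]
        # group-level updates: exact Gibbs for the mean (normal-normal
        # conditional, redrawn on the rare bound violation), log-scale
        # random-walk Metropolis for the spread
        for q in qs:
            lo_m, hi_m, m0, s0 = mu_bounds[q]
            hs = SIGMA_SCALE[q]
            for g in range(n_g):
                vals = ind[q][members[g]]
                n_hyp[q][g] += 1
                sq = sig[q][g]
                prec = 1.0 / (s0 * s0) + vals.size / (sq * sq)
                cmean = (m0 / (s0 * s0) + np.sum(vals) / (sq * sq)) / prec
                csd = 1.0 / math.sqrt(prec)
                for _ in range(20):
                    draw = cmean + csd * rng.standard_normal()
                    if lo_m < draw < hi_m:
                        mu[q][g] = draw
                        a_mu[q][g] += 1
                        break
                mq = mu[q][g]
                old = sig[q][g]
                new = old * math.exp(step_sig[q][g] * rng.standard_normal())
                if 1e-4 < new < 50.0:
                    ssq = np.sum((vals - mq) ** 2)
                    dpost = (old ** 2 - new ** 2) / (2.0 * hs * hs)  # half-normal prior
                    dpost += vals.size * (log(old) - log(new))
                    dpost += ssq / (2.0 * old * old) - ssq / (2.0 * new * new)
                    dpost += log(new) - log(old)  # Jacobian of the log-scale walk
                    if log(rng.random()) < dpost:
                        sig[q][g] = new
                        a_sig[q][g] += 1
        # accumulate joint-proposal covariance over the late burn-in
        if cov_start <= it < cfg.n_burnin:
            w_count += 1
            vecs = np.column_stack([ind[q] for q in qs])
            delta = vecs - w_mean
            w_mean += delta / w_count
            w_m2 += np.einsum("pi,pj->pij", delta, vecs - w_mean)
        # step-size adaptation, burn-in only
        if it < cfg.n_burnin and (it + 1) % cfg.adapt_interval == 0:
            for q in qs:
                for arr, accs, atts in ((step_ind[q], a_ind[q], n_ind[q]),
                                        (step_sig[q], a_sig[q], n_hyp[q])):
                    with np.errstate(invalid="ignore", divide="ignore"):
                        rate = np.where(atts > 0, accs / np.maximum(atts, 1), cfg.target_accept)
                    arr *= np.exp(0.8 * (rate - cfg.target_accept))
                    np.clip(arr, 1e-5, 5.0, out=arr)
                    accs[:] = 0.0
                    atts[:] = 0.0
            _refresh_chol()
            mask = n_joint > 0
            if mask.any():
                rate = np.where(mask, a_joint / np.maximum(n_joint, 1), 0.25)
                joint_scale *= np.exp(0.8 * (rate - 0.25))
                np.clip(joint_scale, 1e-3, 10.0, out=joint_scale)
                a_joint[:] = 0.0
                n_joint[:] = 0.0
        # recording
        if it >= cfg.n_burnin:
            r = it - cfg.n_burnin
            col = 0
            for q in qs:
                out[r, col:col + n_p] = ind[q]
                col += n_p
            for q in qs:
                out[r, col:col + n_g] = mu[q]
                col += n_g
                out[r, col:col + n_g] = sig[q]
                col += n_g
            dev[r] = -2.0 * float(np.sum(ll))
            for g in range(n_g):
                dev_g[r, g] = -2.0 * float(np.sum(ll[members[g]]))

    # ---- unpack chains -----------------------------------------------------
    chains: dict = {}
    col = 0
    raw_ind = {}
    for q in qs:
        raw_ind[q] = out[:, col:col + n_p]
        col += n_p
    for q in qs:
        for g, gname in enumerate(groups):
            chains[f"mu:{q}:{gname}"] = out[:, col + g].copy()
        col += n_g
        for g, gname in enumerate(groups):
            chains[f"sigma:{q}:{gname}"] = out[:, col + g].copy()
        col += n_g
    for p, pd_ in enumerate(pdata):
        chains[f"a:{pd_.pid}"] = raw_ind["a"][:, p].copy()
        if spec.z_free:
            chains[f"z:{pd_.pid}"] = expit(raw_ind["z_logit"][:, p])
        else:
            chains[f"z:{pd_.pid}"] = np.full(n_ret, 0.5)
        if spec.drift_symmetric:
            chains[f"v_go:{pd_.pid}"] = raw_ind["v"][:, p].copy()
            chains[f"v_nogo:{pd_.pid}"] = -raw_ind["v"][:, p]
        else:
            chains[f"v_go:{pd_.pid}"] = raw_ind["v_go"][:, p].copy()
            chains[f"v_nogo:{pd_.pid}"] = raw_ind["v_nogo"][:, p].copy()
        chains[f"ter:{pd_.pid}"] = raw_ind["ter"][:, p].copy()
    # convenience aliases on the natural scale / shared drift
    for gname in groups:
        if spec.z_free:
            chains[f"mu:z:{gname}"] = expit(chains[f"mu:z_logit:{gname}"])
        else:
            chains[f"mu:z:{gname}"] = np.full(n_ret, 0.5)
        if spec.drift_symmetric:
            chains[f"mu:v_go:{gname}"] = chains[f"mu:v:{gname}"].copy()
            chains[f"mu:v_nogo:{gname}"] = -chains[f"mu:v:{gname}"]

    # ---- deviance at the posterior mean ------------------------------------
    dhat_by_group = {}
    dhat = 0.0
    for p, pd_ in enumerate(pdata):
        theta = (float(np.mean(chains[f"a:{pd_.pid}"])),
                 float(np.clip(np.mean(chains[f"z:{pd_.pid}"]), 1e-6, 1 - 1e-6)),
                 float(np.mean(chains[f"v_go:{pd_.pid}"])),
                 float(np.mean(chains[f"v_nogo:{pd_.pid}"])),
                 float(np.mean(chains[f"ter:{pd_.pid}"])))
        d = -2.0 * pd_.loglik(*theta)
        dhat += d
        gname = groups[pd_.gi]
        dhat_by_group[gname] = dhat_by_group.get(gname, 0.0) + d

    acceptance = {"ind": {q: float(np.mean(a_ind[q] / np.maximum(n_ind[q], 1))) for q in qs}}
    return PosteriorFit(
        chains=chains, n_samples=cfg.n_samples, n_burnin=cfg.n_burnin,
        deviance=dev, deviance_by_group={groups[g]: dev_g[:, g].copy() for g in range(n_g)},
        dhat=dhat, dhat_by_group=dhat_by_group,
        participants=[(pd_.pid, groups[pd_.gi]) for pd_ in pdata],
        model=spec, seed=int(seed), acceptance=acceptance)


# ---------------------------------------------------------------------------
# diagnostics


def _mcmc_var(x: np.ndarray) -> float:
    """Monte-Carlo variance via Geyer's initial-positive-sequence estimator
    of the spectral density at frequency zero."""
    n = x.size
    d = x - x.mean()
    g0 = float(np.dot(d, d)) / n
    if g0 == 0.0:
        return 0.0

    def gamma(k):
        if k >= n:
            return 0.0
        return float(np.dot(d[: n - k], d[k:])) / n

    s = -g0
    m = 0
    while True:
        G = gamma(2 * m) + gamma(2 * m + 1)
        if G <= 0.0 or 2 * m + 1 >= n - 1:
            break
        s += 2.0 * G
        m += 1
    return max(s, 0.0)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke z-score: mean of the first 10% vs the last 50% of the chain,
    with spectral-density variance estimates."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 100)")
    if np.ptp(x) == 0.0:  # constant chain: trivially stationary
        return 0.0
    a = x[: max(1, int(first * n))]
    b = x[n - int(last * n):]
    var = _mcmc_var(a) / a.size + _mcmc_var(b) / b.size
    if var == 0.0:
        return 0.0 if a.mean() == b.mean() else math.inf
    return float((a.mean() - b.mean()) / math.sqrt(var))


@dataclass
class ConvergenceReport:
    scores: dict
    threshold: float

    @property
    def flagged(self) -> list:
        return [k for k, z in self.scores.items() if abs(z) > self.threshold]

    @property
    def fraction_flagged(self) -> float:
        return len(self.flagged) / max(len(self.scores), 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"quantity": list(self.scores),
                             "z": list(self.scores.values()),
                             "flagged": [abs(z) > self.threshold
                                         for z in self.scores.values()]})


def geweke_check(fit: PosteriorFit, threshold: float = 2.0) -> ConvergenceReport:
    """Per-quantity Geweke convergence scores for all retained chains."""
    scores = {name: geweke_z(chain) for name, chain in fit.chains.items()}
    return ConvergenceReport(scores=scores, threshold=threshold)


def compute_dic(fit: PosteriorFit):
    """Deviance information criterion.

    Returns (DIC, Dbar, Dhat, pD) with Dbar the posterior-mean deviance,
    Dhat the deviance at posterior-mean individual parameters,
    pD = Dbar - Dhat and DIC = Dbar + pD.  Negative pD is reported with a
    warning, not an error.
    """
    if fit.deviance.size == 0:
        raise ValueError("deviance trace is empty")
    dbar = float(np.mean(fit.deviance))
    dhat = float(fit.dhat)
    pd_ = dbar - dhat
    if pd_ < 0:
        warnings.warn(f"negative effective parameter count pD={pd_:.2f}", RuntimeWarning)
    return dbar + pd_, dbar, dhat, pd_


def dic_by_group(fit: PosteriorFit) -> dict:
    """DIC decomposition restricted to each group's trials."""
    out = {}
    for g, trace in fit.deviance_by_group.items():
        dbar = float(np.mean(trace))
        pd_ = dbar - fit.dhat_by_group.get(g, dbar)
        out[g] = dbar + pd_
    return out
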