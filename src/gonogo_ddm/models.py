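"""Model variants, DIC model comparison, posterior-predictive checks.

Four constraint variants of the Go/No-Go diffusion model are compared:

1. unbiased start (z = 0.5), symmetric drifts (v_nogo = -v_go)
2. unbiased start, free drifts
3. free start, symmetric drifts
4. free start, free drifts

Drift symmetry acts at the individual level: variants 1 and 3 carry a
single underlying drift per participant.  Models are ranked by DIC; the
per-group decomposition restricts the deviance sum to that group's trials.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import DDMParams, sample_trials
from .hierarchy import (McmcConfig, PosteriorFit, compute_dic, dic_by_group,
                        fit_hierarchical, geweke_check)
from .io import StudyDataset

logger = logging.getLogger("gonogo_ddm")


@dataclass(frozen=True)
class ModelSpec:
    variant_id: int
    z_free: bool
    drift_symmetric: bool

    _TABLE = {1: (False, True), 2: (False, False), 3: (True, True), 4: (True, False)}

    def __post_init__(self):
        expected = self._TABLE.get(self.variant_id)
        if expected is None:
            raise ValueError(f"variant_id must be 1..4, got {self.variant_id}")
        if (self.z_free, self.drift_symmetric) != expected:
            raise ValueError(f"variant {self.variant_id} requires "
                             f"(z_free, drift_symmetric) = {expected}")

    @classmethod
    def variant(cls, k: int) -> "ModelSpec":
        if k not in cls._TABLE:
            raise ValueError(f"variant_id must be 1..4, got {k}")
        z_free, sym = cls._TABLE[k]
        return cls(variant_id=k, z_free=z_free, drift_symmetric=sym)


ALL_VARIANTS = tuple(ModelSpec.variant(k) for k in (1, 2, 3, 4))


def compare_models(data: StudyDataset, config: McmcConfig | None = None,
                   seed: int = 0, variants=ALL_VARIANTS,
                   convergence_gate: float = 0.2):
    """Fit every variant and rank them by DIC.

    Returns (table, best_spec, fits).  The table holds DIC, Dbar, pD, the
    per-group DIC decomposition, and delta_dic relative to the best
    converged model.  A variant whose Geweke check flags more than
    ``convergence_gate`` of quantities stays in the table but is excluded
    from the argmin with a warning.
    """
    rows, fits = [], {}
    ss = np.random.SeedSequence(int(seed))
    child = ss.generate_state(len(variants))
    for spec, s in zip(variants, child):
        fit = fit_hierarchical(data, spec, config=config, seed=int(s % (2 ** 31)))
        fits[spec.variant_id] = fit
        dic, dbar, dhat, pd_ = compute_dic(fit)
        frac = geweke_check(fit).fraction_flagged
        converged = frac <= convergence_gate
        if not converged:
            logger.warning("variant %d: %.0f%% of quantities flagged by Geweke; "
                           "excluded from model selection", spec.variant_id, 100 * frac)
        row = {"variant": spec.variant_id, "dic": dic, "dbar": dbar, "pd": pd_,
               "geweke_flagged_fraction": frac, "converged": converged}
        for g, v in dic_by_group(fit).items():
            row[f"dic_{g}"] = v
        rows.append(row)
    table = pd.DataFrame(rows)
    eligible = table[table["converged"]]
    if eligible.empty:
        raise RuntimeError("no model variant converged")
    best_id = int(eligible.loc[eligible["dic"].idxmin(), "variant"])
    best_dic = float(eligible["dic"].min())
    table["delta_dic"] = table["dic"] - best_dic
    return table, ModelSpec.variant(best_id), fits


@dataclass
class PPCResult:
    """Averaged posterior-predictive summaries per group and condition.

    Histograms use 25 ms bins over [0, 1500] ms.  Displays follow the
    signed-axis convention: correct Go latencies on the positive axis,
    No-Go commission latencies mirrored onto the negative axis.  Densities
    are normalized per condition so that response mass plus non-response
    probability equals 1.
    """

    bins_ms: np.ndarray
    observed_density: dict   # (group, condition) -> array per bin
    predicted_density: dict  # (group, condition) -> mean over simulations
    predicted_rates: dict    # (group, condition) -> per-sim response-rate array
    observed_rates: dict     # (group, condition) -> scalar response rate
    n_sims: int
    predicted_deciles: dict = None  # group -> (n_sims, 9) Go-latency deciles
    observed_deciles: dict = None   # group -> 9 observed Go-latency deciles

    def rate_band(self, group: str, condition: str, level: float = 0.95):
        sims = self.predicted_rates[(group, condition)]
        lo, hi = np.quantile(sims, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)

    def decile_bands(self, group: str, level: float = 0.95):
        """Per-decile (lo, hi) bands for the Go-latency deciles."""
        sims = self.predicted_deciles[group]
        qs = [(1 - level) / 2, 1 - (1 - level) / 2]
        lo, hi = np.nanquantile(sims, qs, axis=0)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        rows = []
        centers = 0.5 * (self.bins_ms[:-1] + self.bins_ms[1:])
        for (g, c), dens in self.predicted_density.items():
            sign = 1.0 if c == "GO" else -1.0
            for b, d in enumerate(dens):
                rows.append({"group": g, "condition": c,
                             "bin_ms": sign * centers[b],
                             "observed_density": self.observed_density[(g, c)][b],
                             "predicted_density": d})
        return pd.DataFrame(rows)


def _hist_density(lat_ms: np.ndarray, n_trials: int, bins: np.ndarray) -> np.ndarray:
    """Histogram scaled so that sum(density * binwidth) = response fraction."""
    if n_trials == 0:
        return np.zeros(bins.size - 1)
    counts, _ = np.histogram(lat_ms, bins=bins)
    width = np.diff(bins)
    return counts / (n_trials * width)


def posterior_predictive(fit: PosteriorFit, data: StudyDataset, n_sims: int = 500,
                         seed: int = 0, dt: float = 2e-4,
                         deadline_s: float = 1.5,
                         track_deciles: bool = True) -> PPCResult:
    """Average ``n_sims`` simulations of model-predicted data matched to the
    observed design (one joint posterior draw per simulation, preserving
    posterior correlations; per participant exactly the observed number of
    valid trials per condition)."""
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    rng = np.random.default_rng(int(seed))
    bins = np.arange(0.0, 1500.0 + 25.0, 25.0)
    groups = sorted({g for _, g in fit.participants})
    counts = {}
    obs_lat = {(g, c): [] for g in groups for c in ("GO", "NOGO")}
    obs_resp = {(g, c): [0, 0] for g in groups for c in ("GO", "NOGO")}
    pid_group = dict(fit.participants)
    for t in data.trials:
        if not t.valid or t.participant_id not in pid_group:
            continue
        key = (t.participant_id, t.condition)
        counts[key] = counts.get(key, 0) + 1
        gkey = (pid_group[t.participant_id], t.condition)
        obs_resp[gkey][1] += 1
        if t.responded:
            obs_resp[gkey][0] += 1
            obs_lat[gkey].append(t.latency_ms)

    draw_idx = rng.integers(fit.n_retained, size=n_sims)
    sim_lat = {k: [[] for _ in range(n_sims)] for k in obs_lat}
    sim_resp = {k: np.zeros((n_sims, 2)) for k in obs_lat}
    deciles = {g: np.full((n_sims, 9), np.nan) for g in groups}
    for s in range(n_sims):
        r = draw_idx[s]
        for pid, g in fit.participants:
            params = DDMParams(
                a=float(fit.chains[f"a:{pid}"][r]),
                z=float(np.clip(fit.chains[f"z:{pid}"][r], 1e-6, 1 - 1e-6)),
                v_go=float(fit.chains[f"v_go:{pid}"][r]),
                v_nogo=float(fit.chains[f"v_nogo:{pid}"][r]),
                ter=float(fit.chains[f"ter:{pid}"][r]))
            for c in ("GO", "NOGO"):
                n = counts.get((pid, c), 0)
                if n == 0:
                    continue
                sim = sample_trials(params, c, n, deadline_s,
                                    seed=int(rng.integers(2 ** 31)), dt=dt)
                lats = [t.latency_ms for t in sim if t.responded]
                sim_lat[(g, c)][s].extend(lats)
                sim_resp[(g, c)][s, 0] += len(lats)
                sim_resp[(g, c)][s, 1] += n
        if track_deciles:
            for g in groups:
                lats = sim_lat[(g, "GO")][s]
                if len(lats) >= 10:
                    deciles[g][s] = np.percentile(lats, np.arange(10, 100, 10))

    observed_density, predicted_density = {}, {}
    predicted_rates, observed_rates = {}, {}
    for key in obs_lat:
        n_obs = obs_resp[key][1]
        observed_density[key] = _hist_density(np.array(obs_lat[key]), n_obs, bins)
        dens = np.stack([
            _hist_density(np.array(sim_lat[key][s]),
                          int(sim_resp[key][s, 1]) or 1, bins)
            for s in range(n_sims)])
        predicted_density[key] = dens.mean(axis=0)
        with np.errstate(invalid="ignore"):
            predicted_rates[key] = sim_resp[key][:, 0] / np.maximum(sim_resp[key][:, 1], 1)
        observed_rates[key] = obs_resp[key][0] / n_obs if n_obs else np.nan
    obs_dec = {}
    for g in groups:
        lats = obs_lat[(g, "GO")]
        obs_dec[g] = (np.percentile(lats, np.arange(10, 100, 10))
                      if len(lats) >= 10 else np.full(9, np.nan))
    return PPCResult(bins_ms=bins, observed_density=observed_density,
                     predicted_density=predicted_density,
                     predicted_rates=predicted_rates, observed_rates=observed_rates,
                     n_sims=n_sims, predicted_deciles=deciles,
                     observed_deciles=obs_dec)
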