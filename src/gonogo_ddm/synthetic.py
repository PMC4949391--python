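"""Synthetic Go/No-Go cohorts with known hierarchical ground truth.

Each cohort mirrors the study design: three diagnostic groups (default
sizes 19 PSP, 24 PD, 26 controls), 300 trials per participant, 50% Go /
50% No-Go, a 1500 ms response deadline, and a random 1500-2500 ms
foreperiod that is generated for realism but never influences latencies.
Participant parameters are drawn from group-level normal distributions on
the same scales the hierarchical fit uses (z on the logit scale), and
trials are simulated by forward diffusion with deadline censoring.

Preset magnitudes are synthetic: they encode the qualitative group
orderings of interest (PSP bias z elevated, patient drift rates and
non-decision times reduced), not estimates from any recorded cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .ddm import DDMParams, sample_trials
from .io import GROUPS, StudyDataset, TrialRecord

# sampling-scale parameter names: z is carried as logit(z)
HYPER_PARAMS = ("a", "z_logit", "v_go", "v_nogo", "ter")


@dataclass(frozen=True)
class CohortTruth:
    """Ground-truth hyperparameters and design constants for one cohort."""

    group_means: dict  # group -> {param: mean}
    group_sds: dict    # group -> {param: sd}
    n_participants: dict = field(default_factory=lambda: {"PSP": 19, "PD": 24, "CONTROL": 26})
    n_trials: int = 300
    go_fraction: float = 0.5
    deadline_s: float = 1.5
    foreperiod_range_s: tuple = (1.5, 2.5)
    invalid_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for g in self.n_participants:
            if g not in self.group_means or g not in self.group_sds:
                raise ValueError(f"missing hyperparameters for group {g}")
            for p in HYPER_PARAMS:
                if p not in self.group_means[g] or p not in self.group_sds[g]:
                    raise ValueError(f"missing hyperparameter {p} for group {g}")
                if self.group_sds[g][p] <= 0:
                    raise ValueError("group-level sds must be positive")
        if not 0.0 < self.go_fraction < 1.0:
            raise ValueError("go_fraction must be in (0,1)")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials (one per condition)")
        for g in self.group_means:
            if self.group_means[g]["ter"] >= 0.8 * self.deadline_s:
                raise ValueError(
                    f"infeasible truth: mean non-decision time of {g} "
                    f"({self.group_means[g]['ter']} s) leaves no room before the deadline")


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    raise ValueError(f"cannot draw from N({mean},{sd}) within ({lo},{hi})")


def draw_participant_params(truth: CohortTruth, group: str, rng) -> DDMParams:
    m, s = truth.group_means[group], truth.group_sds[group]
    a = _truncated_normal(rng, m["a"], s["a"], 0.05, 12.0)
    z = float(expit(rng.normal(m["z_logit"], s["z_logit"])))
    v_go = rng.normal(m["v_go"], s["v_go"])
    v_nogo = rng.normal(m["v_nogo"], s["v_nogo"])
    ter = _truncated_normal(rng, m["ter"], s["ter"], 0.02, truth.deadline_s)
    return DDMParams(a=a, z=z, v_go=v_go, v_nogo=v_nogo, ter=ter)


def generate_cohort(truth: CohortTruth, seed: int | None = None,
                    dt: float = 2e-4) -> tuple[StudyDataset, dict]:
    """Simulate a full cohort; returns (dataset, {participant_id: DDMParams}).

    Condition order and target sides are randomized per participant; a
    configurable fraction of trials (default 5%) is flagged invalid
    uniformly at random to emulate blink/artefact rejection.  Deterministic
    given the seed.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    roster: list[tuple[str, str]] = []
    params: dict[str, DDMParams] = {}
    for group in GROUPS:
        if group not in truth.n_participants:
            continue
        for k in range(truth.n_participants[group]):
            pid = f"{group}{k + 1:02d}"
            roster.append((pid, group))
            p = draw_participant_params(truth, group, rng)
            params[pid] = p
            n_go = int(round(truth.n_trials * truth.go_fraction))
            n_nogo = truth.n_trials - n_go
            go = sample_trials(p, "GO", n_go, truth.deadline_s,
                               seed=int(rng.integers(2 ** 31)), dt=dt)
            nogo = sample_trials(p, "NOGO", n_nogo, truth.deadline_s,
                                 seed=int(rng.integers(2 ** 31)), dt=dt)
            pool = go + nogo
            order = rng.permutation(len(pool))
            invalid = set(np.flatnonzero(rng.random(len(pool)) < truth.invalid_fraction))
            for slot, idx in enumerate(order):
                t = pool[idx]
                trials.append(replace(
                    t, participant_id=pid, group=group,
                    target_side=("LEFT", "RIGHT")[int(rng.integers(2))],
                    foreperiod_ms=float(rng.uniform(*truth.foreperiod_range_s)) * 1000.0,
                    valid=slot not in invalid))
    return StudyDataset(trials=trials, participants=roster), params


def _truth(means, sds, **kw) -> CohortTruth:
    return CohortTruth(group_means=means, group_sds=sds, **kw)


def preset_cohorts(name: str) -> CohortTruth:
    """Built-in cohort definitions.

    null_cohort : all three groups share identical hyperparameters.
    paper_like  : synthetic magnitudes encoding the qualitative orderings of
                  interest -- PSP bias z above PD above 0.5, both patient
                  groups' Go drift and non-decision time below controls.
    separable   : inter-group gaps of at least 5 group SDs on z, v_go and
                  ter, forcing near-perfect classification.
    """
    control = {"a": 1.6, "z_logit": 0.3, "v_go": 3.0, "v_nogo": -2.0, "ter": 0.21}
    sds = {"a": 0.15, "z_logit": 0.25, "v_go": 0.35, "v_nogo": 0.35, "ter": 0.02}
    if name == "null_cohort":
        return _truth({g: dict(control) for g in GROUPS}, {g: dict(sds) for g in GROUPS})
    if name == "paper_like":
        means = {
            "PSP": {"a": 1.6, "z_logit": 1.0, "v_go": 1.7, "v_nogo": -1.4, "ter": 0.16},
            "PD": {"a": 1.6, "z_logit": 0.5, "v_go": 2.3, "v_nogo": -1.5, "ter": 0.17},
            "CONTROL": dict(control),
        }
        return _truth(means, {g: dict(sds) for g in GROUPS})
    if name == "separable":
        tight = {"a": 0.04, "z_logit": 0.05, "v_go": 0.05, "v_nogo": 0.05, "ter": 0.005}
        means = {
            "PSP": {"a": 1.6, "z_logit": 1.8, "v_go": 1.2, "v_nogo": -1.0, "ter": 0.12},
            "PD": {"a": 1.6, "z_logit": 0.9, "v_go": 2.6, "v_nogo": -1.6, "ter": 0.18},
            "CONTROL": {"a": 1.6, "z_logit": 0.2, "v_go": 4.0, "v_nogo": -2.5, "ter": 0.24},
        }
        return _truth(means, {g: dict(tight) for g in GROUPS})
    raise ValueError(f"unknown preset {name!r}")


def write_truth_sidecar(truth: CohortTruth, params: dict, path) -> None:
    """Ground-truth sidecar: hyperparameters, per-participant parameters, seed."""
    import json
    from dataclasses import asdict

    payload = {"truth": asdict(truth),
               "participants": {pid: asdict(p) for pid, p in params.items()}}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
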