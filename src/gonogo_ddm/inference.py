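"""Behavioural measures, frequentist group tests, Bayesian posterior contrasts.

Four behavioural measures are computed per participant from valid trials,
sides pooled: omission rate (Go trials without a response), commission
rate (No-Go trials with a response), and the mean saccadic latencies of
successful Go trials and of No-Go commission trials.

Group statistics follow the classical reporting style for this design:
one-way ANOVA with partial eta squared, plus the three pairwise
equal-variance t-tests, uncorrected.  The Bayesian contrast P_p|D is the
proportion of retained posterior samples supporting a directional
hypothesis about group-level means; ties count as not supporting (a
measure-zero convention for continuous chains).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import PosteriorFit
from .io import StudyDataset


@dataclass(frozen=True)
class BehaviouralMeasures:
    participant_id: str
    group: str
    omission_rate: float
    commission_rate: float
    mean_go_latency_ms: Optional[float]    # None when no successful Go trial
    mean_nogo_latency_ms: Optional[float]  # None when no commission trial


def behavioural_measures(data: StudyDataset) -> pd.DataFrame:
    """Per-participant measures over valid trials; a participant with zero
    valid trials in a condition is flagged (``usable`` False) and excluded
    from group tests."""
    rows = []
    for pid, grp in data.participants:
        tr = [t for t in data.trials_of(pid) if t.valid]
        go = [t for t in tr if t.condition == "GO"]
        nogo = [t for t in tr if t.condition == "NOGO"]
        usable = bool(go) and bool(nogo)
        go_resp = [t.latency_ms for t in go if t.responded]
        nogo_resp = [t.latency_ms for t in nogo if t.responded]
        rows.append({
            "participant_id": pid, "group": grp, "usable": usable,
            "omission_rate": 1.0 - len(go_resp) / len(go) if go else np.nan,
            "commission_rate": len(nogo_resp) / len(nogo) if nogo else np.nan,
            "mean_go_latency_ms": float(np.mean(go_resp)) if go_resp else np.nan,
            "mean_nogo_latency_ms": float(np.mean(nogo_resp)) if nogo_resp else np.nan,
        })
    return pd.DataFrame(rows)


def frequentist_tests(values: pd.Series, groups: pd.Series) -> dict:
    """One-way ANOVA plus all pairwise equal-variance t-tests.

    ``values`` and ``groups`` are aligned per-participant series.  Returns
    {"anova": {F, df1, df2, p, partial_eta2}, "pairwise": {(g1, g2): {t, df, p}}}.
    """
    mask = ~pd.isna(values)
    values, groups = values[mask], groups[mask]
    names = list(pd.unique(groups))
    samples = [np.asarray(values[groups == g], dtype=float) for g in names]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need at least 2 groups with at least 2 participants each")
    if all(np.var(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in all groups")
    grand = np.concatenate(samples)
    ss_between = sum(len(s) * (s.mean() - grand.mean()) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df1, df2 = len(samples) - 1, len(grand) - len(samples)
    F, p = stats.f_oneway(*samples)
    out = {"anova": {"F": float(F), "df1": df1, "df2": df2, "p": float(p),
                     "partial_eta2": float(ss_between / (ss_between + ss_within))}}
    pairwise = {}
    for (i, gi), (j, gj) in combinations(enumerate(names), 2):
        t, pt = stats.ttest_ind(samples[i], samples[j], equal_var=True)
        pairwise[(gi, gj)] = {"t": float(t),
                              "df": len(samples[i]) + len(samples[j]) - 2,
                              "p": float(pt)}
    out["pairwise"] = pairwise
    return out


@dataclass(frozen=True)
class ContrastResult:
    hypothesis: str
    p_pd: float   # proportion of posterior samples supporting the hypothesis
    mcse: float   # Monte-Carlo standard error (batch means on the indicator)

    def complement(self) -> float:
        return 1.0 - self.p_pd


def _indicator_mcse(ind: np.ndarray, n_batches: int = 20) -> float:
    n = ind.size
    if n < n_batches * 2:
        return float(np.std(ind) / math.sqrt(max(n, 1)))
    m = n // n_batches
    means = ind[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_batches))


def bayesian_contrast(fit: PosteriorFit, lhs: str, op: str,
                      rhs) -> ContrastResult:
    """P_p|D for the directional hypothesis ``lhs op rhs``.

    ``lhs`` is a chain name (e.g. "mu:z:PSP"); ``rhs`` is another chain name
    or a numeric constant (one-group tests such as mu:z:PSP > 0.5).  Strict
    inequalities only, computed over retained samples.
    """
    if op not in (">", "<"):
        raise ValueError("op must be '>' or '<'")
    left = fit.chain(lhs)
    right = fit.chain(rhs) if isinstance(rhs, str) else float(rhs)
    ind = (left > right) if op == ">" else (left < right)
    ind = np.asarray(ind, dtype=float)
    return ContrastResult(hypothesis=f"{lhs} {op} {rhs}",
                          p_pd=float(ind.mean()), mcse=_indicator_mcse(ind))


def chi_square_counts(table: np.ndarray) -> dict:
    """Chi-square test of independence for categorical contingency tables
    (demographics reporting utility)."""
    chi2, p, dof, _ = stats.chi2_contingency(np.asarray(table))
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}


def contrast_table(results: dict) -> pd.DataFrame:
    """Tidy frame from {measure: frequentist_tests output} for reporting."""
    rows = []
    for measure, res in results.items():
        a = res["anova"]
        rows.append({"measure": measure, "comparison": "omnibus", "stat": a["F"],
                     "df": f"({a['df1']},{a['df2']})", "p": a["p"],
                     "partial_eta2": a["partial_eta2"]})
        for (g1, g2), r in res["pairwise"].items():
            rows.append({"measure": measure, "comparison": f"{g1} vs {g2}",
                         "stat": r["t"], "df": str(r["df"]), "p": r["p"],
                         "partial_eta2": np.nan})
    return pd.DataFrame(rows)
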