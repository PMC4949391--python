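"""Model-based three-way classification of participants.

A multinomial logistic-regression classifier with mild L2 regularization
is trained under leave-one-out cross-validation: each participant is
classified by a model trained on all others, with features standardized
using training-fold statistics only.  Feature sets are either the five
posterior-mean diffusion parameters (a, z, Ter, v_go, v_nogo) or the four
raw behavioural measures.  Performance is summarized per class by hit
rate (true-positive rate), precision and one-vs-rest ROC AUC, plus
class-size-weighted averages, and two feature sets are compared with a
permutation test that swaps, per participant, the two sets' leave-one-out
outcomes with probability one half.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .io import GROUPS

logger = logging.getLogger("gonogo_ddm")

DDM_FEATURES = ("a", "z", "ter", "v_go", "v_nogo")
BEHAV_FEATURES = ("omission_rate", "commission_rate",
                  "mean_go_latency_ms", "mean_nogo_latency_ms")


@dataclass
class FeatureTable:
    """Per-participant feature matrix with group labels.

    ``frame`` columns: participant_id, label, then feature columns.
    """

    frame: pd.DataFrame
    feature_names: tuple

    def __post_init__(self):
        missing = [c for c in ("participant_id", "label", *self.feature_names)
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        feats = self.frame[list(self.feature_names)]
        if feats.isna().any().any():
            # a mean latency is undefined when its trial set is empty;
            # impute with the column mean so participant sets stay aligned
            self.frame = self.frame.copy()
            self.frame[list(self.feature_names)] = feats.fillna(feats.mean())
            logger.warning("imputed missing feature values with column means")

    @classmethod
    def from_fit(cls, fit) -> "FeatureTable":
        df = fit.point_estimates().rename(columns={"group": "label"})
        return cls(frame=df, feature_names=DDM_FEATURES)

    @classmethod
    def from_behavioural(cls, measures: pd.DataFrame) -> "FeatureTable":
        df = measures[measures.get("usable", True) == True].copy()  # noqa: E712
        df = df.rename(columns={"group": "label"})
        return cls(frame=df.reset_index(drop=True), feature_names=BEHAV_FEATURES)


@dataclass
class ClassificationResult:
    folds: pd.DataFrame      # pid, true, pred, p_<class> per classified fold
    per_class: pd.DataFrame  # class, n, hit_rate, precision, auc
    weighted: dict           # weighted hit_rate / precision / auc
    classes: tuple


def _ovr_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """One-vs-rest AUC by the rank formula (ties averaged, i.e. trapezoidal
    with tie-averaged step contributions)."""
    npos = int(positive.sum())
    nneg = positive.size - npos
    if npos == 0 or nneg == 0:
        return np.nan
    ranks = rankdata(scores)
    return float((ranks[positive].sum() - npos * (npos + 1) / 2) / (npos * nneg))


def _metrics(y: np.ndarray, pred: np.ndarray, probs: np.ndarray, classes) -> tuple:
    rows = []
    for ci, c in enumerate(classes):
        is_c = y == ci
        n_c = int(is_c.sum())
        hit = float((pred[is_c] == ci).mean()) if n_c else np.nan
        pp = int((pred == ci).sum())
        prec = float(((pred == ci) & is_c).sum() / pp) if pp else np.nan
        auc = _ovr_auc(probs[:, ci], is_c)
        rows.append({"class": c, "n": n_c, "hit_rate": hit,
                     "precision": prec, "auc": auc})
    per_class = pd.DataFrame(rows)
    w = per_class["n"].to_numpy(dtype=float)
    weighted = {}
    for m in ("hit_rate", "precision", "auc"):
        vals = per_class[m].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        weighted[m] = float(np.sum(w[ok] * vals[ok]) / np.sum(w[ok])) if ok.any() else np.nan
    return per_class, weighted


def loo_classify(features: FeatureTable, seed: int = 0, c: float = 1.0) -> ClassificationResult:
    """Leave-one-out three-way classification.

    Class order is fixed (PSP < PD < CONTROL) so that exact probability
    ties resolve deterministically via first-argmax.  A class with a single
    member overall cannot be predicted for its own fold; that fold is
    skipped with a warning.
    """
    df = features.frame.reset_index(drop=True)
    classes = tuple(g for g in GROUPS if g in set(df["label"]))
    if len(classes) < 3:
        raise ValueError("need at least 3 classes present")
    code = {g: i for i, g in enumerate(classes)}
    y = df["label"].map(code).to_numpy()
    X = df[list(features.feature_names)].to_numpy(dtype=float)
    counts = np.bincount(y, minlength=len(classes))
    if (counts < 2).any():
        singletons = [classes[i] for i in np.flatnonzero(counts < 2)]
        logger.warning("classes with one member are skipped as held-out folds: %s",
                       singletons)
    rows = []
    for i in range(len(df)):
        if counts[y[i]] < 2:
            continue
        mask = np.ones(len(df), dtype=bool)
        mask[i] = False
        scaler = StandardScaler().fit(X[mask])
        clf = LogisticRegression(C=c, max_iter=2000)
        clf.fit(scaler.transform(X[mask]), y[mask])
        proba = np.zeros(len(classes))
        p = clf.predict_proba(scaler.transform(X[i:i + 1]))[0]
        for k, cl in enumerate(clf.classes_):
            proba[int(cl)] = p[k]
        rows.append({"participant_id": df.loc[i, "participant_id"],
                     "true": classes[y[i]], "pred": classes[int(np.argmax(proba))],
                     **{f"p_{cl}": proba[j] for j, cl in enumerate(classes)}})
    folds = pd.DataFrame(rows)
    yv = folds["true"].map(code).to_numpy()
    predv = folds["pred"].map(code).to_numpy()
    probs = folds[[f"p_{cl}" for cl in classes]].to_numpy()
    per_class, weighted = _metrics(yv, predv, probs, classes)
    return ClassificationResult(folds=folds, per_class=per_class,
                                weighted=weighted, classes=classes)


def _weighted_metrics_rows(y, pred_m, prob_ms, n_classes):
    """Vectorized weighted metrics for a batch of permuted fold outcomes.

    y: (n,), pred_m: (b, n) predicted codes, prob_ms: list of n_classes
    (b, n) probability matrices.  Returns (b,) arrays for weighted hit
    rate, precision and AUC.
    """
    b, n = pred_m.shape
    w = np.array([(y == c).sum() for c in range(n_classes)], dtype=float)
    hit = (pred_m == y[None, :]).mean(axis=1)  # prevalence-weighted TPR
    prec_num = np.zeros(b)
    prec_den = np.zeros(b)
    auc_num = np.zeros(b)
    auc_den = np.zeros(b)
    for c in range(n_classes):
        is_c = y == c
        pp = (pred_m == c).sum(axis=1).astype(float)
        tp = ((pred_m == c) & is_c[None, :]).sum(axis=1).astype(float)
        ok = pp > 0
        prec_num[ok] += w[c] * tp[ok] / pp[ok]
        prec_den[ok] += w[c]
        npos, nneg = int(is_c.sum()), int(n - is_c.sum())
        if npos and nneg:
            ranks = rankdata(prob_ms[c], axis=1)
            auc = (ranks[:, is_c].sum(axis=1) - npos * (npos + 1) / 2) / (npos * nneg)
            auc_num += w[c] * auc
            auc_den += w[c]
    with np.errstate(invalid="ignore"):
        return hit, prec_num / prec_den, auc_num / auc_den


def permutation_compare(result_a: ClassificationResult, result_b: ClassificationResult,
                        n_perm: int = 100000, seed: int = 0,
                        batch: int = 20000) -> dict:
    """Permutation test of feature-set superiority (A over B).

    The null swaps, independently per participant with probability 1/2, the
    two feature sets' leave-one-out outcomes (predicted label and class
    probabilities move together), recomputes each weighted metric
    difference, and reports the one-sided smoothed p-value
    (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    fa = result_a.folds.sort_values("participant_id").reset_index(drop=True)
    fb = result_b.folds.sort_values("participant_id").reset_index(drop=True)
    if list(fa["participant_id"]) != list(fb["participant_id"]):
        raise ValueError("the two results cover different participant sets")
    if result_a.classes != result_b.classes:
        raise ValueError("class sets differ between results")
    classes = result_a.classes
    code = {g: i for i, g in enumerate(classes)}
    y = fa["true"].map(code).to_numpy()
    pa = fa["pred"].map(code).to_numpy()
    pb = fb["pred"].map(code).to_numpy()
    qa = fa[[f"p_{c}" for c in classes]].to_numpy()
    qb = fb[[f"p_{c}" for c in classes]].to_numpy()
    nc = len(classes)

    def diffs(swap):  # swap: (b, n) boolean; True -> this entry takes B's outcome
        pred_a = np.where(swap, pb[None, :], pa[None, :])
        pred_b = np.where(swap, pa[None, :], pb[None, :])
        prob_a = [np.where(swap, qb[None, :, c], qa[None, :, c]) for c in range(nc)]
        prob_b = [np.where(swap, qa[None, :, c], qb[None, :, c]) for c in range(nc)]
        ma = _weighted_metrics_rows(y, pred_a, prob_a, nc)
        mb = _weighted_metrics_rows(y, pred_b, prob_b, nc)
        return tuple(a - b for a, b in zip(ma, mb))

    obs = diffs(np.zeros((1, y.size), dtype=bool))
    obs = tuple(float(d[0]) for d in obs)
    rng = np.random.default_rng(int(seed))
    counts = np.zeros(3)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        swap = rng.random((b, y.size)) < 0.5
        for k, d in enumerate(diffs(swap)):
            counts[k] += int(np.sum(d >= obs[k] - 1e-12))
        done += b
    names = ("weighted_hit_rate", "weighted_precision", "weighted_auc")
    return {name: {"observed_diff": obs[k],
                   "p": float((1 + counts[k]) / (n_perm + 1))}
            for k, name in enumerate(names)}
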