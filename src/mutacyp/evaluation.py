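"""Accuracy measures, ROC analysis, and the cross-validation protocol.

The four headline measures on a confusion table (deleterious = positive):

    Q2  = (TP + TN) / (TP + TN + FP + FN) · 100%
    R   = TP / (TP + FN) · 100%
    P   = TP / (TP + FP) · 100%
    MCC = (TP·TN - FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

MCC is 0 when any marginal vanishes; recall/precision with a zero
denominator are reported as NaN, never silently 0.

Model assessment follows a stratified 5-fold cross-validation in which a
further stratified 20% of each fold's training portion is withdrawn as a
validation subset; candidate models (e.g. several random restarts of the
network) compete on validation MCC, the per-fold winner is scored on the
fold's untouched test portion, and the final single model is the fold
winner that generalizes best from validation to test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    BENIGN,
    DELETERIOUS,
    NeuralNet,
    Prediction,
    TrainConfig,
    labels_to_bool,
    lda_train,
    nn_train,
)


@dataclass(frozen=True)
class ConfusionTable:
    """TP/TN/FP/FN counts with deleterious as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_bd_counts(cls, bb: int, bd: int, db: int, dd: int) -> "ConfusionTable":
        """Build from the B-B / B-D / D-B / D-D layout of published
        confusion tables (true class first, called class second)."""
        return cls(tp=dd, tn=bb, fp=bd, fn=db)


@dataclass(frozen=True)
class MetricsReport:
    q2: float  # percent
    recall: float  # percent; NaN when no true deleterious
    precision: float  # percent; NaN when nothing called deleterious
    mcc: float
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        d = {"MCC": self.mcc, "Q2": self.q2, "R": self.recall, "P": self.precision}
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def confusion(labels: Sequence[str], predictions: Sequence[str]) -> ConfusionTable:
    """Tally a confusion table from aligned true labels and calls."""
    y = labels_to_bool(labels)
    p = labels_to_bool(predictions)
    if len(y) != len(p):
        raise ValueError(f"labels ({len(y)}) and predictions ({len(p)}) misaligned")
    return ConfusionTable(
        tp=int(np.sum(y & p)),
        tn=int(np.sum(~y & ~p)),
        fp=int(np.sum(~y & p)),
        fn=int(np.sum(y & ~p)),
    )


def metrics(ct: ConfusionTable, scores_auc: Optional[float] = None) -> MetricsReport:
    """Q2, recall, precision and MCC from a confusion table."""
    if ct.total == 0:
        raise ValueError("empty confusion table")
    q2 = (ct.tp + ct.tn) / ct.total * 100.0
    recall = ct.tp / (ct.tp + ct.fn) * 100.0 if ct.tp + ct.fn else math.nan
    precision = ct.tp / (ct.tp + ct.fp) * 100.0 if ct.tp + ct.fp else math.nan
    denom = (ct.tp + ct.fn) * (ct.tp + ct.fp) * (ct.tn + ct.fp) * (ct.tn + ct.fn)
    mcc = 0.0 if denom == 0 else (ct.tp * ct.tn - ct.fp * ct.fn) / math.sqrt(denom)
    return MetricsReport(q2=q2, recall=recall, precision=precision, mcc=mcc,
                         auc=scores_auc)


def roc_curve(scores: Sequence[float], labels: Sequence[str]):
    """ROC points (FPR, TPR) from a descending threshold sweep over the
    unique scores, with (0,0) and (1,1) anchors."""
    s = np.asarray(scores, dtype=float)
    y = labels_to_bool(labels)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # collapse tied scores: keep the last index of each distinct value
    distinct = np.nonzero(np.diff(s, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    return fpr, tpr


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Trapezoid area under the ROC curve.

    Equals the Mann-Whitney statistic P(score_del > score_ben) + ½ P(tie).
    """
    fpr, tpr = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    fold: int
    model: object
    model_id: str
    validation: MetricsReport
    test: MetricsReport
    test_indices: np.ndarray


@dataclass
class CVResult:
    folds: list[FoldResult]
    fold_assignments: np.ndarray  # fold index per dataset row

    @property
    def mean_test_mcc(self) -> float:
        return float(np.mean([f.test.mcc for f in self.folds]))

    def summary(self) -> pd.DataFrame:
        """Mean ± sd (sample sd across folds) of each test-subset metric."""
        rows = {
            name: [getattr(f.test, attr) for f in self.folds]
            for name, attr in (("MCC", "mcc"), ("Q2", "q2"),
                               ("R", "recall"), ("P", "precision"))
        }
        return pd.DataFrame(
            {
                "mean": {k: float(np.mean(v)) for k, v in rows.items()},
                "sd": {k: float(np.std(v, ddof=1)) for k, v in rows.items()},
            }
        )


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Deal shuffled indices of each class round-robin into k folds."""
    assignment = np.empty(len(y), dtype=int)
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            assignment[j] = i % k
    return assignment


def _stratified_split(idx: np.ndarray, y: np.ndarray, frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Withdraw a stratified fraction of ``idx``; returns (rest, withdrawn)."""
    withdrawn = []
    for cls in (True, False):
        pool = idx[y[idx] == cls]
        pool = pool.copy()
        rng.shuffle(pool)
        n = max(1, int(round(frac * len(pool))))
        withdrawn.append(pool[:n])
    w = np.sort(np.concatenate(withdrawn))
    rest = np.setdiff1d(idx, w)
    return rest, w


def cross_validate(
    X,
    labels: Sequence[str],
    model: str = "rprop",
    seed: int = 0,
    k: int = 5,
    n_restarts: int = 10,
    train_cfg: Optional[TrainConfig] = None,
    layers: tuple[int, ...] = (0,),  # sentinel: infer input width
) -> CVResult:
    """Stratified k-fold cross-validation with a held-out validation subset.

    ``model`` is 'lda', 'rprop' or 'stdbp'. For the network models,
    ``n_restarts`` candidate nets with different initial weights are trained
    per fold and the one with the highest validation MCC is kept. All
    randomness derives from ``seed``; a rerun is bit-identical.
    """
    Xa = np.asarray(X, dtype=float)
    y = labels_to_bool(labels)
    labels_arr = np.where(y, DELETERIOUS, BENIGN)
    if len(Xa) < 25:
        raise ValueError("cross-validation needs at least 25 rows")
    rng = np.random.default_rng(seed)
    assignment = _stratified_folds(y, k, rng)
    for f in range(k):
        if len(set(y[assignment == f])) < 2:
            raise ValueError(f"fold {f} lacks a class; dataset too small/imbalanced")

    if layers == (0,):
        layers = (Xa.shape[1], 10, 5, 2)

    folds: list[FoldResult] = []
    for f in range(k):
        test_idx = np.flatnonzero(assignment == f)
        pool_idx = np.flatnonzero(assignment != f)
        train_idx, val_idx = _stratified_split(pool_idx, y, 0.2, rng)

        if model == "lda":
            fitted = lda_train(Xa[train_idx], labels_arr[train_idx])
            candidates = [(fitted, f"lda-fold{f}")]
        else:
            cfg = train_cfg or TrainConfig(algorithm=model, seed=seed)
            candidates = []
            for r in range(n_restarts):
                net = NeuralNet.initialize(layers, seed=[seed, f, r])
                trained, _ = nn_train(
                    net, Xa[train_idx], labels_arr[train_idx],
                    Xa[val_idx], labels_arr[val_idx], cfg,
                )
                candidates.append((trained, f"{model}-fold{f}-restart{r}"))

        scored = []
        for cand, cid in candidates:
            val_calls = [p.label for p in cand.predict(Xa[val_idx])]
            val_rep = metrics(
                confusion(labels_arr[val_idx], val_calls),
                roc_auc(cand.predict_scores(Xa[val_idx]), labels_arr[val_idx]),
            )
            scored.append((val_rep.mcc, cand, cid, val_rep))
        best_mcc = max(s[0] for s in scored)
        _, winner, winner_id, val_rep = next(s for s in scored if s[0] == best_mcc)

        test_calls = [p.label for p in winner.predict(Xa[test_idx])]
        test_rep = metrics(
            confusion(labels_arr[test_idx], test_calls),
            roc_auc(winner.predict_scores(Xa[test_idx]), labels_arr[test_idx]),
        )
        folds.append(
            FoldResult(fold=f, model=winner, model_id=winner_id,
                       validation=val_rep, test=test_rep, test_indices=test_idx)
        )
    return CVResult(folds=folds, fold_assignments=assignment)


def select_final_model(cv: CVResult) -> FoldResult:
    """The fold winner with the best generalization to its test subset.

    Maximal test MCC, ties broken by the smallest |MCC_val - MCC_test| gap.
    """
    if not cv.folds:
        raise ValueError("empty cross-validation result")
    return min(
        cv.folds,
        key=lambda f: (-f.test.mcc, abs(f.validation.mcc - f.test.mcc), f.fold),
    )


def cv_consensus_labels(cv: CVResult, X, mode: str = "majority") -> list[str]:
    """Combine the k per-fold winners by consensus voting over a dataset."""
    from .classifiers import consensus

    preds = [f.model.predict(np.asarray(X, dtype=float)) for f in cv.folds]
    return consensus(preds, mode=mode)


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------


def compare_methods(
    score_tables: Mapping[str, Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    threshold: float = 0.5,
) -> dict:
    """Cross-method score correlations, call tallies and agreement.

    ``score_tables`` maps method name → scores aligned on the same mutation
    list; missing predictions are NaN and are dropped pairwise (with the
    retained count reported). Returns pairwise Pearson r of raw scores,
    per-method benign/deleterious call counts, the unanimity fraction over
    rows every method scored, and — when true labels are supplied —
    per-method confusion tables and metrics.
    """
    from .feature_selection import pearson_r

    names = list(score_tables)
    if len(names) < 2:
        raise ValueError("need at least 2 methods to compare")
    arr = {m: np.asarray(score_tables[m], dtype=float) for m in names}
    n = {len(a) for a in arr.values()}
    if len(n) != 1:
        raise ValueError("methods are not aligned on the same mutation list")

    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pair_n = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            mask = np.isfinite(arr[a]) & np.isfinite(arr[b])
            if not mask.any():
                raise ValueError(f"no shared mutations between {a} and {b}")
            r = pearson_r(arr[a][mask], arr[b][mask])
            corr.loc[a, b] = corr.loc[b, a] = r
            pair_n.loc[a, b] = pair_n.loc[b, a] = int(mask.sum())

    calls = {
        m: {
            "deleterious": int(np.sum(arr[m][np.isfinite(arr[m])] >= threshold)),
            "benign": int(np.sum(arr[m][np.isfinite(arr[m])] < threshold)),
            "missing": int(np.sum(~np.isfinite(arr[m]))),
        }
        for m in names
    }

    all_present = np.logical_and.reduce([np.isfinite(arr[m]) for m in names])
    if all_present.any():
        call_mat = np.stack([arr[m][all_present] >= threshold for m in names])
        unanimity = float(np.mean(np.all(call_mat == call_mat[0], axis=0)))
    else:
        unanimity = math.nan

    out = {
        "correlation": corr,
        "pairwise_n": pair_n,
        "calls": calls,
        "unanimity": unanimity,
    }
    if labels is not None:
        y = np.asarray(labels)
        per_method = {}
        for m in names:
            mask = np.isfinite(arr[m])
            pred = np.where(arr[m][mask] >= threshold, DELETERIOUS, BENIGN)
            ct = confusion(y[mask], pred)
            per_method[m] = {
                "confusion": ct,
                "metrics": metrics(ct, roc_auc(arr[m][mask], y[mask])),
                "n_evaluated": int(mask.sum()),
            }
        out["per_method"] = per_method
    return out
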