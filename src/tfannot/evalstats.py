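"""Evaluation protocols: stratified nested cross-validation, threshold-
averaged ROC curves, avgROC summaries, and the PFM-transfer error/rate
curves.

avgROC is the unweighted mean of the areas under the ROC curves across
outer cross-validation folds (and, for multiclass problems, across the
one-versus-rest tasks).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    """An ROC curve with its score thresholds and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @classmethod
    def from_scores(cls, y_true, scores, pos_label=1) -> "RocCurve":
        fpr, tpr, thr = roc_curve(y_true, scores, pos_label=pos_label)
        return cls(fpr=fpr, tpr=tpr, thresholds=thr,
                   auc=float(roc_auc_score(y_true == pos_label, scores)))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\tthreshold\n")
            for f, t, thr in zip(self.fpr, self.tpr, self.thresholds):
                fh.write(f"{f:.6g}\t{t:.6g}\t{thr:.6g}\n")


def stratified_folds(labels: Sequence, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0 .. n_folds-1 per item).

    Per-fold class proportions match the global proportions to within one
    item.  Every class must have at least ``n_folds`` members.
    """
    labels = np.asarray(labels)
    for c in np.unique(labels):
        n = int(np.sum(labels == c))
        if n < n_folds:
            raise ValueError(f"class {c!r} has {n} members, fewer than "
                             f"{n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)),
                                                   labels)):
        assignment[test_idx] = fold
    return assignment


def _binary_scores(model, X) -> np.ndarray:
    """Positive-class score of a fitted binary classifier."""
    if hasattr(model, "decision_function"):
        s = model.decision_function(X)
        if np.ndim(s) == 1:
            return np.asarray(s, dtype=float)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, -1]
    return np.asarray(model.predict(X), dtype=float)


@dataclass
class NestedCvResult:
    curves: list            # per-outer-fold RocCurve (binary task)
    fold_aucs: np.ndarray   # per-outer-fold AUC (binary) or avg OvR AUC
    avg_roc: float
    best_params: list       # chosen hyperparameters per outer fold


def nested_cv(X, y, estimator, param_grid: Optional[dict] = None,
              outer: int = 4, inner: int = 4, seed: int = 42,
              pos_label=None) -> NestedCvResult:
    """Stratified nested cross-validation with inner-loop model selection.

    For each outer fold the hyperparameter grid is selected on the inner
    folds of the outer-training data only, the winning model is refit on the
    full outer-training split and scored on the held-out outer-test split.
    Binary problems are summarized by per-fold ROC curves; multiclass
    problems by the mean one-versus-rest AUC per fold.  ``avg_roc`` is the
    unweighted mean of the per-fold values.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes = np.unique(y)
    binary = len(classes) == 2
    if binary and pos_label is None:
        pos_label = classes[1]
    assignment = stratified_folds(y, outer, seed)
    curves, aucs, best_params = [], [], []
    for fold in range(outer):
        train = assignment != fold
        test = ~train
        model = clone(estimator)
        if param_grid:
            inner_cv = StratifiedKFold(n_splits=inner, shuffle=True,
                                       random_state=seed + 1)
            gs = GridSearchCV(model, param_grid, cv=inner_cv,
                              scoring="roc_auc" if binary
                              else "roc_auc_ovr", n_jobs=None)
            gs.fit(X[train], y[train])
            model = gs.best_estimator_
            best_params.append(gs.best_params_)
        else:
            model.fit(X[train], y[train])
            best_params.append({})
        if binary:
            scores = _binary_scores(model, X[test])
            if pos_label != classes[1]:
                scores = -scores
            curve = RocCurve.from_scores(y[test] == pos_label, scores)
            curves.append(curve)
            aucs.append(curve.auc)
        else:
            if hasattr(model, "decision_scores"):
                scores = model.decision_scores(X[test])
            elif hasattr(model, "predict_proba"):
                scores = model.predict_proba(X[test])
            else:
                scores = model.decision_function(X[test])
            aucs.append(avg_roc_multiclass(scores, y[test],
                                           classes=classes))
    aucs = np.asarray(aucs, dtype=float)
    return NestedCvResult(curves=curves, fold_aucs=aucs,
                          avg_roc=float(aucs.mean()), best_params=best_params)


def threshold_avg_roc(curves: Sequence[RocCurve]) -> RocCurve:
    """Average ROC curves over folds at pooled score thresholds.

    All thresholds from all curves are pooled; at each threshold every
    curve's (FPR, TPR) operating point is evaluated (step interpolation on
    its own threshold list) and averaged across curves.  Endpoints (0,0)
    and (1,1) are preserved.
    """
    if not curves:
        raise ValueError("no curves to average")
    pooled = np.unique(np.concatenate([c.thresholds for c in curves]))[::-1]
    fprs = np.empty((len(curves), len(pooled)))
    tprs = np.empty((len(curves), len(pooled)))
    for i, c in enumerate(curves):
        # thresholds descend; operating point at t = last point with
        # threshold >= t
        desc = c.thresholds
        idx = np.searchsorted(-desc, -pooled, side="right") - 1
        idx = np.clip(idx, 0, len(desc) - 1)
        below = pooled > desc[0]
        fprs[i] = np.where(below, 0.0, c.fpr[idx])
        tprs[i] = np.where(below, 0.0, c.tpr[idx])
    fpr = np.concatenate([fprs.mean(axis=0), [1.0]])
    tpr = np.concatenate([tprs.mean(axis=0), [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=np.concatenate(
        [pooled, [-np.inf]]), auc=auc)


def avg_roc_multiclass(scores, labels, classes=None) -> float:
    """Unweighted mean of one-versus-rest AUCs.

    ``scores`` is an (n, k) array of per-class decision scores in the order
    of ``classes`` (sorted unique labels when omitted).  Classes absent from
    ``labels`` are skipped with a warning.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    aucs = []
    for j, c in enumerate(classes):
        mask = labels == c
        if mask.all() or not mask.any():
            warnings.warn(f"class {c!r} absent from one side; skipped")
            continue
        aucs.append(roc_auc_score(mask, scores[:, j]))
    return float(np.mean(aucs))


@dataclass
class TransferCurves:
    """Transfer rate and error as functions of the best-match threshold."""

    thresholds: np.ndarray
    rate: np.ndarray        # fraction of queries with a prediction
    error: np.ndarray       # mean PFM distance of the predictions (NaN if none)
    dynamic_rate: float
    dynamic_error: float


def pfm_transfer_eval(tf_entries, folds: int = 4, seed: int = 42,
                      thresholds: Optional[np.ndarray] = None,
                      model_factory: Optional[Callable] = None,
                      sim_cache=None) -> TransferCurves:
    """Cross-validated PFM transfer error and rate versus threshold.

    ``tf_entries`` is a sequence of :class:`~tfannot.motif.TfEntry` (id,
    superclass, DNA-binding-domain sequence, annotated PFM).  For each of
    ``folds`` stratified folds (by superclass) a transfer model is fit on
    the training factors; each held-out factor's candidate similarities are
    predicted once and then thresholded over the grid (default: 10 evenly
    spaced values in [0.5, 0.95]).  At each threshold the transfer rate is
    the fraction of queries with at least one selected best match, and the
    transfer error the mean Smax distance between merged prediction and
    annotated PFM over those queries.  The dynamic-threshold operating
    point is evaluated alongside.
    """
    from .motif import PfmTransferModel, SmaxCache, smax_distance

    if thresholds is None:
        thresholds = np.linspace(0.5, 0.95, 10)
    thresholds = np.asarray(thresholds, dtype=float)
    entries = list(tf_entries)
    labels = [e.superclass for e in entries]
    assignment = stratified_folds(labels, folds, seed)
    cache = sim_cache if sim_cache is not None else SmaxCache()
    if model_factory is None:
        model_factory = lambda: PfmTransferModel(random_state=seed,
                                                 sim_cache=cache)

    n_pred = np.zeros(len(thresholds))
    err_sum = np.zeros(len(thresholds))
    dyn_pred = 0
    dyn_err_sum = 0.0
    n_queries = 0
    for fold in range(folds):
        train = [e for e, a in zip(entries, assignment) if a != fold]
        test = [e for e, a in zip(entries, assignment) if a == fold]
        model = model_factory()
        model.fit(train)
        for query in test:
            n_queries += 1
            sims = model.candidate_similarities(query.dbd_sequence,
                                                query.superclass)
            for i, t in enumerate(thresholds):
                result = model.transfer_from_similarities(sims, threshold=t)
                if result.pfm is not None:
                    n_pred[i] += 1
                    err_sum[i] += smax_distance(result.pfm, query.pfm,
                                                cache=cache)
            result = model.transfer_from_similarities(sims,
                                                      threshold="dynamic")
            if result.pfm is not None:
                dyn_pred += 1
                dyn_err_sum += smax_distance(result.pfm, query.pfm,
                                             cache=cache)
    with np.errstate(invalid="ignore", divide="ignore"):
        error = np.where(n_pred > 0, err_sum / np.maximum(n_pred, 1), np.nan)
    return TransferCurves(
        thresholds=thresholds,
        rate=n_pred / max(n_queries, 1),
        error=error,
        dynamic_rate=dyn_pred / max(n_queries, 1),
        dynamic_error=(dyn_err_sum / dyn_pred) if dyn_pred else float("nan"),
    )
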