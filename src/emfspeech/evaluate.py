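"""Leave-one-subject-out evaluation of the EMF classifier and metrics.

Every fold holds out one subject; the DFS cascade is run on the remaining
subjects' EMF rows against the held-out EMF vector, a linear-margin SVM
(box constraint 1, per-feature standardization fitted on training rows only)
is trained on the selected features, and the held-out subject's prediction
and signed decision score are recorded.  Reports use TD as the negative and
DD as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from emfspeech.data import DD_SUBGROUPS, DIAGNOSES, CohortManifest
from emfspeech.dfs import DFSThresholds, DFSTrace, dfs_select
from emfspeech.emf import EMFDataset


@dataclass(frozen=True)
class FoldRecord:
    """Bookkeeping for one leave-one-subject-out fold."""

    subject_id: str
    truth: int
    prediction: int
    score: float
    mask: np.ndarray
    fallback: str


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts, derived rates and ranking metrics.

    Undefined rates (empty denominator) are ``None`` rather than NaN.  Note
    on naming: ``npv`` is TN/(TN+FN); some reports print this same quantity
    under the label "FOR", which conventionally denotes its complement — both
    readings are recoverable from the counts.
    """

    tn: int
    fp: int
    fn: int
    tp: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    balanced_accuracy: float | None
    ppv: float | None
    npv: float | None
    auc: float | None = None
    folds: tuple[FoldRecord, ...] = field(default_factory=tuple)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return self.tn, self.fp, self.fn, self.tp

    def to_dict(self) -> dict:
        return {
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "tp": self.tp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
        }


@dataclass(frozen=True)
class SelectionFrequencyTable:
    """Per-feature, per-diagnosis-group selection percentages across folds."""

    table: pd.DataFrame  # index = feature names, columns = diagnosis groups

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 100):
            raise ValueError("selection percentages must lie in [0, 100]")


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def rank_auc(scores: np.ndarray, truths: np.ndarray) -> float | None:
    """AUC by the Mann-Whitney rank formulation; ties count one half.

    Invariant under any strictly increasing transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=int)
    n_pos = int((truths == 1).sum())
    n_neg = int((truths == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    r_pos = ranks[truths == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    tn: int,
    fp: int,
    fn: int,
    tp: int,
    scores: np.ndarray | None = None,
    truths: np.ndarray | None = None,
    folds: tuple[FoldRecord, ...] = (),
) -> EvaluationReport:
    """Assemble an evaluation report from confusion counts and optional scores."""
    for name, c in (("tn", tn), ("fp", fp), ("fn", fn), ("tp", tp)):
        if c < 0:
            raise ValueError(f"count {name} must be >= 0")
    sens = _rate(tp, tp + fn)
    spec = _rate(tn, tn + fp)
    total = tn + fp + fn + tp
    acc = _rate(tp + tn, total)
    bal = None if sens is None or spec is None else (sens + spec) / 2
    auc = None
    if scores is not None and truths is not None:
        if len(scores) != len(truths):
            raise ValueError("scores and truths must align")
        auc = rank_auc(np.asarray(scores), np.asarray(truths))
    return EvaluationReport(
        tn=tn,
        fp=fp,
        fn=fn,
        tp=tp,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=bal,
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
        auc=auc,
        folds=folds,
    )


def _fit_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, c: float, seed: int
) -> tuple[int, float]:
    clf = make_pipeline(
        StandardScaler(),
        SVC(kernel="linear", C=c, random_state=seed),
    )
    clf.fit(train_x, train_y)
    pred = int(clf.predict(test_x)[0])
    score = float(clf.decision_function(test_x)[0])
    return pred, score


def loso_evaluate(
    dataset: EMFDataset,
    thresholds: DFSThresholds = DFSThresholds(),
    manifest: CohortManifest | None = None,
    c: float = 1.0,
    seed: int = 0,
    collect_traces: bool = False,
) -> tuple[EvaluationReport, SelectionFrequencyTable, dict[str, DFSTrace]]:
    """Leave-one-subject-out evaluation with per-fold dynamic feature selection.

    ``manifest`` (when given) labels the selection-frequency table by
    diagnosis subgroup; otherwise groups are the binary TD/DD labels.
    """
    if int((dataset.Y == 0).sum()) < 2 or int((dataset.Y == 1).sum()) < 2:
        raise ValueError("need >= 2 subjects per class for LOSO evaluation")
    folds: list[FoldRecord] = []
    traces: dict[str, DFSTrace] = {}
    for i, sid in enumerate(dataset.subject_ids):
        training = dataset.drop_subject(sid)
        if np.unique(training.Y).size < 2:
            raise ValueError(f"training fold for {sid!r} lost a class")
        mask, trace = dfs_select(training, dataset.D[i], thresholds)
        pred, score = _fit_predict(
            training.D[:, mask], training.Y, dataset.D[i : i + 1, mask], c, seed
        )
        folds.append(
            FoldRecord(
                subject_id=sid,
                truth=int(dataset.Y[i]),
                prediction=pred,
                score=score,
                mask=mask,
                fallback=trace.fallback,
            )
        )
        if collect_traces:
            traces[sid] = trace

    truths = np.array([f.truth for f in folds])
    preds = np.array([f.prediction for f in folds])
    scores = np.array([f.score for f in folds])
    tn = int(((truths == 0) & (preds == 0)).sum())
    fp = int(((truths == 0) & (preds == 1)).sum())
    fn = int(((truths == 1) & (preds == 0)).sum())
    tp = int(((truths == 1) & (preds == 1)).sum())
    report = compute_metrics(tn, fp, fn, tp, scores, truths, folds=tuple(folds))

    groups = {
        f.subject_id: (manifest.diagnosis(f.subject_id) if manifest else ("DD" if f.truth else "TD"))
        for f in folds
    }
    freq = selection_frequency(
        {f.subject_id: f.mask for f in folds}, groups, dataset.column_names
    )
    return report, freq, traces


def selection_frequency(
    masks: dict[str, np.ndarray],
    groups: dict[str, str],
    feature_names: tuple[str, ...],
) -> SelectionFrequencyTable:
    """Percentage of test folds selecting each feature, per diagnosis group."""
    group_names = [g for g in DIAGNOSES if g in set(groups.values())]
    group_names += [g for g in sorted(set(groups.values())) if g not in group_names]
    data = {}
    for g in group_names:
        members = [s for s in masks if groups[s] == g]
        if not members:
            continue
        stack = np.vstack([masks[s] for s in members])
        data[g] = 100.0 * stack.mean(axis=0)
    return SelectionFrequencyTable(pd.DataFrame(data, index=list(feature_names)))


def subgroup_recall(
    predictions: dict[str, int], manifest: CohortManifest
) -> dict[str, dict]:
    """Fraction of each DD subgroup predicted DD.  Empty subgroups are omitted."""
    out: dict[str, dict] = {}
    for g in DD_SUBGROUPS:
        members = [s for s in manifest.subjects_with(g) if s in predictions]
        if not members:
            continue
        hit = sum(predictions[s] for s in members)
        out[g] = {
            "correct": hit,
            "total": len(members),
            "fraction": hit / len(members),
            "percent": 100.0 * hit / len(members),
        }
    return out
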