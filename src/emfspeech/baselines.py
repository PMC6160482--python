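"""Standard-paradigm comparators.

Two utterance-level diagnosis baselines classify each utterance as TD or DD
with a linear SVM after feature selection on the training partition only:

FS1
    Features ranked by the absolute two-sided Welch t statistic between DD
    and TD utterance values; the top-k (default 100) retained.
FS2
    The valence-correlation selection rule (per-subject |rho| > threshold,
    union over subjects) applied to the training partition.

A third comparator is the per-subject three-class valence recogniser: a
linear discriminant classifier over the 0.7-rule features, scored by
leave-one-utterance-out balanced accuracy (chance 1/3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GroupKFold, KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from emfspeech.data import (
    SUBJECT_COL,
    VALENCE_LEVELS,
    CohortManifest,
    DegenerateDataError,
    UtteranceFeatureTable,
)
from emfspeech.selection import (
    pearson_valence_correlation,
    select_subject_features,
    union_selected_features,
)


@dataclass(frozen=True)
class BaselineConfig:
    """Settings for the FS1/FS2 standard-paradigm runs."""

    mode: str = "FS1"  # "FS1" | "FS2"
    top_k: int = 100
    threshold: float = 0.7
    cv_unit: str = "subject"  # "subject" (grouped folds) | "utterance"
    n_splits: int = 10
    c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("FS1", "FS2"):
            raise ValueError(f"unknown baseline mode {self.mode!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.cv_unit not in ("subject", "utterance"):
            raise ValueError(f"unknown cv_unit {self.cv_unit!r}")


@dataclass(frozen=True)
class UtteranceEvaluationReport:
    """Utterance-level confusion counts and rates for a baseline run."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def n_utterances(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def overall_rate(self) -> float:
        return (self.tn + self.tp) / self.n_utterances

    @property
    def td_rate(self) -> float | None:
        den = self.tn + self.fp
        return None if den == 0 else self.tn / den

    @property
    def dd_rate(self) -> float | None:
        den = self.tp + self.fn
        return None if den == 0 else self.tp / den

    @property
    def balanced_accuracy(self) -> float | None:
        if self.td_rate is None or self.dd_rate is None:
            return None
        return (self.td_rate + self.dd_rate) / 2

    def to_dict(self) -> dict:
        return {
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "tp": self.tp,
            "overall_rate": self.overall_rate,
            "td_rate": self.td_rate,
            "dd_rate": self.dd_rate,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _welch_abs_t(x_dd: np.ndarray, x_td: np.ndarray) -> np.ndarray:
    """|t| per feature column; both-variances-zero gives 0, zero s.e. with
    distinct means gives +inf (ranks first, as a perfectly separated feature
    should)."""
    m_dd, m_td = x_dd.mean(axis=0), x_td.mean(axis=0)
    v_dd = x_dd.var(axis=0, ddof=1) if x_dd.shape[0] > 1 else np.zeros(x_dd.shape[1])
    v_td = x_td.var(axis=0, ddof=1) if x_td.shape[0] > 1 else np.zeros(x_td.shape[1])
    se2 = v_dd / x_dd.shape[0] + v_td / x_td.shape[0]
    diff = np.abs(m_dd - m_td)
    out = np.zeros_like(diff)
    pos = se2 > 0
    out[pos] = diff[pos] / np.sqrt(se2[pos])
    out[~pos & (diff > 0)] = np.inf
    return out


def fs1_ttest_rank(
    table: UtteranceFeatureTable,
    manifest: CohortManifest,
    training_rows: np.ndarray,
    top_k: int = 100,
) -> list[int]:
    """Welch-t ranking of features by diagnosis, on the training rows only."""
    df = table.df.iloc[np.asarray(training_rows)]
    is_dd = df[SUBJECT_COL].map(lambda s: manifest.is_dd(s)).to_numpy(dtype=bool)
    if is_dd.all() or not is_dd.any():
        raise ValueError("training rows must contain both TD and DD utterances")
    x = df[table.feature_names].to_numpy(dtype=float)
    t = _welch_abs_t(x[is_dd], x[~is_dd])
    order = sorted(range(t.size), key=lambda j: (-t[j], j))
    return order[: min(top_k, t.size)]


def fs2_valence_select(
    table: UtteranceFeatureTable,
    training_rows: np.ndarray,
    threshold: float = 0.7,
) -> list[int]:
    """Valence-correlation selection restricted to the training partition."""
    sub = UtteranceFeatureTable(
        table.df.iloc[np.asarray(training_rows)].reset_index(drop=True)
    )
    per_subject: dict[str, set[int]] = {}
    for sid in sub.subjects:
        try:
            profile = pearson_valence_correlation(sub, sid)
        except DegenerateDataError:
            continue
        per_subject[sid] = select_subject_features(profile, threshold)
    return list(union_selected_features(per_subject, table.feature_names).indices)


def baseline_evaluate(
    table: UtteranceFeatureTable,
    manifest: CohortManifest,
    config: BaselineConfig = BaselineConfig(),
) -> UtteranceEvaluationReport:
    """Cross-validated utterance-level TD/DD classification.

    With ``cv_unit="subject"`` folds are grouped by subject so no subject's
    utterances straddle the train/test split; ``"utterance"`` shuffles rows
    freely (the literal row-level reading).
    """
    y = table.df[SUBJECT_COL].map(lambda s: int(manifest.is_dd(s))).to_numpy()
    x_all = table.feature_matrix()
    n = len(y)
    if config.cv_unit == "subject":
        groups = table.df[SUBJECT_COL].to_numpy()
        n_splits = min(config.n_splits, len(np.unique(groups)))
        splitter = GroupKFold(n_splits=n_splits)
        split_iter = splitter.split(x_all, y, groups)
    else:
        splitter = KFold(
            n_splits=min(config.n_splits, n), shuffle=True, random_state=config.seed
        )
        split_iter = splitter.split(x_all, y)

    truths = np.empty(n, dtype=int)
    preds = np.empty(n, dtype=int)
    seen = np.zeros(n, dtype=bool)
    for train_idx, test_idx in split_iter:
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("a training fold lacks one of the classes")
        if config.mode == "FS1":
            feats = fs1_ttest_rank(table, manifest, train_idx, config.top_k)
        else:
            feats = fs2_valence_select(table, train_idx, config.threshold)
        if not feats:  # selection came up empty on this partition
            feats = list(range(x_all.shape[1]))
        clf = make_pipeline(
            StandardScaler(),
            SVC(kernel="linear", C=config.c, random_state=config.seed),
        )
        clf.fit(x_all[np.ix_(train_idx, feats)], y[train_idx])
        preds[test_idx] = clf.predict(x_all[np.ix_(test_idx, feats)])
        truths[test_idx] = y[test_idx]
        seen[test_idx] = True
    assert seen.all(), "every utterance must be predicted exactly once"
    return UtteranceEvaluationReport(
        tn=int(((truths == 0) & (preds == 0)).sum()),
        fp=int(((truths == 0) & (preds == 1)).sum()),
        fn=int(((truths == 1) & (preds == 0)).sum()),
        tp=int(((truths == 1) & (preds == 1)).sum()),
    )


def valence_lda_accuracy(
    table: UtteranceFeatureTable,
    subject_id: str,
    threshold: float = 0.7,
) -> float:
    """Per-subject three-class valence recognition, leave-one-utterance-out.

    Features are re-selected by the correlation rule on each training split;
    a singular within-class scatter falls back to a ridge-regularised
    (shrinkage) discriminant.  Returns balanced accuracy over the three
    valence classes (chance 1/3).
    """
    x, e = table.subject_arrays(subject_id)
    n = x.shape[0]
    for v in VALENCE_LEVELS:
        if int((e == v).sum()) < 2:
            raise DegenerateDataError(
                f"subject {subject_id!r} needs >= 2 utterances per valence class"
            )
    preds = np.empty(n, dtype=int)
    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        xt, et = x[train], e[train]
        # correlation-based selection on the training split
        ec = et - et.mean()
        xc = xt - xt.mean(axis=0, keepdims=True)
        ss_x = np.einsum("ij,ij->j", xc, xc)
        ss_e = float(ec @ ec)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(ss_x > 0, (xc.T @ ec) / np.sqrt(np.where(ss_x > 0, ss_x, 1.0) * ss_e), 0.0)
        feats = np.flatnonzero(np.abs(rho) > threshold)
        if feats.size == 0:
            feats = np.arange(x.shape[1])
        preds[i] = _fit_lda(xt[:, feats], et, x[i : i + 1, feats])
    recalls = [float((preds[e == v] == v).mean()) for v in VALENCE_LEVELS]
    return float(np.mean(recalls))


def _fit_lda(train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray) -> int:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda = LinearDiscriminantAnalysis()
            lda.fit(train_x, train_y)
            return int(lda.predict(test_x)[0])
    except np.linalg.LinAlgError:
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.1)
        lda.fit(train_x, train_y)
        return int(lda.predict(test_x)[0])
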