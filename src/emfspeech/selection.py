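"""Emotion-related feature selection.

For each subject, every acoustic feature is correlated (Pearson) against the
numeric valence sequence of that subject's utterances; features whose
absolute correlation exceeds a threshold (0.7 by default) are retained for
that subject, and the cohort-level selected set is the union over subjects so
that every subject is described by the same feature list.  An optional greedy
mutual-correlation pass prunes redundant (near-collinear) features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from emfspeech.data import DegenerateDataError, UtteranceFeatureTable

DEFAULT_CORRELATION_THRESHOLD = 0.7


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-subject Pearson correlations of each feature with valence.

    Zero-variance feature columns have undefined correlation; they are
    flagged in ``undefined`` and carry an effective rho of 0 so that constant
    nuisance columns can never crash a run or be selected.
    """

    subject_id: str
    rho: np.ndarray
    undefined: np.ndarray  # boolean, same length as rho

    def __post_init__(self) -> None:
        defined = ~self.undefined
        if np.any(np.abs(self.rho[defined]) > 1 + 1e-12):
            raise ValueError("|rho| must be <= 1 where defined")


@dataclass(frozen=True)
class SelectedFeatureSet:
    """Cohort-level selected features, in original column order."""

    names: tuple[str, ...]
    indices: tuple[int, ...]
    provenance: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_opt(self) -> int:
        return len(self.indices)

    def __len__(self) -> int:
        return len(self.indices)


def pearson_valence_correlation(
    table: UtteranceFeatureTable, subject_id: str
) -> CorrelationProfile:
    """Pearson correlation of every feature column with the subject's valences.

    Valence labels {-1, 0, +1} are used arithmetically.  Requires at least
    two utterances spanning at least two distinct valence levels.
    """
    x, e = table.subject_arrays(subject_id)
    if x.shape[0] < 2:
        raise DegenerateDataError(f"subject {subject_id!r} has fewer than 2 utterances")
    if np.unique(e).size < 2:
        raise DegenerateDataError(
            f"subject {subject_id!r}: all utterances share one valence level"
        )
    ec = e - e.mean()
    xc = x - x.mean(axis=0, keepdims=True)
    ss_x = np.einsum("ij,ij->j", xc, xc)
    ss_e = float(ec @ ec)
    cov = xc.T @ ec
    undefined = ss_x == 0.0
    denom = np.sqrt(np.where(undefined, 1.0, ss_x) * ss_e)
    rho = np.where(undefined, 0.0, cov / denom)
    rho = np.clip(rho, -1.0, 1.0)
    return CorrelationProfile(subject_id=subject_id, rho=rho, undefined=undefined)


def select_subject_features(
    profile: CorrelationProfile, threshold: float = DEFAULT_CORRELATION_THRESHOLD
) -> set[int]:
    """Indices with |rho| strictly above the threshold (undefined excluded)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    keep = (np.abs(profile.rho) > threshold) & ~profile.undefined
    return set(np.flatnonzero(keep).tolist())


def union_selected_features(
    per_subject_sets: Iterable[set[int]] | dict[str, set[int]],
    column_order: Sequence[str],
) -> SelectedFeatureSet:
    """Union of per-subject selections, ordered by original column order."""
    if isinstance(per_subject_sets, dict):
        provenance = {s: tuple(sorted(v)) for s, v in per_subject_sets.items()}
        sets = list(per_subject_sets.values())
    else:
        sets = list(per_subject_sets)
        provenance = {}
    union: set[int] = set().union(*sets) if sets else set()
    for j in union:
        if not 0 <= j < len(column_order):
            raise ValueError(f"feature index {j} outside column order")
    indices = tuple(sorted(union))
    return SelectedFeatureSet(
        names=tuple(column_order[j] for j in indices),
        indices=indices,
        provenance=provenance,
    )


def prune_redundant_features(
    table: UtteranceFeatureTable,
    candidate: SelectedFeatureSet,
    redundancy_threshold: float = 0.95,
) -> SelectedFeatureSet:
    """Greedy mutual-correlation pruning of the candidate set.

    Candidates are visited in descending order of their strongest per-subject
    valence correlation (ties broken toward the lower column index); a
    feature is dropped when its absolute Pearson correlation over all
    utterances with an already-kept feature exceeds the threshold.
    """
    if not 0.0 < redundancy_threshold <= 1.0:
        raise ValueError("redundancy_threshold must be in (0, 1]")
    if candidate.n_opt <= 1:
        return candidate
    idx = list(candidate.indices)
    strength = _max_abs_valence_correlation(table, idx)
    order = sorted(range(len(idx)), key=lambda p: (-strength[p], idx[p]))

    cols = table.feature_matrix()[:, idx]
    cc = cols - cols.mean(axis=0, keepdims=True)
    ss = np.einsum("ij,ij->j", cc, cc)
    kept: list[int] = []
    for p in order:
        redundant = False
        for q in kept:
            denom = np.sqrt(ss[p] * ss[q])
            r = 0.0 if denom == 0.0 else abs(float(cc[:, p] @ cc[:, q]) / denom)
            if r > redundancy_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(p)
    kept_indices = tuple(sorted(idx[p] for p in kept))
    names = tuple(table.feature_names[j] for j in kept_indices)
    return SelectedFeatureSet(
        names=names, indices=kept_indices, provenance=candidate.provenance
    )


def _max_abs_valence_correlation(
    table: UtteranceFeatureTable, indices: Sequence[int]
) -> np.ndarray:
    out = np.zeros(len(indices))
    for sid in table.subjects:
        try:
            profile = pearson_valence_correlation(table, sid)
        except DegenerateDataError:
            continue
        out = np.maximum(out, np.abs(profile.rho[list(indices)]))
    return out


def select_features(
    table: UtteranceFeatureTable,
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
    redundancy_threshold: float | None = None,
    subjects: Sequence[str] | None = None,
) -> SelectedFeatureSet:
    """Full selection pass: per-subject correlation, union, optional pruning.

    ``subjects`` restricts the union to a subset (used by the "strict"
    leakage mode, which recomputes the selection from training subjects only
    inside each cross-validation fold).  Subjects whose utterances span a
    single valence level are skipped rather than fatal.
    """
    per_subject: dict[str, set[int]] = {}
    for sid in subjects if subjects is not None else table.subjects:
        try:
            profile = pearson_valence_correlation(table, sid)
        except DegenerateDataError:
            continue
        per_subject[sid] = select_subject_features(profile, threshold)
    selected = union_selected_features(per_subject, table.feature_names)
    if redundancy_threshold is not None:
        selected = prune_redundant_features(table, selected, redundancy_threshold)
    return selected
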