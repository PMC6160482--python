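"""The emotional modulation function (EMF).

Each subject's utterances are grouped by valence class; within each class and
for each selected feature, three distribution descriptors are computed —
skewness, mean and kurtosis — yielding a 3 x 3*N_opt moment matrix M_i whose
rows correspond to valence -1, 0, +1.  The EMF is the coefficient vector B_i
of the multilinear regression M_i B_i = (-1, 0, +1)^T, taken as the
minimum-norm least-squares solution (Moore-Penrose pseudoinverse).  With 3
observations and 3*N_opt unknowns the system is underdetermined for
N_opt >= 2, so the normal-equation form is singular; the pseudoinverse
coincides with it whenever the inverse exists and otherwise picks the
least-squares solution of smallest Euclidean norm.  Stacking B_i over
subjects gives the dataset classified downstream.

Moment conventions: population central moments m_r = sum((x-mu)^r)/N;
skewness = m3 / m2^(3/2), kurtosis = m4 / m2^2 (non-excess; a Gaussian has
kurtosis 3).  A valence class with zero variance gets skewness 0 and
kurtosis 0, flagged as degenerate, so a constant feature cannot abort a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emfspeech.data import (
    DIAGNOSIS_CODES,
    VALENCE_LEVELS,
    CohortManifest,
    DegenerateDataError,
    UtteranceFeatureTable,
    validate_cohort,
)
from emfspeech.selection import SelectedFeatureSet

#: fixed regression target: the three valence levels, one per row of M_i
VALENCE_TARGETS = np.array([-1.0, 0.0, 1.0])

MOMENT_BLOCKS = ("skew", "mean", "kurt")


class EmptyCohortError(ValueError):
    """No subject survived validation."""


@dataclass(frozen=True)
class MomentMatrix:
    """Per-subject 3 x 3*N_opt matrix of per-valence distribution descriptors.

    Columns come in three blocks of N_opt — [skewness | mean | kurtosis] —
    and rows are the valence classes (-1, 0, +1) in that order.
    """

    subject_id: str
    matrix: np.ndarray  # (3, 3 * n_opt)
    feature_names: tuple[str, ...]
    degenerate: np.ndarray  # (3, n_opt) True where a class had zero variance

    def __post_init__(self) -> None:
        if self.matrix.shape != (3, 3 * len(self.feature_names)):
            raise ValueError("moment matrix must be 3 x 3*N_opt")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("moment matrix contains non-finite entries")

    @property
    def n_opt(self) -> int:
        return len(self.feature_names)

    @property
    def column_names(self) -> list[str]:
        return [f"{b}:{f}" for b in MOMENT_BLOCKS for f in self.feature_names]

    def block(self, name: str) -> np.ndarray:
        i = MOMENT_BLOCKS.index(name)
        n = self.n_opt
        return self.matrix[:, i * n : (i + 1) * n]


@dataclass(frozen=True)
class EMFVector:
    """A subject's EMF: regression coefficients plus fit diagnostics."""

    subject_id: str
    coefficients: np.ndarray  # (3 * n_opt,)
    residual_norm: float
    rank: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("EMF coefficients must be finite")


@dataclass(frozen=True)
class EMFDataset:
    """Stacked EMF vectors with binary (Y) and four-class (L) labels.

    L codes: TD=0, PDD-NOS=1, SLI=2, AD=3; Y = (L > 0), i.e. 1 for any DD.
    """

    D: np.ndarray  # (n_subjects, 3 * n_opt)
    Y: np.ndarray  # (n_subjects,) in {0, 1}
    L: np.ndarray  # (n_subjects,) in {0, 1, 2, 3}
    subject_ids: tuple[str, ...]
    column_names: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    diagnostics: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.D.shape[0] != len(self.subject_ids):
            raise ValueError("row count must match subject ids")
        if not np.array_equal(self.Y, (self.L > 0).astype(int)):
            raise ValueError("Y must be the indicator of L > 0")

    @property
    def n_subjects(self) -> int:
        return self.D.shape[0]

    def drop_subject(self, subject_id: str) -> "EMFDataset":
        """Training view with one subject held out (leave-one-subject-out)."""
        keep = [i for i, s in enumerate(self.subject_ids) if s != subject_id]
        if len(keep) == self.n_subjects:
            raise KeyError(f"unknown subject {subject_id!r}")
        return EMFDataset(
            D=self.D[keep],
            Y=self.Y[keep],
            L=self.L[keep],
            subject_ids=tuple(self.subject_ids[i] for i in keep),
            column_names=self.column_names,
        )


def _class_moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean, skewness, kurtosis and a zero-variance flag, per feature column."""
    mu = values.mean(axis=0)
    dev = values - mu
    m2 = np.mean(dev**2, axis=0)
    m3 = np.mean(dev**3, axis=0)
    m4 = np.mean(dev**4, axis=0)
    degenerate = m2 == 0.0
    safe = np.where(degenerate, 1.0, m2)
    sk = np.where(degenerate, 0.0, m3 / safe**1.5)
    ku = np.where(degenerate, 0.0, m4 / safe**2)
    return mu, sk, ku, degenerate


def per_valence_moments(
    table: UtteranceFeatureTable,
    subject_id: str,
    features: SelectedFeatureSet,
) -> MomentMatrix:
    """Build a subject's 3 x 3*N_opt moment matrix over valence classes."""
    if features.n_opt < 1:
        raise ValueError("empty feature set: nothing to aggregate")
    x, e = table.subject_arrays(subject_id)
    x = x[:, list(features.indices)]
    n_opt = features.n_opt
    matrix = np.empty((3, 3 * n_opt))
    degenerate = np.zeros((3, n_opt), dtype=bool)
    for row, v in enumerate(VALENCE_LEVELS):
        vals = x[e == v]
        if vals.shape[0] == 0:
            raise DegenerateDataError(
                f"subject {subject_id!r} has no utterances in valence class {v}"
            )
        mu, sk, ku, dg = _class_moments(vals)
        matrix[row, :n_opt] = sk
        matrix[row, n_opt : 2 * n_opt] = mu
        matrix[row, 2 * n_opt :] = ku
        degenerate[row] = dg
    return MomentMatrix(
        subject_id=subject_id,
        matrix=matrix,
        feature_names=features.names,
        degenerate=degenerate,
    )


def estimate_emf(
    moments: MomentMatrix, targets: np.ndarray = VALENCE_TARGETS
) -> EMFVector:
    """Minimum-norm least-squares fit of the moment matrix to the valence targets.

    Whenever rank(M_i) = 3 the fit interpolates exactly (residual 0);
    diagnostics record the rank and residual either way.
    """
    m = moments.matrix
    v = np.asarray(targets, dtype=float).reshape(3)
    coef, _, rank, _ = np.linalg.lstsq(m, v, rcond=None)
    residual = float(np.linalg.norm(m @ coef - v))
    return EMFVector(
        subject_id=moments.subject_id,
        coefficients=coef,
        residual_norm=residual,
        rank=int(rank),
    )


def build_emf_dataset(
    table: UtteranceFeatureTable,
    manifest: CohortManifest,
    features: SelectedFeatureSet,
    min_per_valence: int = 3,
) -> EMFDataset:
    """One EMF row per subject passing validation; labels from the manifest."""
    report = validate_cohort(table, manifest, min_per_valence)
    included = report.included
    if not included:
        raise EmptyCohortError("no subject passed cohort validation")
    rows: list[np.ndarray] = []
    labels: list[int] = []
    diagnostics: dict[str, dict] = {}
    column_names: tuple[str, ...] = ()
    for sid in included:
        mm = per_valence_moments(table, sid, features)
        emf = estimate_emf(mm)
        rows.append(emf.coefficients)
        labels.append(DIAGNOSIS_CODES[manifest.diagnosis(sid)])
        diagnostics[sid] = {
            "rank": emf.rank,
            "residual_norm": emf.residual_norm,
            "degenerate_cells": int(mm.degenerate.sum()),
        }
        column_names = tuple(mm.column_names)
    L = np.array(labels, dtype=int)
    return EMFDataset(
        D=np.vstack(rows),
        Y=(L > 0).astype(int),
        L=L,
        subject_ids=tuple(included),
        column_names=column_names,
        excluded=tuple(report.excluded),
        diagnostics=diagnostics,
    )
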