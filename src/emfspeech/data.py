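"""Reading, validation and writing of utterance-level feature tables and
cohort manifests.

The row unit throughout the package is the *utterance*: a segmented speech
unit with a complete prosodic contour.  Each row carries a subject id, a
three-level valence annotation (negative -1, neutral 0, positive +1) and a
vector of real-valued acoustic features.  A cohort manifest maps each subject
to one of four diagnostic labels: TD (typically developing) or one of the
three developmental-disorder (DD) subgroups PDD-NOS, SLI and AD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DIAGNOSES = ("TD", "PDD-NOS", "SLI", "AD")
DD_SUBGROUPS = ("PDD-NOS", "SLI", "AD")
#: integer codes for the four-class label vector (TD=0, then DD subgroups)
DIAGNOSIS_CODES = {"TD": 0, "PDD-NOS": 1, "SLI": 2, "AD": 3}
VALENCE_LEVELS = (-1, 0, 1)

SUBJECT_COL = "subject_id"
VALENCE_COL = "valence"

# float format chosen so that text round-trips are bit-exact for doubles
_FLOAT_FMT = "%.17g"


class CorpusFormatError(ValueError):
    """Structural problem in an input file (missing column, duplicate id)."""


class DegenerateDataError(ValueError):
    """Data too degenerate for the requested operation (e.g. single valence)."""


@dataclass(frozen=True)
class UtteranceFeatureTable:
    """Validated utterance-level feature table.

    Parameters
    ----------
    df : DataFrame with columns ``subject_id``, ``valence`` and one numeric
        column per acoustic feature; one row per utterance.  Row order within
        a subject is meaningful and preserved.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_table_frame(self.df)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in (SUBJECT_COL, VALENCE_COL)]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def subjects(self) -> list[str]:
        # order of first appearance, stable across runs
        return list(dict.fromkeys(self.df[SUBJECT_COL]))

    def subject_rows(self, subject_id: str) -> pd.DataFrame:
        sub = self.df[self.df[SUBJECT_COL] == subject_id]
        if sub.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        return sub

    def subject_arrays(self, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix (n_utterances x n_features) and valence vector."""
        sub = self.subject_rows(subject_id)
        x = sub[self.feature_names].to_numpy(dtype=float)
        e = sub[VALENCE_COL].to_numpy(dtype=int)
        return x, e

    def feature_matrix(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    def valence_counts(self, subject_id: str) -> dict[int, int]:
        _, e = self.subject_arrays(subject_id)
        return {v: int(np.sum(e == v)) for v in VALENCE_LEVELS}


def _validate_table_frame(df: pd.DataFrame) -> None:
    for col in (SUBJECT_COL, VALENCE_COL):
        if col not in df.columns:
            raise CorpusFormatError(f"mandatory column {col!r} missing")
    features = [c for c in df.columns if c not in (SUBJECT_COL, VALENCE_COL)]
    if not features:
        raise CorpusFormatError("table has no feature columns")
    valence = df[VALENCE_COL]
    bad = ~valence.isin(VALENCE_LEVELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"valence must be one of {{-1, 0, +1}}; row {row} has {valence.iloc[row]!r}"
        )
    feat = df[features]
    non_numeric = [c for c in features if not pd.api.types.is_numeric_dtype(feat[c])]
    if non_numeric:
        raise ValueError(f"non-numeric feature column(s): {non_numeric}")
    if feat.isna().to_numpy().any():
        cells = list(zip(*np.nonzero(feat.isna().to_numpy())))
        raise ValueError(f"missing feature values at (row, feature) cells {cells[:5]}")


@dataclass(frozen=True)
class CohortManifest:
    """Mapping subject id -> diagnosis, with optional age/sex metadata."""

    diagnoses: dict[str, str]
    age: dict[str, float] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, dx in self.diagnoses.items():
            if dx not in DIAGNOSES:
                raise ValueError(
                    f"subject {sid!r}: diagnosis {dx!r} not in {DIAGNOSES}"
                )

    def __len__(self) -> int:
        return len(self.diagnoses)

    def diagnosis(self, subject_id: str) -> str:
        try:
            return self.diagnoses[subject_id]
        except KeyError:
            raise KeyError(f"subject {subject_id!r} absent from manifest") from None

    def is_dd(self, subject_id: str) -> bool:
        return self.diagnosis(subject_id) != "TD"

    def subjects_with(self, diagnosis: str) -> list[str]:
        return [s for s, d in self.diagnoses.items() if d == diagnosis]


@dataclass(frozen=True)
class ValidationReport:
    """Per-subject valence-class utterance counts and the exclusion list."""

    counts: dict[str, dict[int, int]]  # subject -> {-1: n, 0: n, +1: n}
    excluded: list[tuple[str, str]]  # (subject, reason)
    min_per_valence: int

    @property
    def included(self) -> list[str]:
        out = {s for s, _ in self.excluded}
        return [s for s in self.counts if s not in out]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "min_per_valence": self.min_per_valence,
            "counts": {s: {str(v): n for v, n in c.items()} for s, c in self.counts.items()},
            "excluded": [{"subject_id": s, "reason": r} for s, r in self.excluded],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def read_feature_table(path: str | Path, **csv_options) -> UtteranceFeatureTable:
    """Read an utterance-level feature table from CSV.

    Expected layout: header row with ``subject_id``, ``valence`` and at least
    one feature column; comma separator, '.' decimal, UTF-8.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, **csv_options)
    if SUBJECT_COL in df.columns:
        df[SUBJECT_COL] = df[SUBJECT_COL].astype(str)
    return UtteranceFeatureTable(df)


def write_feature_table(table: UtteranceFeatureTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest from CSV (subject_id,diagnosis[,age,sex]) or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        if isinstance(raw, dict):
            records = [{"subject_id": k, "diagnosis": v} for k, v in raw.items()]
        else:
            records = raw
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    if "subject_id" not in df.columns or "diagnosis" not in df.columns:
        raise CorpusFormatError("manifest needs 'subject_id' and 'diagnosis' columns")
    ids = df["subject_id"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise CorpusFormatError(f"duplicate subject id(s) in manifest: {dupes}")
    diagnoses = dict(zip(ids, df["diagnosis"].astype(str)))
    age = (
        {s: float(a) for s, a in zip(ids, df["age"]) if pd.notna(a)}
        if "age" in df.columns
        else {}
    )
    sex = (
        {s: str(x) for s, x in zip(ids, df["sex"]) if pd.notna(x)}
        if "sex" in df.columns
        else {}
    )
    return CohortManifest(diagnoses=diagnoses, age=age, sex=sex)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for sid, dx in manifest.diagnoses.items():
        row = {"subject_id": sid, "diagnosis": dx}
        if sid in manifest.age:
            row["age"] = manifest.age[sid]
        if sid in manifest.sex:
            row["sex"] = manifest.sex[sid]
        rows.append(row)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def validate_cohort(
    table: UtteranceFeatureTable,
    manifest: CohortManifest,
    min_per_valence: int = 3,
) -> ValidationReport:
    """Flag subjects with too few utterances in any valence class.

    ``min_per_valence`` defaults to 3 so that skewness and kurtosis are
    generically finite in every class.  A subject from the table missing in
    the manifest is a hard error; exclusion is only about utterance counts.
    """
    counts: dict[str, dict[int, int]] = {}
    excluded: list[tuple[str, str]] = []
    for sid in table.subjects:
        manifest.diagnosis(sid)  # raises KeyError if absent
        c = table.valence_counts(sid)
        counts[sid] = c
        empty = [v for v in VALENCE_LEVELS if c[v] == 0]
        short = [v for v in VALENCE_LEVELS if 0 < c[v] < min_per_valence]
        if empty and min_per_valence >= 1:
            excluded.append((sid, f"empty valence class {empty[0]}"))
        elif short:
            excluded.append(
                (sid, f"fewer than {min_per_valence} utterances in valence class {short[0]}")
            )
    return ValidationReport(counts=counts, excluded=excluded, min_per_valence=min_per_valence)


def make_table(
    subject_ids: Iterable[str],
    valences: Iterable[int],
    features: Mapping[str, Iterable[float]] | np.ndarray,
    feature_names: list[str] | None = None,
) -> UtteranceFeatureTable:
    """Convenience constructor used by the simulator and tests."""
    data: dict[str, object] = {SUBJECT_COL: list(subject_ids), VALENCE_COL: list(valences)}
    if isinstance(features, np.ndarray):
        if feature_names is None:
            feature_names = [f"f{j + 1}" for j in range(features.shape[1])]
        for j, name in enumerate(feature_names):
            data[name] = features[:, j]
    else:
        for name, col in features.items():
            data[name] = list(col)
    return UtteranceFeatureTable(pd.DataFrame(data))
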