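"""Synthetic cohort generation.

The generator emulates the statistical skeleton the EMF analysis assumes: a
cohort of TD children and three DD subgroups (PDD-NOS, SLI, AD) telling the
same picture story, each subject producing a fixed number of utterances per
valence level.  "Signal" features are linearly modulated by valence with
subject-specific slopes drawn around group-specific means; "nuisance"
features are valence-independent noise.  The default cohort shape mirrors the
study design: 68 TD / 10 PDD-NOS / 13 SLI / 11 AD subjects and 15 negative,
6 neutral, 5 positive utterances per subject (the emotional composition of
the pictured book used for elicitation).

Two slope geometries are available:

``subgroup_signs`` (default)
    TD subjects modulate every signal feature with mean slope ``base_slope``;
    each DD subgroup's mean slope is shifted by ``effect_size`` with a
    subgroup-specific sign pattern, so binary TD-vs-DD signal strength is
    governed solely by ``effect_size`` while the three subgroups remain
    mutually distinguishable.

``sign_flip``
    TD mean slope is ``+effect_size/2`` and all DD subgroups use
    ``-effect_size/2`` on every signal feature.  With an equal number of
    negative and positive utterances, per-utterance feature marginals are
    then identical across groups: the groups differ *only* in how features
    co-vary with valence, which is the regime where utterance-level
    classifiers are blind but the EMF signature is not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from emfspeech.data import (
    DD_SUBGROUPS,
    CohortManifest,
    UtteranceFeatureTable,
    make_table,
)

Count = int | tuple[int, int]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model.

    utterances_per_valence entries may be a fixed count or an inclusive
    (lo, hi) range sampled per subject.  ``effect_size`` is the shift of the
    group-mean modulation slope (same units as the slope itself);
    ``within_group_sd`` is the subject-to-subject slope jitter within a
    group; ``noise_sd`` is the additive utterance-level noise on signal
    features, whose scale is ~``base_slope``x(valence spread) ~ 1.
    """

    n_td: int = 68
    n_nos: int = 10
    n_sli: int = 13
    n_ad: int = 11
    utterances_per_valence: tuple[Count, Count, Count] = (15, 6, 5)
    n_signal: int = 10
    n_nuisance: int = 20
    effect_size: float = 0.9
    noise_sd: float = 0.1
    within_group_sd: float = 0.3
    base_slope: float = 1.0
    offset_sd: float = 1.0
    slope_mode: str = "subgroup_signs"  # or "sign_flip"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_td", "n_nos", "n_sli", "n_ad", "n_signal", "n_nuisance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("effect_size", "noise_sd", "within_group_sd", "offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.slope_mode not in ("subgroup_signs", "sign_flip"):
            raise ValueError(f"unknown slope_mode {self.slope_mode!r}")
        if self.n_signal + self.n_nuisance < 1:
            raise ValueError("at least one feature required")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "TD": self.n_td,
            "PDD-NOS": self.n_nos,
            "SLI": self.n_sli,
            "AD": self.n_ad,
        }

    @property
    def signal_features(self) -> list[str]:
        return [f"f{j + 1}" for j in range(self.n_signal)]

    @property
    def nuisance_features(self) -> list[str]:
        return [f"f{self.n_signal + j + 1}" for j in range(self.n_nuisance)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters: per-subject slopes/offsets and group means."""

    diagnoses: dict[str, str]
    slopes: dict[str, np.ndarray]  # subject -> (n_signal,)
    offsets: dict[str, np.ndarray]  # subject -> (n_signal,)
    group_mean_slopes: dict[str, np.ndarray]  # group -> (n_signal,)
    signal_features: list[str] = field(default_factory=list)
    nuisance_features: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "diagnoses": self.diagnoses,
            "slopes": {s: v.tolist() for s, v in self.slopes.items()},
            "offsets": {s: v.tolist() for s, v in self.offsets.items()},
            "group_mean_slopes": {g: v.tolist() for g, v in self.group_mean_slopes.items()},
            "signal_features": self.signal_features,
            "nuisance_features": self.nuisance_features,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _group_mean_slopes(config: SyntheticConfig) -> dict[str, np.ndarray]:
    n = config.n_signal
    ones = np.ones(n)
    if config.slope_mode == "sign_flip":
        td = 0.5 * config.effect_size * ones
        return {"TD": td, "PDD-NOS": -td, "SLI": -td, "AD": -td}
    # Subgroup patterns share +1 on even-indexed signal features (a common
    # shift direction, so the pooled DD class stays linearly separable from
    # TD) and differ on odd-indexed ones (so the subgroups stay mutually
    # distinguishable for subgroup-level analyses).
    idx = np.arange(n)
    odd = idx % 2 == 1
    nos = ones.copy()
    sli = np.where(odd, -1.0, 1.0)
    ad = np.where(odd & (idx % 4 == 3), -1.0, 1.0)
    patterns = {"PDD-NOS": nos, "SLI": sli, "AD": ad}
    means = {"TD": config.base_slope * ones}
    for g in DD_SUBGROUPS:
        means[g] = config.base_slope * ones + config.effect_size * patterns[g]
    return means


def _draw_count(rng: np.random.Generator, c: Count) -> int:
    if isinstance(c, tuple):
        lo, hi = c
        return int(rng.integers(lo, hi + 1))
    return int(c)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[UtteranceFeatureTable, CohortManifest, GroundTruth]:
    """Draw a full synthetic cohort, reproducibly from ``config.seed``.

    Signal feature j for subject i at utterance k takes the value
    ``a_ij * e(k) + b_ij + eps`` with ``eps ~ N(0, noise_sd^2)``; slopes
    ``a_ij ~ N(group mean, within_group_sd^2)``, offsets
    ``b_ij ~ N(0, offset_sd^2)``.  Nuisance features are standard-normal
    noise independent of valence.
    """
    rng = np.random.default_rng(config.seed)
    group_means = _group_mean_slopes(config)
    feature_names = config.signal_features + config.nuisance_features

    subject_ids: list[str] = []
    diagnoses: dict[str, str] = {}
    counter = 0
    for group in ("TD",) + DD_SUBGROUPS:
        for _ in range(config.group_sizes[group]):
            counter += 1
            sid = f"s{counter:03d}"
            subject_ids.append(sid)
            diagnoses[sid] = group

    rows_sid: list[str] = []
    rows_val: list[int] = []
    rows_feat: list[np.ndarray] = []
    slopes: dict[str, np.ndarray] = {}
    offsets: dict[str, np.ndarray] = {}
    for sid in subject_ids:
        group = diagnoses[sid]
        a = group_means[group] + config.within_group_sd * rng.standard_normal(config.n_signal)
        b = config.offset_sd * rng.standard_normal(config.n_signal)
        slopes[sid] = a
        offsets[sid] = b
        n_neg, n_neu, n_pos = (
            _draw_count(rng, config.utterances_per_valence[0]),
            _draw_count(rng, config.utterances_per_valence[1]),
            _draw_count(rng, config.utterances_per_valence[2]),
        )
        e = np.concatenate(
            [np.full(n_neg, -1), np.full(n_neu, 0), np.full(n_pos, 1)]
        ).astype(int)
        n_utt = e.size
        signal = a[None, :] * e[:, None] + b[None, :]
        signal = signal + config.noise_sd * rng.standard_normal((n_utt, config.n_signal))
        nuisance = rng.standard_normal((n_utt, config.n_nuisance))
        feats = np.hstack([signal, nuisance]) if config.n_nuisance else signal
        rows_sid.extend([sid] * n_utt)
        rows_val.extend(e.tolist())
        rows_feat.append(feats)

    table = make_table(
        rows_sid, rows_val, np.vstack(rows_feat), feature_names=feature_names
    )
    manifest = CohortManifest(diagnoses=diagnoses)
    truth = GroundTruth(
        diagnoses=dict(diagnoses),
        slopes=slopes,
        offsets=offsets,
        group_mean_slopes=group_means,
        signal_features=config.signal_features,
        nuisance_features=config.nuisance_features,
    )
    return table, manifest, truth


def permute_labels(manifest: CohortManifest, seed: int) -> CohortManifest:
    """Randomly permute diagnoses across subjects (label multiset preserved)."""
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(seed)
    sids = list(manifest.diagnoses)
    labels = [manifest.diagnoses[s] for s in sids]
    perm = rng.permutation(len(sids))
    shuffled = {sids[i]: labels[perm[i]] for i in range(len(sids))}
    return CohortManifest(diagnoses=shuffled, age=dict(manifest.age), sex=dict(manifest.sex))
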