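"""Experiment orchestration: configuration, full pipeline runs, artifacts.

``run_emf_pipeline`` chains data loading (or synthesis), cohort validation,
valence-based feature selection, EMF construction and the leave-one-subject-
out DFS + SVM evaluation, writing every report to the output directory.
``run_baseline_comparison`` additionally runs the FS1/FS2 standard-paradigm
baselines on the identical cohort and emits a side-by-side summary.

The selection stage supports two leakage modes.  "as-paper" computes the
shared selected-feature set from every subject's valence annotations once,
before cross-validation (diagnosis labels are never used, but the held-out
subject's valence structure can influence the set).  "strict" recomputes the
set from the training subjects only inside each fold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from emfspeech import baselines as bl
from emfspeech.data import (
    CohortManifest,
    UtteranceFeatureTable,
    read_feature_table,
    read_manifest,
    validate_cohort,
    write_feature_table,
    write_manifest,
)
from emfspeech.dfs import DFSThresholds, dfs_select
from emfspeech.emf import EMFDataset, build_emf_dataset
from emfspeech.evaluate import (
    EvaluationReport,
    FoldRecord,
    SelectionFrequencyTable,
    _fit_predict,
    compute_metrics,
    loso_evaluate,
    selection_frequency,
    subgroup_recall,
)
from emfspeech.selection import select_features
from emfspeech.simulate import SyntheticConfig, generate_cohort

logger = logging.getLogger("emfspeech")


class PipelineError(RuntimeError):
    """An orchestration stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run.  All fields have defaults except
    the data source: exactly one of (feature_table + manifest) paths or a
    synthetic config must be provided."""

    feature_table: str | None = None
    manifest: str | None = None
    synthetic: SyntheticConfig | None = None
    selection_threshold: float = 0.7
    redundancy_threshold: float | None = 0.95
    leakage_mode: str = "as-paper"  # "as-paper" | "strict"
    min_per_valence: int = 3
    dfs: DFSThresholds = field(default_factory=DFSThresholds)
    svm_c: float = 1.0
    baseline: bl.BaselineConfig = field(default_factory=bl.BaselineConfig)
    seed: int = 0
    out_dir: str = "runs/latest"
    trace: bool = False

    def __post_init__(self) -> None:
        has_paths = self.feature_table is not None and self.manifest is not None
        if not has_paths and self.synthetic is None:
            raise ValueError("config needs either data paths or a synthetic section")
        if self.leakage_mode not in ("as-paper", "strict"):
            raise ValueError(f"unknown leakage_mode {self.leakage_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            syn = dict(raw["synthetic"])
            if "utterances_per_valence" in syn:
                syn["utterances_per_valence"] = tuple(
                    tuple(v) if isinstance(v, list) else v
                    for v in syn["utterances_per_valence"]
                )
            raw["synthetic"] = SyntheticConfig(**syn)
        if "dfs" in raw and isinstance(raw["dfs"], dict):
            raw["dfs"] = DFSThresholds(**raw["dfs"])
        if "baseline" in raw and isinstance(raw["baseline"], dict):
            raw["baseline"] = bl.BaselineConfig(**raw["baseline"])
        return cls(**raw)


@dataclass(frozen=True)
class RunArtifacts:
    """Manifest of emitted files with SHA-256 checksums."""

    files: dict[str, dict[str, str]]  # name -> {"path": ..., "sha256": ...}

    def verify(self) -> bool:
        for entry in self.files.values():
            p = Path(entry["path"])
            if not p.exists() or _sha256(p) != entry["sha256"]:
                return False
        return True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.files, indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_generate(
    config: RunConfig, out: Path
) -> tuple[UtteranceFeatureTable, CohortManifest, list[Path]]:
    written: list[Path] = []
    if config.synthetic is not None:
        table, manifest, truth = generate_cohort(config.synthetic)
        write_feature_table(table, out / "features.csv")
        write_manifest(manifest, out / "manifest.csv")
        truth.to_json(out / "ground_truth.json")
        written = [out / "features.csv", out / "manifest.csv", out / "ground_truth.json"]
    else:
        table = read_feature_table(config.feature_table)
        manifest = read_manifest(config.manifest)
    return table, manifest, written


def loso_evaluate_strict(
    table: UtteranceFeatureTable,
    manifest: CohortManifest,
    config: RunConfig,
) -> tuple[EvaluationReport, SelectionFrequencyTable]:
    """LOSO where the selected-feature set is recomputed per training fold."""
    report = validate_cohort(table, manifest, config.min_per_valence)
    included = report.included
    folds: list[FoldRecord] = []
    name_hits: dict[str, dict[str, int]] = {}
    group_sizes: dict[str, int] = {}
    for sid in included:
        train_subjects = [s for s in included if s != sid]
        selected = select_features(
            table,
            config.selection_threshold,
            config.redundancy_threshold,
            subjects=train_subjects,
        )
        if selected.n_opt == 0:
            raise PipelineError("selection", f"empty feature set in fold {sid!r}")
        sub_manifest = CohortManifest(
            diagnoses={s: manifest.diagnosis(s) for s in included}
        )
        dataset = build_emf_dataset(table, sub_manifest, selected, config.min_per_valence)
        i = dataset.subject_ids.index(sid)
        training = dataset.drop_subject(sid)
        mask, trace = dfs_select(training, dataset.D[i], config.dfs)
        pred, score = _fit_predict(
            training.D[:, mask], training.Y, dataset.D[i : i + 1, mask], config.svm_c, config.seed
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
        g = manifest.diagnosis(sid)
        group_sizes[g] = group_sizes.get(g, 0) + 1
        for name, kept in zip(dataset.column_names, mask):
            if kept:
                name_hits.setdefault(name, {}).setdefault(g, 0)
                name_hits[name][g] += 1

    truths = np.array([f.truth for f in folds])
    preds = np.array([f.prediction for f in folds])
    scores = np.array([f.score for f in folds])
    rep = compute_metrics(
        tn=int(((truths == 0) & (preds == 0)).sum()),
        fp=int(((truths == 0) & (preds == 1)).sum()),
        fn=int(((truths == 1) & (preds == 0)).sum()),
        tp=int(((truths == 1) & (preds == 1)).sum()),
        scores=scores,
        truths=truths,
        folds=tuple(folds),
    )
    import pandas as pd

    names = sorted(name_hits)
    freq = SelectionFrequencyTable(
        pd.DataFrame(
            {
                g: [100.0 * name_hits[n].get(g, 0) / group_sizes[g] for n in names]
                for g in group_sizes
            },
            index=names,
        )
    )
    return rep, freq


def run_emf_pipeline(config: RunConfig) -> RunArtifacts:
    """Execute the full EMF pipeline and write all reports under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict[str, str]] = {}

    def register(name: str, path: Path) -> None:
        files[name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        table, manifest, written = _load_or_generate(config, out)
    except (OSError, ValueError) as exc:
        raise PipelineError("corpus_io", str(exc)) from exc
    for p in written:
        register(p.stem, p)

    try:
        vreport = validate_cohort(table, manifest, config.min_per_valence)
        vreport.to_json(out / "validation_report.json")
        register("validation_report", out / "validation_report.json")
    except (KeyError, ValueError) as exc:
        raise PipelineError("validation", str(exc)) from exc

    if config.leakage_mode == "strict":
        try:
            report, freq = loso_evaluate_strict(table, manifest, config)
        except ValueError as exc:
            raise PipelineError("classification", str(exc)) from exc
        traces = {}
        preds = {f.subject_id: f.prediction for f in report.folds}
    else:
        try:
            selected = select_features(
                table, config.selection_threshold, config.redundancy_threshold
            )
            if selected.n_opt == 0:
                raise PipelineError("selection", "no feature passed the correlation rule")
            (out / "selected_features.json").write_text(
                json.dumps(
                    {
                        "names": list(selected.names),
                        "indices": list(selected.indices),
                        "provenance": {
                            s: list(v) for s, v in selected.provenance.items()
                        },
                    },
                    indent=2,
                )
            )
            register("selected_features", out / "selected_features.json")
        except ValueError as exc:
            raise PipelineError("selection", str(exc)) from exc

        try:
            dataset = build_emf_dataset(table, manifest, selected, config.min_per_valence)
            _write_emf_dataset(dataset, out)
            register("emf_dataset", out / "emf_dataset.csv")
            register("emf_sidecar", out / "emf_dataset.json")
        except ValueError as exc:
            raise PipelineError("emf", str(exc)) from exc

        try:
            report, freq, traces = loso_evaluate(
                dataset,
                config.dfs,
                manifest=manifest,
                c=config.svm_c,
                seed=config.seed,
                collect_traces=config.trace,
            )
        except ValueError as exc:
            raise PipelineError("classification", str(exc)) from exc
        preds = {f.subject_id: f.prediction for f in report.folds}

    for f in report.folds:
        logger.info(
            "fold subject=%s n_selected=%d score=%+.4f pred=%d truth=%d",
            f.subject_id,
            int(f.mask.sum()),
            f.score,
            f.prediction,
            f.truth,
        )

    payload = report.to_dict()
    payload["subgroup_recall"] = subgroup_recall(preds, manifest)
    payload["config"] = _config_dict(config)
    (out / "evaluation_report.json").write_text(json.dumps(payload, indent=2))
    register("evaluation_report", out / "evaluation_report.json")
    freq.table.to_csv(out / "selection_frequency.csv")
    register("selection_frequency", out / "selection_frequency.csv")
    if config.trace and traces:
        (out / "dfs_traces.json").write_text(
            json.dumps({s: t.to_dict() for s, t in traces.items()}, indent=2)
        )
        register("dfs_traces", out / "dfs_traces.json")

    artifacts = RunArtifacts(files=files)
    artifacts.to_json(out / "artifacts.json")
    return artifacts


def run_baseline_comparison(config: RunConfig) -> RunArtifacts:
    """EMF pipeline plus FS1/FS2 baselines on the identical cohort."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = run_emf_pipeline(config)
    files = dict(artifacts.files)

    emf_report = json.loads((out / "evaluation_report.json").read_text())
    if config.synthetic is not None:
        table = read_feature_table(out / "features.csv")
        manifest = read_manifest(out / "manifest.csv")
    else:
        table = read_feature_table(config.feature_table)
        manifest = read_manifest(config.manifest)

    rows = [
        {
            "paradigm": "EMF",
            "balanced_accuracy": emf_report["balanced_accuracy"],
            "overall_rate": emf_report["accuracy"],
        }
    ]
    for mode in ("FS1", "FS2"):
        cfg = dataclasses.replace(config.baseline, mode=mode, seed=config.seed)
        try:
            rep = bl.baseline_evaluate(table, manifest, cfg)
        except ValueError as exc:
            raise PipelineError(f"baseline-{mode}", str(exc)) from exc
        rows.append(
            {
                "paradigm": mode,
                "balanced_accuracy": rep.balanced_accuracy,
                "overall_rate": rep.overall_rate,
            }
        )
        (out / f"baseline_{mode.lower()}.json").write_text(json.dumps(rep.to_dict(), indent=2))
        files[f"baseline_{mode.lower()}"] = {
            "path": str(out / f"baseline_{mode.lower()}.json"),
            "sha256": _sha256(out / f"baseline_{mode.lower()}.json"),
        }

    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "paradigm_comparison.csv", index=False)
    files["paradigm_comparison"] = {
        "path": str(out / "paradigm_comparison.csv"),
        "sha256": _sha256(out / "paradigm_comparison.csv"),
    }
    result = RunArtifacts(files=files)
    result.to_json(out / "artifacts.json")
    return result


def _write_emf_dataset(dataset: EMFDataset, out: Path) -> None:
    import pandas as pd

    df = pd.DataFrame(dataset.D, columns=list(dataset.column_names))
    df.insert(0, "subject_id", list(dataset.subject_ids))
    df.to_csv(out / "emf_dataset.csv", index=False)
    (out / "emf_dataset.json").write_text(
        json.dumps(
            {
                "Y": dataset.Y.tolist(),
                "L": dataset.L.tolist(),
                "subject_ids": list(dataset.subject_ids),
                "excluded": [list(e) for e in dataset.excluded],
                "diagnostics": dataset.diagnostics,
            },
            indent=2,
        )
    )


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    # output location is not part of the scientific state; leaving it out
    # keeps report checksums identical across reruns in different directories
    return {
        k: enc(v) for k, v in dataclasses.asdict(config).items() if k != "out_dir"
    }
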