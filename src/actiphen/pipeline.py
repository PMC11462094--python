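"""End-to-end orchestration: simulate -> preprocess -> scan lags -> select
features -> cluster -> associate -> transitions, with a run manifest.

Every stage writes its artifact (CSV/JSON) into the output directory and the
manifest records the seed, per-stage row counts and SHA-256 digests of every
artifact, so an identical config + seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path

import yaml

from . import association, clustering, lags, longitudinal, preprocessing, synthetic
from .core import (
    logger,
    read_daily_records,
    read_questionnaires,
    write_daily_records,
    write_questionnaires,
    write_windows,
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    daily_path: str | None = None  # used when simulate is False
    pro_path: str | None = None
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    window_days: int = 42
    min_coverage: float = 0.5
    lags_weeks: tuple = lags.DEFAULT_LAGS_WEEKS
    candidate_features: tuple = tuple(clustering.FEATURE_ATTRS)
    kmeans: clustering.KMeansParams = field(default_factory=clustering.KMeansParams)
    run_feature_search: bool = True
    min_n_paired: int = 5

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        raw.update(overrides)
        cohort = synthetic.CohortConfig(**raw.pop("cohort", {}))
        kmeans = clustering.KMeansParams(**raw.pop("kmeans", {}))
        config = cls(cohort=cohort, kmeans=kmeans, **raw)
        return config


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    try:
        manifest["version"] = pkg_version("actiphen")
    except PackageNotFoundError:  # pragma: no cover
        manifest["version"] = "unknown"

    def artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _digest(path)}

    # -- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            cohort_config = config.cohort
            cohort_config.seed = config.seed
            daily, questionnaires, truth = synthetic.generate_cohort(cohort_config)
            write_daily_records(daily, out / "daily.csv")
            write_questionnaires(questionnaires, out / "questionnaires.csv")
            truth.write(out / "truth.csv")
            artifact("daily", out / "daily.csv")
            artifact("questionnaires", out / "questionnaires.csv")
            artifact("truth", out / "truth.csv")
        else:
            if not config.daily_path or not config.pro_path:
                raise FileNotFoundError("daily_path and pro_path required when simulate is off")
            daily = read_daily_records(config.daily_path)
            questionnaires = read_questionnaires(config.pro_path)
        manifest["stages"][stage] = {"daily_rows": len(daily), "questionnaires": len(questionnaires)}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- preprocess ---------------------------------------------------------
    stage = "preprocess"
    try:
        cleaned, report = preprocessing.clean_daily_records(daily)
        windows = preprocessing.build_windows(
            cleaned, questionnaires, window_days=config.window_days, min_coverage=config.min_coverage, report=report
        )
        write_windows(windows, out / "windows.csv")
        (out / "cleaning_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        wear = preprocessing.wear_summary(windows)
        (out / "wear_summary.json").write_text(json.dumps(wear.to_dict(), indent=2))
        artifact("windows", out / "windows.csv")
        artifact("cleaning_report", out / "cleaning_report.json")
        artifact("wear_summary", out / "wear_summary.json")
        manifest["stages"][stage] = report.to_dict()
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- scan lags ----------------------------------------------------------
    stage = "scan_lags"
    try:
        scan = lags.scan_lags(cleaned, questionnaires, lags_weeks=config.lags_weeks, min_coverage=config.min_coverage)
        (out / "lagscan.json").write_text(json.dumps(scan.to_dict(), indent=2))
        artifact("lagscan", out / "lagscan.json")
        manifest["stages"][stage] = {"selected_lag_weeks": scan.selected_lag_weeks}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- feature selection --------------------------------------------------
    stage = "select_features"
    try:
        if config.run_feature_search:
            best, ranking = clustering.feature_subset_search(windows, config.candidate_features, config.kmeans)
            payload = {
                "selected": list(best),
                "ranking": [{"features": list(sub), "average_silhouette": score} for sub, score in sorted(ranking.items(), key=lambda kv: -kv[1])],
            }
            features = best
        else:
            features = clustering.DEFAULT_FEATURES
            payload = {"selected": list(features), "ranking": None}
        (out / "features.json").write_text(json.dumps(payload, indent=2))
        artifact("features", out / "features.json")
        manifest["stages"][stage] = {"selected": list(features)}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- cluster ------------------------------------------------------------
    stage = "cluster"
    try:
        usable = [
            w for w in windows if all(getattr(w, clustering.FEATURE_ATTRS[f]) is not None for f in features)
        ]
        matrix = clustering.windows_matrix(usable, features)
        model = clustering.lloyd(matrix, config.kmeans, feature_names=features)
        clustering.attach_silhouette(model, matrix)
        clustering.label_clusters(model)
        (out / "model.json").write_text(json.dumps(model.to_dict(), indent=2))
        assignments = {
            (w.participant_id, w.questionnaire_date): model.labels[int(model.assignments[i])]
            for i, w in enumerate(usable)
        }
        with open(out / "assignments.csv", "w", encoding="utf-8") as handle:
            handle.write("participant_id,questionnaire_date,cluster_label\n")
            for (pid, qdate), label in sorted(assignments.items()):
                handle.write(f"{pid},{qdate.isoformat()},{label}\n")
        artifact("model", out / "model.json")
        artifact("assignments", out / "assignments.csv")
        manifest["stages"][stage] = {
            "n_windows_clustered": len(usable),
            "sse": model.sse,
            "average_silhouette": model.silhouette.overall_mean,
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- associate ----------------------------------------------------------
    stage = "associate"
    try:
        profile = association.profile_clusters(usable, assignments, questionnaires)
        (out / "profile.json").write_text(json.dumps(profile.to_dict(), indent=2))
        artifact("profile", out / "profile.json")
        manifest["stages"][stage] = {"n_windows": sum(profile.n_windows.values())}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- transitions --------------------------------------------------------
    stage = "transitions"
    try:
        records = longitudinal.pair_consecutive(questionnaires, assignments)
        if records:
            summary = longitudinal.summarize_transitions(records, min_n=config.min_n_paired)
            (out / "transitions.json").write_text(json.dumps(summary.to_dict(), indent=2))
            artifact("transitions", out / "transitions.json")
            manifest["stages"][stage] = {
                "total_pairs": summary.total_pairs,
                "percent_same": summary.percent_same,
            }
        else:
            logger.warning("no consecutive questionnaire pairs; transitions stage skipped")
            manifest["stages"][stage] = {"total_pairs": 0}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
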