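"""End-to-end orchestration: config file parsing and the two entry points.

``cmd_simulate`` writes a synthetic cohort (trace CSV, covariate CSV and a
ground-truth JSON of the latent parameters); ``cmd_analyze`` runs
trim → day segmentation → completeness QC → biomarkers → subject aggregation
→ cohort statistics on existing files, writing a per-day QC table, the
subject biomarker table, the results JSON and a deterministic log of the
exclusion flow (subjects read, eligible, days valid).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarkers as bm
from . import cohort as ch
from . import io as cio
from . import qc as dq
from .qc import ConfigurationError
from .simulate import GeneratorConfig, TruncNormal, generate_cohort


class NoEligibleSubjectsError(RuntimeError):
    """Raised when QC leaves no subject with enough valid days."""


@dataclass
class PipelineConfig:
    """Single config object driving both the simulate and analyze commands."""

    seed: int
    traces: Path
    covariates: Path
    output_dir: Path
    qc: dq.QCConfig = field(default_factory=dq.QCConfig)
    detector: bm.DetectorConfig = field(default_factory=bm.DetectorConfig)
    generator: GeneratorConfig | None = None
    nocturnal: bool = True
    severity_bounds: dict | None = None


def _build(cls, mapping: dict, what: str):
    try:
        return cls(**mapping)
    except TypeError as exc:
        raise ConfigurationError(f"bad {what} block: {exc}") from None


def load_config(path) -> PipelineConfig:
    """Parse the YAML pipeline config; seed and paths are mandatory."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    if "seed" not in raw:
        raise ConfigurationError(f"{path}: a 'seed' entry is mandatory")
    paths = raw.get("paths", {})
    for key in ("traces", "covariates", "output_dir"):
        if key not in paths:
            raise ConfigurationError(f"{path}: paths.{key} is required")
    generator = None
    if "generator" in raw:
        gen_raw = dict(raw["generator"])
        gen_raw.setdefault("seed", raw["seed"])
        for dist_key in ("age", "bmi", "illness_duration", "edi2_total"):
            if dist_key in gen_raw and isinstance(gen_raw[dist_key], dict):
                spec = gen_raw[dist_key]
                gen_raw[dist_key] = _build(
                    TruncNormal,
                    {"mean": spec["mean"], "sd": spec["sd"],
                     "min": spec["min"], "max": spec["max"]},
                    f"generator.{dist_key}",
                )
        generator = _build(GeneratorConfig, gen_raw, "generator")
    analysis = raw.get("analysis", {})
    severity_bounds = None
    if "severity_bounds" in analysis:
        severity_bounds = {
            label: (float(lo), float(hi))
            for label, (lo, hi) in analysis["severity_bounds"].items()
        }
    return PipelineConfig(
        seed=int(raw["seed"]),
        traces=Path(paths["traces"]),
        covariates=Path(paths["covariates"]),
        output_dir=Path(paths["output_dir"]),
        qc=_build(dq.QCConfig, raw.get("qc", {}), "qc"),
        detector=_build(bm.DetectorConfig, raw.get("detector", {}), "detector"),
        generator=generator,
        nocturnal=bool(analysis.get("nocturnal", True)),
        severity_bounds=severity_bounds,
    )


def cmd_simulate(config: PipelineConfig) -> dict:
    """Generate a synthetic cohort and write its three artifacts.

    Returns a small summary dict. Identical config and seed produce
    byte-identical files.
    """
    if config.generator is None:
        raise ConfigurationError("simulate requires a 'generator' block")
    config.output_dir.mkdir(parents=True, exist_ok=True)
    records, traces = generate_cohort(config.generator)
    cio.write_covariates(records, config.covariates)
    cio.write_traces(traces, config.traces)
    truth = config.generator.ground_truth()
    truth_path = config.output_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {
        "n_subjects": len(records),
        "n_samples": int(sum(t.n_samples for t in traces)),
        "traces": str(config.traces),
        "covariates": str(config.covariates),
        "ground_truth": str(truth_path),
    }


def subject_biomarkers_from_trace(trace: cio.SensorTrace, qc: dq.QCConfig,
                                  det: bm.DetectorConfig
                                  ) -> tuple[list[dq.DayWindow],
                                             bm.SubjectBiomarkers | None]:
    """Trim, segment and aggregate one subject; None when ineligible."""
    trimmed = dq.trim_warmup(trace, qc)
    windows = dq.segment_days(trimmed, qc)
    valid, eligible = dq.eligible_days(windows, qc)
    if not eligible:
        return windows, None
    dailies = [bm.daily_biomarkers(w, det) for w in valid]
    return windows, bm.aggregate_subject(dailies, trace.subject_id,
                                         qc.min_valid_days)


def nocturnal_biomarkers_from_windows(subject_id: str,
                                      windows: list[dq.DayWindow],
                                      qc: dq.QCConfig, det: bm.DetectorConfig
                                      ) -> bm.SubjectBiomarkers | None:
    """Aggregate the nocturnal-window biomarkers; None when too few nights.

    Each calendar day's night window must itself meet the completeness rule
    (re-based on the samples the night interval can hold).
    """
    nights = [dq.night_window(w, qc) for w in windows]
    valid = [w for w in nights if w.valid]
    if len(valid) < qc.min_valid_days:
        return None
    dailies = [bm.daily_biomarkers(w, det) for w in valid]
    return bm.aggregate_subject(dailies, subject_id, qc.min_valid_days)


def _subject_frame(rows: list[bm.SubjectBiomarkers]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def cmd_analyze(config: PipelineConfig) -> ch.CohortResults:
    """Run the full analysis on existing trace and covariate files.

    Writes ``day_qc.csv``, ``subject_biomarkers.csv``, ``results.json`` and
    ``analyze.log`` (the exclusion-flow counts) under the output directory.
    Deterministic: no randomness, no timestamps in outputs.
    """
    for p in (config.traces, config.covariates):
        if not Path(p).exists():
            raise ConfigurationError(f"input file not found: {p}")
    config.output_dir.mkdir(parents=True, exist_ok=True)
    records = cio.read_covariates(config.covariates)
    traces = cio.read_traces(config.traces)
    covariate_ids = {r.subject_id for r in records}

    qc_rows = []
    subject_rows: list[bm.SubjectBiomarkers] = []
    nocturnal_rows: list[bm.SubjectBiomarkers] = []
    n_excluded_days = 0
    n_no_covariates = 0
    for trace in traces:
        if trace.subject_id not in covariate_ids:
            n_no_covariates += 1
            continue
        windows, subject = subject_biomarkers_from_trace(
            trace, config.qc, config.detector
        )
        for w in windows:
            qc_rows.append({
                "subject_id": w.subject_id, "date": w.date.isoformat(),
                "n_samples": w.n_samples,
                "completeness": round(w.completeness, 6),
                "valid": w.valid,
            })
        if subject is None:
            n_excluded_days += 1
            continue
        subject_rows.append(subject)
        if config.nocturnal:
            night = nocturnal_biomarkers_from_windows(
                trace.subject_id, windows, config.qc, config.detector
            )
            if night is not None:
                nocturnal_rows.append(night)

    qc_frame = pd.DataFrame(
        qc_rows, columns=["subject_id", "date", "n_samples",
                          "completeness", "valid"]
    )
    counts = {
        "subjects_in_covariates": len(records),
        "subjects_with_traces": len(traces),
        "subjects_without_covariates": n_no_covariates,
        "subjects_excluded_insufficient_valid_days": n_excluded_days,
        "subjects_eligible": len(subject_rows),
        "subjects_eligible_nocturnal": len(nocturnal_rows),
        "days_total": int(len(qc_frame)),
        "days_valid": int(qc_frame["valid"].sum()) if len(qc_frame) else 0,
    }
    qc_frame.to_csv(config.output_dir / "day_qc.csv", index=False)
    if not subject_rows:
        _write_log(config.output_dir / "analyze.log", counts)
        raise NoEligibleSubjectsError(
            "no subject passed QC (>=2 valid days); see analyze.log "
            f"in {config.output_dir}"
        )

    covariate_frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    table = _subject_frame(subject_rows).merge(covariate_frame, on="subject_id")
    table.to_csv(config.output_dir / "subject_biomarkers.csv", index=False,
                 float_format="%.6f")
    nocturnal_table = None
    if config.nocturnal and nocturnal_rows:
        nocturnal_table = _subject_frame(nocturnal_rows).merge(
            covariate_frame, on="subject_id"
        )
    severity_bounds = config.severity_bounds
    results = ch.run_full_analysis(table, nocturnal_table, severity_bounds)
    payload = results.to_dict()
    payload["qc_flow"] = counts
    (config.output_dir / "results.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    results.correlations_frame().to_csv(
        config.output_dir / "correlations.csv", index=False, float_format="%.6f"
    )
    _write_log(config.output_dir / "analyze.log", counts)
    return results


def _write_log(path: Path, counts: dict) -> None:
    lines = [f"{key}: {value}" for key, value in counts.items()]
    path.write_text("\n".join(lines) + "\n")
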