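"""End-to-end orchestration: two cohorts in, result bundle out.

Stages per cohort: QC -> outlier screen -> baseline table -> association
panel -> FDR + E-values -> quantile sensitivity for notable proteins; then
cross-cohort replication classification. Deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from ._errors import ConfigurationError, DataError
from .assay import Cohort, read_cohort, write_panel, write_participants, write_truth
from .association_models import ModelSpec, run_panel
from .descriptives import build_baseline_table
from .inference import (
    InferenceConfig,
    annotate_inference,
    classify_replication,
    verdict_summary,
    verdicts_to_dataframe,
)
from .outlier_filter import OutlierConfig, write_trace
from .qc_proteins import QCConfig
from .sensitivity_quantile import QuantileConfig, fit_median_regression
from .synthetic_cohort import (
    CohortConfig,
    discovery_default_config,
    generate_cohort,
    replication_default_config,
)

RESULT_COLUMNS = (
    "protein", "study_label", "model_type", "beta", "se", "ci_low", "ci_high",
    "p_value", "q_value", "notable", "n_used", "transform", "knots",
    "n_outliers_removed", "n_influential_removed", "outcome_sd",
    "rr_approx", "ev_point", "ev_ci", "display",
)


@dataclass
class CohortSource:
    """Either file paths to an existing cohort or a generator config."""

    participants: Optional[str] = None
    panel: Optional[str] = None
    assay_meta: Optional[str] = None
    generator: Optional[CohortConfig] = None

    def load(self, label: str) -> Cohort:
        if self.generator is not None:
            return generate_cohort(self.generator)
        if not (self.participants and self.panel and self.assay_meta):
            raise ConfigurationError(
                f"cohort source '{label}' needs either a generator or all three file paths"
            )
        return read_cohort(self.participants, self.panel, self.assay_meta, study_label=label)


@dataclass
class PipelineConfig:
    discovery: CohortSource = field(default_factory=lambda: CohortSource(generator=discovery_default_config()))
    replication: CohortSource = field(default_factory=lambda: CohortSource(generator=replication_default_config()))
    qc: QCConfig = field(default_factory=QCConfig)
    outliers: OutlierConfig = field(default_factory=OutlierConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    quantile: QuantileConfig = field(default_factory=QuantileConfig)
    quantile_all: bool = False  # run quantile fits for every protein, not only notables
    select_splines: bool = True
    compute_diagnostics: bool = True
    output_dir: str = "pleioscan_out"
    seed: Optional[int] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        for arm in ("discovery", "replication"):
            if arm in raw:
                spec = dict(raw[arm])
                if "generator" in spec:
                    gen_raw = dict(spec["generator"] or {})
                    base = (
                        discovery_default_config() if arm == "discovery"
                        else replication_default_config()
                    )
                    if "contamination" in gen_raw:
                        gen_raw["contamination"] = tuple(gen_raw["contamination"])
                    if "duplicate_spec" in gen_raw:
                        gen_raw["duplicate_spec"] = [tuple(e) for e in gen_raw["duplicate_spec"]]
                    gen = dataclasses.replace(base, **gen_raw)
                    setattr(cfg, arm, CohortSource(generator=gen))
                else:
                    setattr(cfg, arm, CohortSource(**spec))
        for section, klass in (
            ("qc", QCConfig), ("outliers", OutlierConfig),
            ("inference", InferenceConfig), ("quantile", QuantileConfig),
        ):
            if section in raw:
                setattr(cfg, section, klass(**raw[section]))
        for key in ("quantile_all", "select_splines", "compute_diagnostics",
                    "output_dir", "seed", "log_level"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def effective_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _results_dataframe(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = r.to_row()
        rows.append({c: row.get(c) for c in RESULT_COLUMNS})
        if r.quantile_fit is not None:
            qrow = {"protein": r.protein, "study_label": r.study_label}
            qrow.update(r.quantile_fit.to_row())
            qrow["q_value"] = None
            qrow["notable"] = None
            rows.append({c: qrow.get(c) for c in RESULT_COLUMNS})
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def run_cohort_analysis(cohort: Cohort, config: PipelineConfig):
    """Single-arm analysis; returns (results, skipped, qc_report, traces, baseline)."""
    results, skipped, qc_report, traces = run_panel(
        cohort,
        qc_config=config.qc,
        outlier_config=config.outliers,
        select_splines=config.select_splines,
        compute_diagnostics=config.compute_diagnostics,
    )
    if len(results) + len(skipped) != qc_report.n_retained:
        raise DataError("protein accounting violated: results + skipped != retained")
    annotate_inference(results, config.inference)
    from .association_models import build_model_frame
    from .outlier_filter import detect_outliers

    for r in results:
        if config.quantile_all or r.notable:
            assay = cohort.assay(r.protein)
            # re-derive the exact frame used for the OLS fit
            flags, _ = detect_outliers(assay.values, config.outliers)
            frame = build_model_frame(cohort, assay, outlier_flags=flags)
            r.quantile_fit = fit_median_regression(frame, r.fit.spec, config.quantile)
    baseline = build_baseline_table(cohort)
    return results, skipped, qc_report, traces, baseline


def _seed_offset_source(source: CohortSource, seed: Optional[int]) -> CohortSource:
    """Generator seed = base seed + pipeline seed; file sources untouched.
    The input config is never mutated (the manifest must replay exactly)."""
    if source.generator is None or seed is None:
        return source
    gen = dataclasses.replace(source.generator, seed=source.generator.seed + int(seed))
    return CohortSource(generator=gen)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute both arms plus replication classification and write the bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle: dict = {"results": {}, "verdicts": None, "paths": {}}
    per_arm_results = {}
    failures = []
    for arm_name in ("discovery", "replication"):
        source = _seed_offset_source(getattr(config, arm_name), config.seed)
        cohort = source.load(arm_name)
        if source.generator is not None:
            write_participants(cohort, out / f"participants_{arm_name}.tsv")
            write_panel(
                cohort, out / f"panel_{arm_name}.tsv", out / f"assay_meta_{arm_name}.tsv"
            )
            write_truth(cohort, out / f"truth_{arm_name}.json")
        results, skipped, qc_report, traces, baseline = run_cohort_analysis(cohort, config)
        failures.extend((arm_name, s.protein, s.reason) for s in skipped)
        df = _results_dataframe(results)
        df.to_csv(out / f"associations_{arm_name}.tsv", sep="\t", index=False)
        baseline.to_tsv(out / f"baseline_{arm_name}.tsv")
        qc_report.to_json(out / f"qc_{arm_name}.json")
        trace_path = out / f"outlier_trace_{arm_name}.jsonl"
        trace_path.write_text("")
        for protein, trace in traces.items():
            write_trace(trace, trace_path, protein=protein)
        per_arm_results[arm_name] = results
        bundle["results"][arm_name] = results
        bundle["paths"][f"associations_{arm_name}"] = str(out / f"associations_{arm_name}.tsv")

    verdicts = classify_replication(
        per_arm_results["discovery"], per_arm_results["replication"], config.inference
    )
    verdicts_to_dataframe(verdicts).to_csv(out / "verdicts.tsv", sep="\t", index=False)
    with open(out / "verdict_summary.json", "w") as fh:
        json.dump(verdict_summary(verdicts), fh, indent=2, sort_keys=True)
        fh.write("\n")
    bundle["verdicts"] = verdicts
    bundle["paths"]["verdicts"] = str(out / "verdicts.tsv")

    import pleioscan

    manifest = {
        "config": config.effective_dict(),
        "seed": config.seed,
        "versions": {
            "pleioscan": pleioscan.__version__,
            "python": platform.python_version(),
            "numpy": __import__("numpy").__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "skipped_proteins": [list(f) for f in failures],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    bundle["manifest"] = manifest
    bundle["failures"] = failures
    return bundle


def export_results(results, fmt: str, path: str | Path) -> Path:
    """Write association results as TSV or JSON; round-trips losslessly."""
    if not results:
        raise DataError("export_results: empty result list")
    if fmt not in ("tsv", "json"):
        raise ConfigurationError(f"unknown export format {fmt!r}")
    path = Path(path)
    df = _results_dataframe(results)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        records = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump({"schema": list(RESULT_COLUMNS), "results": records}, fh, indent=2)
            fh.write("\n")
    return path


def read_results(fmt: str, path: str | Path) -> pd.DataFrame:
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["results"], columns=payload["schema"])
    raise ConfigurationError(f"unknown export format {fmt!r}")
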