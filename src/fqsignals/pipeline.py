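"""End-to-end study pipeline: ingest -> dedup -> signals -> TTO -> risks.

``run_all`` executes every stage on one of three sources — a delimited
export file, the synthetic generator, or the deterministic reference
cohort — and writes tidy CSV tables plus a single JSON manifest with the
headline numbers. Reruns with an identical configuration are
byte-identical (timestamps only go to the log), so pipelines can be
diffed across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import fixture as fixture_mod
from .core import (
    CohortFlow,
    ColumnMap,
    ConfigurationError,
    build_cohort,
    read_dashboard_export,
)
from .disproportionality import BackgroundSummary, screen, shared_signal_prioritization
from .risk_factors import ImputationSpec, knn_impute, screen_risk_factors
from .synthetic import GeneratorParams, generate_cohort
from .trends import (
    TREND_SEGMENTS,
    cohort_summary,
    fatality_summary,
    fit_trend_segments,
    round_half_up,
    yearly_series,
)
from .tto import compute_tto, ecdf, rank_tests, tto_summary
from .vocabulary import PTVocabulary

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained with a FAILED marker."""


@dataclass
class RunConfig:
    source: str = "fixture"  # fixture | simulate | file
    input_path: Optional[str] = None
    vocabulary_path: Optional[str] = None
    synonyms_path: Optional[str] = None
    column_map: Dict[str, str] = field(default_factory=dict)
    ic_min: float = 2.0
    ci_lower_min: float = 0.0
    min_cases: int = 3
    interval_method: str = "gamma_quantile"
    trend_segments: list = field(default_factory=lambda: list(TREND_SEGMENTS))
    impute: bool = False
    imputation_k: int = 5
    suspect_only: bool = False
    background_n: int = 20_000_000
    background_pn_rate: float = 0.01825
    generator: Dict = field(default_factory=dict)
    out_dir: str = "fqsignals_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.source not in {"fixture", "simulate", "file"}:
            raise ConfigurationError(f"source must be fixture/simulate/file, got {self.source!r}")
        if self.source == "file":
            if not self.input_path:
                raise ConfigurationError("input_path is required for source 'file'")
            if not Path(self.input_path).exists():
                raise ConfigurationError(f"input_path does not exist: {self.input_path}")
        for name in ("vocabulary_path", "synonyms_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{name} does not exist: {value}")


def _load_vocab(config: RunConfig) -> PTVocabulary:
    if config.vocabulary_path:
        return PTVocabulary.from_csv(config.vocabulary_path)
    return PTVocabulary.default()


def _frame_to_csv(frame: pd.DataFrame, path: Path) -> None:
    out = frame.copy()
    for col in ("reactions", "pn_pts"):
        if col in out.columns:
            out[col] = out[col].map(lambda pts: "|".join(pts))
    for col in ("start_date", "event_date"):
        if col in out.columns:
            out[col] = out[col].map(lambda d: "" if d is None else str(d))
    out.to_csv(path, index=False)


def _acquire(config: RunConfig, vocab: PTVocabulary):
    """Source stage: returns (frame, flow, background)."""
    if config.source == "fixture":
        frame, background = fixture_mod.build_paper_marginals_fixture(vocab)
        n = len(frame)
        flow = CohortFlow(n, n, n, int(frame["has_pn"].sum()))
        return frame, flow, background
    if config.source == "simulate":
        params = GeneratorParams(**{**config.generator, "seed": config.seed})
        reports, truth = generate_cohort(params, vocab)
        frame, flow = build_cohort(reports, vocab, suspect_only=config.suspect_only)
        return frame, flow, truth["background"]
    reports = read_dashboard_export(
        config.input_path,
        columns=ColumnMap(**config.column_map) if config.column_map else None,
    )
    frame, flow = build_cohort(reports, vocab, suspect_only=config.suspect_only)
    background = BackgroundSummary(
        n_total=config.background_n,
        events={"PN": int(round(config.background_pn_rate * config.background_n))},
    )
    return frame, flow, background


def run_all(config: RunConfig) -> dict:
    """Run every stage, write the report bundle, return the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "setup"
    try:
        vocab = _load_vocab(config)

        stage = "ingest"
        frame, flow, background = _acquire(config, vocab)
        logger.info("cohort: %d raw -> %d dedup -> %d retained (%d PN)",
                    flow.n_raw, flow.n_after_dedup, flow.n_after_exclusion, flow.n_pn)
        _frame_to_csv(frame, out_dir / "cohort.csv")
        (out_dir / "cohort_flow.json").write_text(json.dumps(flow.to_dict(), indent=2) + "\n")

        stage = "descriptives"
        summary = cohort_summary(frame, vocab)
        for name, table in summary["tables"].items():
            table.to_csv(out_dir / f"descriptive_{name}.csv", index=False)
        summary["pn_pt_counts"].to_csv(out_dir / "pn_pt_counts.csv", index=False)
        summary["concurrent_pts"].to_csv(out_dir / "concurrent_pts.csv", index=False)

        stage = "signals"
        signal_tables = {}
        for unit in ("drug_overall", "drug_by_pt", "drug_by_category"):
            table = screen(frame, background, vocab, unit=unit,
                           min_cases=config.min_cases, method=config.interval_method)
            signal_tables[unit] = table
            table.to_csv(out_dir / f"signals_{unit.removeprefix('drug_')}.csv", index=False)
        shared = sorted(shared_signal_prioritization(signal_tables["drug_by_pt"])) \
            if len(signal_tables["drug_by_pt"]) else []

        stage = "trends"
        series = yearly_series(frame)
        series.to_csv(out_dir / "yearly_series.csv", index=False)
        trend_rows = []
        for response in ("counts", "pn_counts_with_offset"):
            try:
                for fit in fit_trend_segments(series, config.trend_segments, response=response):
                    trend_rows.append({"response": response, "segment_start": fit.segment[0],
                                       "segment_end": fit.segment[1], "slope": fit.slope,
                                       "slope_se": fit.slope_se, "dispersion": fit.dispersion,
                                       "p_slope": fit.p_slope, "model": fit.model})
            except ValueError as exc:
                logger.warning("trend fit skipped for %s: %s", response, exc)
        pd.DataFrame(trend_rows).to_csv(out_dir / "trend_fits.csv", index=False)

        stage = "tto"
        tto_result = compute_tto(frame)
        n_tto = len(tto_result.records)
        if n_tto:
            tto_result.records.to_csv(out_dir / "tto_records.csv", index=False)
            tables = [tto_summary(tto_result.records)]
            for by in ("sex", "age_group"):
                if tto_result.records[by].nunique() > 1:
                    tables.append(tto_summary(tto_result.records, by=by))
            pd.concat(tables, ignore_index=True).to_csv(out_dir / "tto_summary.csv", index=False)
            ecdf(tto_result.records).to_csv(out_dir / "tto_ecdf.csv", index=False)
        overall_tto = tto_summary(tto_result.records).iloc[0].to_dict() if n_tto else {}

        stage = "risk_factors"
        risks = screen_risk_factors(frame)
        risks.to_csv(out_dir / "risk_factors_unimputed.csv", index=False)
        if config.impute:
            imputed = knn_impute(frame, ImputationSpec(k=config.imputation_k))
            screen_risk_factors(imputed).to_csv(out_dir / "risk_factors_imputed.csv", index=False)

        stage = "manifest"
        fatal = fatality_summary(frame)
        overall = signal_tables["drug_overall"]

        def _ic(exposure: str) -> float:
            row = overall[overall["exposure"] == exposure]
            return round_half_up(float(row["ic"].iloc[0]), 2) if len(row) else float("nan")

        manifest = {
            "config": {k: v for k, v in dataclasses.asdict(config).items()},
            "cohort_flow": flow.to_dict(),
            "headline": summary["headline"],
            "signals": {
                "ic_all_fqs": _ic("All FQs"),
                "ic_ciprofloxacin": _ic("CFX"),
                "ic_combination": _ic("Combination"),
                "positive_signals": sorted(
                    overall.loc[overall["positive_signal"], "exposure"].tolist()
                ),
                "shared_pt_signals": shared,
            },
            "tto": {"n_records": n_tto, **{k: overall_tto.get(k) for k in ("median", "q1", "q3", "frac_within_7d")}},
            "fatality": {
                "n_fatal": fatal["n_fatal"],
                "n_fatal_pn": fatal["n_fatal_pn"],
                "male_share_pct": fatal["male_share_pct"],
                "monotherapy_fatal_pct": fatal["monotherapy_fatal_pct"],
                "combination_fatal_pct": fatal["combination_fatal_pct"],
            },
            "seed": config.seed,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        return manifest
    except Exception as exc:
        failed_marker.write_text(f"stage={stage}: {exc}\n")
        if isinstance(exc, (ConfigurationError, PipelineError)):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
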