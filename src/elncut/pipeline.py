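"""End-to-end orchestration: cohort -> occult table -> effect series ->
break points -> cut point -> validation, with every intermediate artifact
persisted as a flat file so any stage can be audited or re-run standalone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breakpoint import chow_scan, lowess_fit, select_cutpoint
from .detection import estimate_prior, occult_table
from .effects import (eln_effect_series, fit_stage_migration, fit_survival_model,
                      interaction_test, mean_positive_series,
                      positive_vs_examined_regression)
from .registry import GeneratorConfig, generate_cohort, read_cohort, write_cohort
from .validation import dichotomize_and_fit, validate_on_cohort

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort",
           "load_report_schema", "validate_report"]

log = logging.getLogger("elncut")


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run.

    Exactly one input mode is active: ``generator`` (simulate a derivation
    cohort, and a validation cohort from an offset seed) or
    ``cohort_path``/``validation_path`` (read delimited files).
    """

    outdir: str | Path = "results"
    generator: GeneratorConfig | None = None
    cohort_path: str | Path | None = None
    validation_path: str | Path | None = None
    m_total: int = 40
    sparsity_floor: int = 20
    bandwidth: float = 2.0 / 3.0
    candidate_range: tuple[float, float] | None = None
    threshold_override: int | None = None
    min_segment: int = 3
    include_interactions: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        simulate = self.generator is not None
        if simulate == (self.cohort_path is not None):
            raise ValueError("exactly one input mode must be active: "
                             "either `generator` or `cohort_path`")
        if not simulate and self.validation_path is None:
            log.warning("no validation cohort supplied; validation stage will be skipped")


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Cohort description: size, deaths, follow-up, ELN quantiles, N stage."""
    eln = cohort["eln_count"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=int)
    stage = cohort["n_stage"].astype(str)
    return {
        "n_patients": int(len(cohort)),
        "deaths": int(event.sum()),
        "censored_fraction": float(1.0 - event.mean()),
        "median_followup_years": float(np.median(cohort["time"])),
        "eln_median": float(np.median(eln)),
        "eln_iqr": [float(np.percentile(eln, 25)), float(np.percentile(eln, 75))],
        "n_stage_proportions": {s: float((stage == s).mean()) for s in ("N0", "N1", "N2")},
    }


def _series_frame(series_table: pd.DataFrame, value_col: str) -> tuple[np.ndarray, np.ndarray]:
    return (series_table["x"].to_numpy(dtype=float),
            series_table[value_col].to_numpy(dtype=float))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the analysis stages in order and return the report dict.

    Writes, under ``config.outdir``: the cohorts (simulate mode), the
    occult-probability table, each effect series with its LOWESS fit, each
    Chow scan, and ``report.json`` plus a human-readable ``summary.txt``.
    Fully deterministic given the generator seed.
    """
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "ingestion"
    try:
        if cfg.generator is not None:
            gen = cfg.generator
            if cfg.seed is not None and gen.seed is None:
                gen = dataclasses.replace(gen, seed=cfg.seed)
            log.info("simulating derivation cohort (n=%d)", gen.n_patients)
            cohort = generate_cohort(gen)
            val_gen = dataclasses.replace(
                gen, seed=None if gen.seed is None else gen.seed + 1_000_003)
            validation = generate_cohort(val_gen)
            write_cohort(cohort, outdir / "cohort.csv", include_latent=True)
            write_cohort(validation, outdir / "validation_cohort.csv", include_latent=True)
        else:
            log.info("reading cohort from %s", cfg.cohort_path)
            cohort = read_cohort(cfg.cohort_path)
            validation = (read_cohort(cfg.validation_path)
                          if cfg.validation_path is not None else None)

        stage = "summaries"
        summaries = {"derivation": summarize_cohort(cohort)}
        if validation is not None:
            summaries["validation"] = summarize_cohort(validation)

        stage = "continuous-models"
        migration = fit_stage_migration(cohort)
        os_n0 = fit_survival_model(cohort, subset="node-negative")
        os_npos = fit_survival_model(cohort, subset="node-positive")
        os_npos_adj = fit_survival_model(cohort, subset="node-positive",
                                         include_positive_count=True)
        slope, r2 = positive_vs_examined_regression(cohort)
        slope_pos, r2_pos = positive_vs_examined_regression(cohort, subset="node-positive")
        continuous = {
            "stage_migration_or": migration.ratio("eln_count"),
            "os_hr_node_negative": os_n0.ratio("eln_count"),
            "os_hr_node_positive": os_npos.ratio("eln_count"),
            "os_hr_node_positive_adjusted_for_positive_count":
                os_npos_adj.ratio("eln_count"),
            "positive_vs_examined": {"slope": slope, "r_squared": r2},
            "positive_vs_examined_node_positive": {"slope": slope_pos,
                                                   "r_squared": r2_pos},
        }
        if cfg.include_interactions:
            continuous["interaction_p_migration"] = interaction_test(
                cohort, outcome="stage-migration")
            continuous["interaction_p_survival"] = interaction_test(
                cohort, outcome="survival")

        stage = "occult-table"
        prior = estimate_prior(cohort)
        occ = occult_table(prior, cfg.m_total)
        occ_path = outdir / "occult_table.tsv"
        occ.to_csv(occ_path, sep="\t")

        stage = "effect-series"
        series_paths = {}
        series_data = {}
        or_series = eln_effect_series(cohort, outcome="stage-migration",
                                      sparsity_floor=cfg.sparsity_floor)
        hr_series = eln_effect_series(cohort, outcome="survival",
                                      subset="node-negative",
                                      sparsity_floor=cfg.sparsity_floor)
        mean_pos = mean_positive_series(cohort, sparsity_floor=cfg.sparsity_floor,
                                        terminal_percentile=99.0)
        series_data["migration"] = _series_frame(or_series.table, "estimate")
        series_data["survival"] = _series_frame(hr_series.table, "estimate")
        series_data["mean_positive"] = _series_frame(mean_pos, "mean_positive")
        occ_k0 = occ["p_occult_given_k0"].dropna()
        series_data["occult"] = (occ_k0.index.to_numpy(dtype=float),
                                 occ_k0.to_numpy(dtype=float))
        for name, table in (("migration", or_series.table),
                            ("survival", hr_series.table),
                            ("mean_positive", mean_pos)):
            p = outdir / f"series_{name}.tsv"
            table.to_csv(p, sep="\t", index=False)
            series_paths[name] = str(p)
        series_paths["occult"] = str(occ_path)

        stage = "break-points"
        breaks = {}
        scans = {}
        for name, (x, y) in series_data.items():
            smoothed = lowess_fit(x, y, bandwidth=cfg.bandwidth)
            result = chow_scan(smoothed, candidate_range=cfg.candidate_range,
                               min_segment=cfg.min_segment)
            raw_result = chow_scan((x, y), candidate_range=cfg.candidate_range,
                                   min_segment=cfg.min_segment)
            scans[name] = result
            breaks[name] = {
                "selected_break": result.selected_break,
                "f_at_break": result.f_at_break,
                "p_at_break": result.p_at_break,
                "raw_series_break": raw_result.selected_break,
            }
            scan_path = outdir / f"chow_scan_{name}.tsv"
            result.scan.to_csv(scan_path, sep="\t", index=False)
            breaks[name]["scan_path"] = str(scan_path)

        stage = "cut-point-selection"
        selection = select_cutpoint(scans, survival_key="survival")
        threshold = int(cfg.threshold_override
                        if cfg.threshold_override is not None
                        else round(selection.cutpoint))

        stage = "derivation-validation"
        derivation_fit = dichotomize_and_fit(cohort, threshold=threshold)
        validation_fit = None
        if validation is not None:
            validation_fit = validate_on_cohort(
                validation, threshold=threshold,
                derivation_provenance=cohort.attrs.get("provenance"))

        report = {
            "version": __version__,
            "config": {
                "mode": "simulate" if cfg.generator is not None else "files",
                "seed": cfg.seed if cfg.seed is not None else
                        (cfg.generator.seed if cfg.generator else None),
                "m_total": cfg.m_total,
                "sparsity_floor": cfg.sparsity_floor,
                "bandwidth": cfg.bandwidth,
                "threshold_override": cfg.threshold_override,
            },
            "cohort_summaries": summaries,
            "continuous_models": continuous,
            "occult_table_path": str(occ_path),
            "series_paths": series_paths,
            "break_points": breaks,
            "selected_cutpoint": threshold,
            "cutpoint_spread": list(selection.spread),
            "derivation_fit": derivation_fit.as_dict(),
            "validation_fit": validation_fit.as_dict() if validation_fit else None,
        }
        validate_report(report)
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        (outdir / "summary.txt").write_text(_human_summary(report))
        log.info("pipeline complete; report at %s", report_path)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _human_summary(report: dict) -> str:
    lines = [f"elncut pipeline report (v{report['version']})", ""]
    for name, s in report["cohort_summaries"].items():
        lines.append(
            f"{name}: n={s['n_patients']}, deaths={s['deaths']}, "
            f"median ELN={s['eln_median']:.0f} "
            f"(IQR {s['eln_iqr'][0]:.0f}-{s['eln_iqr'][1]:.0f})")
    cm = report["continuous_models"]
    lines.append("")
    lines.append(f"per-ELN stage-migration OR: {cm['stage_migration_or']['estimate']:.3f}")
    lines.append(f"per-ELN OS HR (node-negative): {cm['os_hr_node_negative']['estimate']:.3f}")
    lines.append(f"per-ELN OS HR (node-positive): {cm['os_hr_node_positive']['estimate']:.3f}")
    lines.append(f"mean positives vs ELN R^2: {cm['positive_vs_examined']['r_squared']:.3f}")
    lines.append("")
    for name, b in report["break_points"].items():
        lines.append(f"break point ({name}): {b['selected_break']:.0f}")
    lines.append(f"selected cut point: {report['selected_cutpoint']}")
    d = report["derivation_fit"]
    lines.append(f"dichotomized HR (derivation): {d['hr']:.3f} "
                 f"({d['ci_low']:.3f}-{d['ci_high']:.3f})")
    if report["validation_fit"]:
        v = report["validation_fit"]
        lines.append(f"dichotomized HR (validation): {v['hr']:.3f} "
                     f"({v['ci_low']:.3f}-{v['ci_high']:.3f})")
    return "\n".join(lines) + "\n"


def load_report_schema() -> dict:
    """The JSON schema the analysis report conforms to."""
    text = resources.files("elncut").joinpath("report_schema.json").read_text()
    return json.loads(text)


_TYPES = {"object": dict, "array": list, "string": str, "integer": int,
          "number": (int, float), "boolean": bool, "null": type(None)}


def validate_report(report: dict, schema: dict | None = None, _path: str = "$") -> None:
    """Check a report against the shipped schema.

    Covers the schema subset the report uses: ``type`` (including unions),
    ``required``, ``properties`` and ``items``.  Raises ``ValueError``
    naming the offending path.
    """
    if schema is None:
        schema = load_report_schema()
    types = schema.get("type")
    if types is not None:
        names = types if isinstance(types, list) else [types]
        allowed: tuple = ()
        for name in names:
            t = _TYPES[name]
            allowed += t if isinstance(t, tuple) else (t,)
        if isinstance(report, bool) and bool not in allowed:
            raise ValueError(f"{_path}: boolean not permitted by schema type {types}")
        if not isinstance(report, allowed):
            raise ValueError(f"{_path}: expected type {types}, got {type(report).__name__}")
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{_path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{_path}.{key}")
    if isinstance(report, list) and "items" in schema:
        for i, item in enumerate(report):
            validate_report(item, schema["items"], f"{_path}[{i}]")
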