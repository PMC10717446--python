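"""End-to-end analysis pipeline driven by a single YAML config.

Sequences the full workflow for one outcome: read summary statistics →
harmonize → instrument selection → Wald ratios → IVW / Egger / SIMEX /
weighted-median / Steiger / multivariable MR → instrument diagnostics →
population-scale transformation → observational meta-analysis →
causal-vs-observational comparison.  Each stage writes its TSV so it can be
inspected or re-run in isolation; the consolidated report is JSON and two
runs with identical config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import diagnostics, estimators, meta, sensitivity, sumstats, transform

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Everything needed for one full analysis run."""

    exposure_path: str
    outcome_path: str
    output_dir: str
    covariate_path: str | None = None
    studies_path: str | None = None
    outcome_label: str = "outcome"
    pvalue_threshold: float = 5e-5
    discordant_rsids: Sequence[str] = ()
    filter_palindromes: bool = False
    maf_window: float = 0.08
    n_boot: int = 10_000
    seed: int = 0
    run_simex: bool = True
    simex_lambdas: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0)
    simex_n_sim: int = 1000
    simex_n_boot: int = 100
    exposure_columns: Mapping[str, str] | None = None
    outcome_columns: Mapping[str, str] | None = None
    covariate_columns: Mapping[str, str] | None = None
    transform_params: transform.TransformParams | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        tp = raw.pop("transform_params", None)
        cfg = cls(**raw)
        if tp is not None:
            cfg.transform_params = transform.TransformParams(**tp)
        return cfg

    def validate(self) -> None:
        for name in ("exposure_path", "outcome_path", "covariate_path", "studies_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {name} {p!r} does not exist")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and return the report (also written as JSON).

    The report carries every pooled estimate (with OR and CI), per-stage
    SNP counts mirroring the filtering cascade, Steiger and strength
    diagnostics, and — when a study table is supplied — the observational
    pooled estimate, funnel test and causal-vs-observational comparison.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cannamr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    report: dict[str, Any] = {"outcome": config.outcome_label, "counts": counts}

    try:
        # --- read ------------------------------------------------------
        exp = _stage("read_exposure")(sumstats.read_summary_stats)(
            config.exposure_path, config.exposure_columns
        )
        out = _stage("read_outcome")(sumstats.read_summary_stats)(
            config.outcome_path, config.outcome_columns
        )
        cov = None
        if config.covariate_path:
            cov = _stage("read_covariate")(sumstats.read_summary_stats)(
                config.covariate_path, config.covariate_columns
            )
        counts["exposure_rows"] = len(exp.records)
        counts["exposure_dropped"] = exp.n_dropped
        counts["outcome_rows"] = len(out.records)

        # --- harmonize + select ---------------------------------------
        harm = _stage("harmonize")(sumstats.harmonize_pair)(
            exp.records, out.records, cov.records if cov else None
        )
        counts["harmonized"] = len(harm.instruments)
        counts["excluded_at_harmonization"] = len(harm.excluded)
        report["harmonization_exclusions"] = [list(e) for e in harm.excluded]

        selected = _stage("select_instruments")(sumstats.select_instruments)(
            harm.instruments, config.pvalue_threshold, config.discordant_rsids
        )
        counts["selected"] = len(selected)
        counts["gw_significant"] = sum(1 for i in selected if i.gw_significant)

        if config.filter_palindromes:
            pal = _stage("filter_palindromic")(sumstats.filter_palindromic)(
                selected, config.maf_window
            )
            selected = pal.kept
            counts["palindromic_removed"] = len(pal.removed)
        counts["analyzed"] = len(selected)
        sumstats.write_instruments(selected, outdir / "instruments.tsv")

        # --- MR suite --------------------------------------------------
        ratios = _stage("wald_ratios")(estimators.wald_ratios)(selected)
        results = [
            _stage("ivw_fixed")(estimators.ivw_fixed)(ratios),
            _stage("ivw_random")(estimators.ivw_random)(ratios),
            _stage("egger")(sensitivity.mr_egger)(selected, config.n_boot, config.seed),
            _stage("weighted_median")(sensitivity.weighted_median)(
                ratios, config.n_boot, config.seed + 1
            ),
        ]
        if config.run_simex:
            results.append(
                _stage("egger_simex")(sensitivity.egger_simex)(
                    selected,
                    config.simex_lambdas,
                    config.simex_n_sim,
                    config.seed + 2,
                    config.simex_n_boot,
                )
            )
        if any(i.beta_covariate is not None for i in selected):
            results.append(
                _stage("mvmr")(sensitivity.mvmr)(selected, config.n_boot, config.seed + 3)
            )

        steiger = _stage("steiger")(sensitivity.steiger_filter)(selected)
        sensitivity.write_steiger(steiger.results, outdir / "steiger.tsv")
        report["steiger"] = {
            "overall_correct_direction": steiger.overall_correct,
            "overall_p": steiger.overall_p,
            "n_wrong_direction": sum(1 for r in steiger.results if not r.correct_direction),
        }

        # --- diagnostics -----------------------------------------------
        r2_total = 0.0
        for ins in selected:
            if ins.eaf is not None:
                r2_total += 2.0 * ins.beta_exposure**2 * ins.eaf * (1.0 - ins.eaf)
        diag: dict[str, Any] = {"r2_total": r2_total}
        if 0 < r2_total < 1 and selected:
            diag["cumulative_f"] = diagnostics.cumulative_f(
                r2_total, selected[0].n_exposure, len(selected)
            )
        report["diagnostics"] = diag

        # --- population transform --------------------------------------
        if config.transform_params is not None:
            for est in [r for r in results if r.method in ("ivw_fixed", "mvmr")]:
                results.append(
                    _stage("transform")(transform.per_log_unit_to_ever_never)(
                        est, config.transform_params
                    )
                )

        estimators.write_estimates(results, outdir / "estimates.tsv")
        estimators.write_estimates(results, outdir / "estimates.json", fmt="json")
        report["estimates"] = {r.method: r.to_dict() for r in results}

        # --- observational meta ----------------------------------------
        if config.studies_path:
            studies = _stage("read_studies")(meta.read_study_table)(config.studies_path)
            pooled = _stage("dl_meta")(meta.dl_meta)(studies)
            obs: dict[str, Any] = {"pooled": pooled.to_dict(), "n_studies": len(studies)}
            if len(studies) >= 3:
                funnel = _stage("funnel")(meta.egger_funnel_test)(studies)
                obs["funnel"] = funnel._asdict()
            meta.forest_data(studies, pooled).to_csv(
                outdir / "forest.tsv", sep="\t", index=False
            )
            report["observational"] = obs
            report["comparison"] = compare_estimates(report)

        report_json = json.dumps(report, indent=2, sort_keys=True, allow_nan=False)
        (outdir / "report.json").write_text(report_json + "\n")
        logger.info("pipeline complete: %s", outdir / "report.json")
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


def compare_estimates(report: Mapping[str, Any]) -> dict[str, Any]:
    """Side-by-side comparison of the observational pooled estimate and the
    population-scale causal estimate, with a between-group Q test."""
    obs = report.get("observational")
    if not obs or "pooled" not in obs:
        raise PipelineError("comparison: report lacks the observational meta-analysis arm")
    causal_key = next(
        (k for k in ("ivw_fixed_population", "ivw_fixed") if k in report.get("estimates", {})),
        None,
    )
    if causal_key is None:
        raise PipelineError("comparison: report lacks a causal (IVW) estimate arm")
    causal = report["estimates"][causal_key]

    def as_est(d: Mapping[str, Any]) -> estimators.MrEstimate:
        return estimators.MrEstimate(
            method=d["method"], theta=d["theta"], se=d["se"], ci_low=d["ci_low"],
            ci_high=d["ci_high"], pvalue=d["pvalue"], n_snps=d["n_snps"],
        )

    q = meta.between_group_q(as_est(obs["pooled"]), as_est(causal))
    return {
        "observational_or": obs["pooled"]["odds_ratio"],
        "causal_method": causal_key,
        "causal_or": causal["odds_ratio"],
        "between_group_q": q.q_stat,
        "between_group_p": q.pvalue,
    }
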