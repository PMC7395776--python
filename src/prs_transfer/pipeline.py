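"""End-to-end orchestration: simulate -> score -> associate -> theory ->
absolute risk -> concordance, from one configuration, with a JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger("prs_transfer")

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either a simulation config (the default) or paths to pre-existing
    inputs; stage toggles; output directory; seed.
    """

    outdir: str = "prs_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    stages: tuple = ("simulate", "score", "assoc", "theory", "absrisk", "icc")
    info_threshold: float = 0.9
    reference_sd: float | None = None   # default: config.control_sd_pop1
    lambda_fam: float = 2.0
    risk_threshold: float = 0.023
    weights_path: str | None = None
    cohort_path: str | None = None
    rates_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _ci_dict(est) -> dict:
    return {"point": est.point, "lcl": est.lcl, "ucl": est.ucl,
            "scale": est.scale, "p": est.p, "label": est.label}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a report.

    Intermediate tables are written into ``config.outdir``; the aggregated
    report (every estimate with CI, theory predictions, absolute-risk
    summaries and ICC) is returned and stored as ``report.json``.
    """
    from . import absrisk, association, concordance, scoring, simulate, theory
    from .weights import WeightPanel

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = simulate.SimulationConfig(**{"seed": config.seed,
                                           **config.simulation})
    ref_sd = config.reference_sd or sim_cfg.control_sd_pop1
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}

    def _stage(name):
        def deco(fn):
            if name in config.stages:
                t0 = time.perf_counter()
                log.info("stage %s ...", name)
                try:
                    fn()
                except Exception as exc:
                    report["stages"][name] = {"status": "failed", "error": str(exc)}
                    (outdir / "report.json").write_text(json.dumps(report, indent=2))
                    raise PipelineError(name, exc) from exc
                report["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.perf_counter() - t0, 3),
                }
            return fn
        return deco

    @_stage("simulate")
    def _simulate():
        if config.weights_path:
            state["panel"] = WeightPanel.from_tsv(config.weights_path)
        else:
            state["panel"] = simulate.gen_weight_panel(sim_cfg)
            state["panel"].to_tsv(outdir / "weights.tsv")
        cohort, dosages, gt = simulate.gen_case_control_cohort(
            state["panel"].filter_by_info(config.info_threshold), sim_cfg)
        cohort = simulate.gen_family_history(cohort, sim_cfg, gt)
        prosp, _ = simulate.gen_prospective_cohort(state["panel"], sim_cfg)
        rates = (absrisk.RatesTable.from_csv(config.rates_path)
                 if config.rates_path else simulate.gen_rates_table())
        gt.to_json(outdir / "ground_truth.json")
        cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
        prosp.to_csv(outdir / "prospective.tsv", sep="\t", index=False)
        rates.to_csv(outdir / "rates.csv")
        state.update(cohort=cohort, dosages=dosages, gt=gt,
                     prospective=prosp, rates=rates)

    @_stage("score")
    def _score():
        panel = state["panel"].filter_by_info(config.info_threshold)
        raw = scoring.compute_prs(state["dosages"], panel)
        std = scoring.standardize(raw, ref_sd)
        state["cohort"]["prs_std"] = std.values
        state["prospective"]["prs_std"] = (
            state["prospective"]["prs_raw"] / ref_sd)
        summary = scoring.summarize_prs(raw, state["cohort"]["status"])
        summary.to_csv(outdir / "prs_summary.tsv", sep="\t", index=False)
        report["prs"] = {
            "n_variants": len(panel),
            "reference_sd": ref_sd,
            "control_sd": float(raw[state["cohort"]["status"] == 0].std(ddof=1)),
        }

    @_stage("assoc")
    def _assoc():
        cohort = state["cohort"]
        per_sd = association.fit_logistic_per_sd(cohort)
        bins = association.percentile_bin_or(cohort)
        auc = association.study_adjusted_auc(cohort)
        fh = association.fh_attenuation(cohort)
        hr = association.fit_cox_per_sd(state["prospective"])
        per_study = [association.fit_logistic_per_sd(g, stratum_col=None)
                     for _, g in cohort.groupby("stratum")]
        meta = association.fixed_effect_meta(per_study)
        report["association"] = {
            "or_per_sd": _ci_dict(per_sd),
            "bin_or": [_ci_dict(e) for e in bins],
            "auc": auc,
            "hr_per_sd": _ci_dict(hr),
            "fh": {"or_unadjusted": _ci_dict(fh.or_unadjusted),
                   "or_adjusted": _ci_dict(fh.or_adjusted),
                   "attenuation_pct": fh.attenuation_pct,
                   "defined": fh.defined},
            "meta": {"pooled": _ci_dict(meta.pooled), "Q": meta.Q,
                     "I2": meta.I2, "p_het": meta.p_het},
        }
        state["or_per_sd"] = per_sd

    @_stage("theory")
    def _theory():
        sd2 = state["gt"].true_prs_sd_by_pop["pop2"]
        model = theory.PolygenicModel.from_or_per_sd(
            state.get("or_per_sd").point if "or_per_sd" in state
            else float(np.exp(sim_cfg.per_sd_log_or)),
            reference_sd=ref_sd, control_sd=sd2,
            prevalence=sim_cfg.prevalence)
        frr = theory.frr_explained(model, config.lambda_fam)
        report["theory"] = {
            "gamma": model.gamma,
            "lambda_p": frr.lambda_p,
            "frr_fraction_explained": frr.fraction_explained,
            "predicted_bin_or": theory.predicted_bin_or(model).tolist(),
            "theoretical_auc": theory.theoretical_auc(model),
        }
        state["model"] = model

    @_stage("absrisk")
    def _absrisk():
        model = state["model"]
        scheme = association.PercentileBinScheme()
        groups = absrisk.RiskGroupSet.from_scheme(scheme, model.gamma)
        curve = absrisk.calibrate_group_hazards(state["rates"], groups)
        lo = int(state["rates"].ages[0])
        hi = min(80, int(state["rates"].ages[-1]))
        lifetime = absrisk.cumulative_risk(curve, lo, hi)
        thr_age = absrisk.age_at_threshold(curve, config.risk_threshold)
        frac_pop, frac_cases, _ = absrisk.screening_eligibility(
            model, state["rates"], config.risk_threshold)
        curve.to_frame().to_csv(outdir / "risk_curves.tsv", sep="\t",
                                index=False)
        report["absolute_risk"] = {
            "bin_labels": list(scheme.labels),
            "lifetime_risk": lifetime.tolist(),
            "threshold_age": thr_age,
            "screened_fraction": frac_pop,
            "cases_captured_fraction": frac_cases,
        }

    @_stage("icc")
    def _icc():
        panel, gt = simulate.gen_effect_panel(sim_cfg)
        fit = concordance.em_icc(panel)
        panel.to_tsv(outdir / "effect_panel.tsv")
        report["icc"] = {"icc": fit.icc, "sigma2_R": fit.sigma2_R,
                         "true_icc": gt.true_icc,
                         "converged": fit.converged,
                         "n_iterations": fit.n_iterations}

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
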