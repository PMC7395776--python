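"""Synthetic cohorts with known ground truth.

Generates every input the downstream analyses consume — a two-population
SNP weight panel, case-control cohorts with allele dosages, first-degree
family history, a right-censored prospective cohort, age-specific rate
tables and per-SNP effect-size panels — from one
:class:`SimulationConfig`, so the whole pipeline is testable end to end
without any external data.

The data-generating process mirrors the statistical structure of a
European-derived breast-cancer PRS evaluated in an Asian population:

* SNPs are independent; dosages are Binomial(2, freq) draws.  A configurable
  fraction of SNPs that are common in population 1 are rare (MAF < 0.05) in
  population 2, which lowers the population-2 PRS SD.
* Disease is sampled under a log-linear model: logit P(case) is linear in
  the raw PRS with slope ``per_sd_log_or / control_sd_pop1`` (the effect is
  parameterised per reference-control SD) at a configurable baseline
  prevalence.
* Family history comes from one simulated first-degree relative whose PRS
  correlates 0.5 with the proband's and whose disease risk follows the same
  log-linear model.
* Prospective follow-up uses a constant baseline hazard multiplied by
  ``exp(beta * PRS)``, independent exponential censoring and an
  administrative follow-up limit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .weights import WeightPanel, WEIGHT_COLUMNS

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the combined Asian case-control analysis: 313 candidate
    SNPs of which 26 fail the INFO filter, ~15% of SNPs rare in the analysed
    population, a per-reference-SD log odds ratio of ln(1.52), control PRS
    SDs of 0.597 (reference population 1) and 0.556 (analysed population 2),
    and the published sample sizes.
    """

    n_snps: int = 313
    n_low_info: int = 26
    frac_rare_pop2: float = 43 / 287
    per_sd_log_or: float = math.log(1.52)
    control_sd_pop1: float = 0.597
    control_sd_pop2: float = 0.556
    n_cases: int = 15_755
    n_controls: int = 16_483
    n_strata: int = 10
    prevalence: float = 0.05
    er_positive_fraction: float = 0.66
    er_typed_fraction: float = 0.97
    er_negative_scale: float = 1.0
    fh_relative_correlation: float = 0.5
    fh_prevalence: float = 0.10
    n_prospective: int = 10_255
    followup_years: float = 19.0
    censoring_rate: float = 0.01
    baseline_hazard: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_snps", "n_cases", "n_controls", "n_strata", "n_prospective"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_low_info <= self.n_snps:
            raise ValueError("n_low_info must lie in [0, n_snps]")
        for name in ("frac_rare_pop2", "er_positive_fraction", "er_typed_fraction",
                     "fh_relative_correlation", "fh_prevalence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (self.control_sd_pop1 > 0 and self.control_sd_pop2 > 0):
            raise ValueError("control SDs must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """True generating parameters, recorded alongside every dataset."""

    true_gamma: float = float("nan")        # log OR per reference (pop1) SD
    true_beta_raw: float = float("nan")     # log OR per raw PRS unit
    true_prs_sd_by_pop: dict = field(default_factory=dict)
    prs_mean: float = float("nan")          # population mean raw PRS (pop2)
    prevalence: float = float("nan")
    baseline_hazard: float = float("nan")
    true_icc: float = float("nan")
    seed: int = -1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# internal helpers

def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # one seeded generator per dataset: (seed, stream-tag) seeds a fresh PCG64
    return np.random.default_rng([config.seed, stream])


def _binom2(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    """Binomial(2, p) dosages as int8, one column per SNP."""
    u1 = rng.random((n, p.size), dtype=np.float32)
    u2 = rng.random((n, p.size), dtype=np.float32)
    p32 = p.astype(np.float32)
    return (u1 < p32).astype(np.int8) + (u2 < p32).astype(np.int8)


def population_prs_moments(panel: WeightPanel, population: str = "pop2",
                           weight_set: str = "overall") -> tuple[float, float]:
    """(mean, SD) of the raw PRS under Binomial(2, freq) dosages."""
    w = panel.weights(weight_set)
    p = panel.table[f"freq_{population}"].to_numpy(float)
    mean = float(np.sum(w * 2 * p))
    sd = float(np.sqrt(np.sum(w**2 * 2 * p * (1 - p))))
    return mean, sd


# --------------------------------------------------------------------------
# generators

def gen_weight_panel(config: SimulationConfig) -> WeightPanel:
    """Two-population weight panel with INFO scores and frequencies.

    Weights are scaled so the population-2 PRS SD equals
    ``config.control_sd_pop2`` exactly; the population-1 SD is then emergent
    from the frequency spectrum (a shared weight vector cannot hit two SD
    targets independently) and is close to ``control_sd_pop1`` at the
    default rare fraction.  ``n_low_info`` randomly chosen SNPs receive INFO
    scores below 0.9 to exercise the imputation-quality filter.
    """
    rng = _rng(config, 1)
    n = config.n_snps
    p1 = rng.uniform(0.10, 0.50, n)
    rare = rng.random(n) < config.frac_rare_pop2
    p2 = np.clip(p1 + rng.normal(0.0, 0.07, n), 0.05, 0.95)
    p2[rare] = rng.uniform(0.005, 0.045, rare.sum())

    w = rng.normal(0.0, 1.0, n)
    var2 = np.sum(w**2 * 2 * p2 * (1 - p2))
    w *= config.control_sd_pop2 / np.sqrt(var2)

    info = rng.uniform(0.90, 1.00, n)
    low = rng.choice(n, size=config.n_low_info, replace=False)
    info[low] = rng.uniform(0.50, 0.899, config.n_low_info)

    eff_idx = rng.integers(0, 4, n)
    shift = rng.integers(1, 4, n)  # ensures other != effect
    oth_idx = (eff_idx + shift) % 4

    table = pd.DataFrame({
        "variant_id": [f"rs{100000 + i}" for i in range(n)],
        "chrom": rng.integers(1, 23, n),
        "pos": np.sort(rng.integers(1, 250_000_000, n)),
        "effect_allele": _NUCS[eff_idx],
        "other_allele": _NUCS[oth_idx],
        "weight_overall": w,
        "weight_erpos": w * (1 + rng.normal(0.0, 0.05, n)),
        "weight_erneg": config.er_negative_scale * w * (1 + rng.normal(0.0, 0.05, n)),
        "info": info,
        "freq_pop1": p1,
        "freq_pop2": p2,
    })
    return WeightPanel(table[WEIGHT_COLUMNS])


def panel_ground_truth(panel: WeightPanel, config: SimulationConfig) -> GroundTruth:
    mean2, sd2 = population_prs_moments(panel, "pop2")
    _, sd1 = population_prs_moments(panel, "pop1")
    return GroundTruth(
        true_gamma=config.per_sd_log_or,
        true_beta_raw=config.per_sd_log_or / config.control_sd_pop1,
        true_prs_sd_by_pop={"pop1": sd1, "pop2": sd2},
        prs_mean=mean2,
        prevalence=config.prevalence,
        baseline_hazard=config.baseline_hazard,
        seed=config.seed,
    )


def gen_case_control_cohort(
    panel: WeightPanel,
    config: SimulationConfig,
    population: str = "pop2",
    max_population: int | None = None,
) -> tuple[pd.DataFrame, "DosageMatrix", GroundTruth]:
    """Case-control cohort sampled by rejection from a synthetic population.

    Individuals are drawn from population ``population`` (dosages
    Binomial(2, freq)); case status is Bernoulli with
    ``logit p = logit(prevalence) + beta_raw * (PRS - mean)``.
    Draws continue until exactly ``n_cases`` cases and ``n_controls``
    controls are collected; if the quota is still unmet after
    ``max_population`` individuals (default: 1000x the target sample size)
    the case count is unattainable and an error is raised.  Strata, ten
    synthetic principal components, age, ethnicity and ER subtype are
    attached.
    """
    from .dosages import DosageMatrix

    if len(panel) == 0:
        raise ValueError("empty weight panel")
    rng = _rng(config, 2)
    gt = panel_ground_truth(panel, config)
    p = panel.table[f"freq_{population}"].to_numpy(float)
    beta = panel.weights("overall")
    mean, _ = population_prs_moments(panel, population)
    b_raw = gt.true_beta_raw
    alpha = logit(config.prevalence)

    need_cases, need_controls = config.n_cases, config.n_controls
    case_rows, control_rows, case_prs, control_prs = [], [], [], []
    drawn = 0
    max_draws = max_population or 1000 * (config.n_cases + config.n_controls)
    batch = 50_000
    while need_cases > 0 or need_controls > 0:
        if drawn > max_draws:
            raise RuntimeError(
                "unattainable case/control count at the configured prevalence"
            )
        x = _binom2(rng, p, batch)
        drawn += batch
        prs = x @ beta
        pdis = expit(alpha + b_raw * (prs - mean))
        status = rng.random(batch) < pdis
        ci = np.flatnonzero(status)[:need_cases]
        ki = np.flatnonzero(~status)[:need_controls]
        if ci.size:
            case_rows.append(x[ci])
            case_prs.append(prs[ci])
            need_cases -= ci.size
        if ki.size:
            control_rows.append(x[ki])
            control_prs.append(prs[ki])
            need_controls -= ki.size

    x_all = np.vstack([np.vstack(case_rows), np.vstack(control_rows)])
    prs_all = np.concatenate([np.concatenate(case_prs), np.concatenate(control_prs)])
    n_total = config.n_cases + config.n_controls
    status_all = np.zeros(n_total, dtype=int)
    status_all[: config.n_cases] = 1

    er = np.array(["unknown"] * n_total, dtype=object)
    typed = rng.random(config.n_cases) < config.er_typed_fraction
    pos = rng.random(config.n_cases) < config.er_positive_fraction
    er[: config.n_cases][typed & pos] = "positive"
    er[: config.n_cases][typed & ~pos] = "negative"

    eth = rng.choice(["Chinese", "Malay", "Indian"], size=n_total,
                     p=[0.72, 0.17, 0.11])
    cohort = pd.DataFrame({
        "sample_id": [f"S{i:06d}" for i in range(n_total)],
        "status": status_all,
        "er_status": er,
        "age": np.clip(rng.normal(52.0, 10.0, n_total), 25, 80).round(1),
        "ethnicity": eth,
        "stratum": [f"study{k + 1}" for k in rng.integers(0, config.n_strata, n_total)],
    })
    for j in range(10):
        cohort[f"pc{j + 1}"] = rng.normal(0.0, 1.0, n_total)
    cohort["prs_raw"] = prs_all

    dosages = DosageMatrix(
        samples=cohort["sample_id"].to_numpy(),
        variant_ids=panel.variant_ids,
        counted_allele=panel.table["effect_allele"].to_numpy(str),
        other_allele=panel.table["other_allele"].to_numpy(str),
        values=x_all.astype(float),
        chrom=panel.table["chrom"].to_numpy(),
        pos=panel.table["pos"].to_numpy(),
    )
    return cohort, dosages, gt


def gen_family_history(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    ground_truth: GroundTruth,
) -> pd.DataFrame:
    """Attach a binary first-degree family-history flag.

    One relative (a mother) is simulated per woman: her PRS correlates
    ``fh_relative_correlation`` with the proband's, and her lifetime disease
    risk is log-linear in her own PRS at marginal prevalence
    ``fh_prevalence``.  Family history is therefore informative about the
    proband's PRS, and (through it) about her case status.
    """
    if "prs_raw" not in cohort.columns:
        raise ValueError("cohort must carry a prs_raw column")
    rho = config.fh_relative_correlation
    rng = _rng(config, 4)
    mu = ground_truth.prs_mean
    sigma = ground_truth.true_prs_sd_by_pop["pop2"]
    prs = cohort["prs_raw"].to_numpy(float)
    rel = mu + rho * (prs - mu) + math.sqrt(1 - rho**2) * sigma * rng.normal(size=len(prs))
    p_fh = expit(logit(config.fh_prevalence)
                 + ground_truth.true_beta_raw * (rel - mu))
    out = cohort.copy()
    out["family_history"] = (rng.random(len(prs)) < p_fh).astype(int)
    return out


def tune_baseline_hazard(
    panel: WeightPanel,
    config: SimulationConfig,
    target_events: float,
) -> float:
    """Baseline hazard whose expected prospective event count hits a target.

    Under a constant baseline with PRS-multiplied rate r, exponential
    censoring c and administrative follow-up F, the per-woman event
    probability is ``r/(r+c) * (1 - exp(-(r+c)F))``; this is averaged over a
    normal approximation to the PRS distribution and solved for the
    baseline by bisection.
    """
    mean, sd = population_prs_moments(panel, "pop2")
    b = config.per_sd_log_or / config.control_sd_pop1
    z = np.linspace(-6, 6, 2001)
    wz = np.exp(-0.5 * z**2)
    wz /= wz.sum()
    mult = np.exp(b * sd * z)
    c, F = config.censoring_rate, config.followup_years

    def expected(lam0: float) -> float:
        r = lam0 * mult
        pe = r / (r + c) * (1 - np.exp(-(r + c) * F)) if c > 0 else 1 - np.exp(-r * F)
        return config.n_prospective * float(np.sum(wz * pe))

    return brentq(lambda l0: expected(l0) - target_events, 1e-8, 0.5)


def gen_prospective_cohort(
    panel: WeightPanel,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Right-censored prospective cohort with PRS-dependent event hazard.

    Entry ages are uniform on 43-75; the event hazard is
    ``baseline_hazard * exp(beta_raw * (PRS - mean))``; censoring is the
    earlier of an exponential dropout time and the administrative follow-up
    limit.  Exit age is entry plus observed follow-up, and ``event`` flags a
    breast-cancer diagnosis at exit.
    """
    if config.followup_years <= 0:
        raise ValueError("followup_years must be positive")
    rng = _rng(config, 3)
    gt = panel_ground_truth(panel, config)
    n = config.n_prospective
    p = panel.table["freq_pop2"].to_numpy(float)
    beta = panel.weights("overall")
    x = _binom2(rng, p, n)
    prs = x @ beta
    rate = config.baseline_hazard * np.exp(gt.true_beta_raw * (prs - gt.prs_mean))

    entry = rng.uniform(43.0, 75.0, n)
    t_event = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.followup_years)
    follow = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    df = pd.DataFrame({
        "sample_id": [f"P{i:06d}" for i in range(n)],
        "entry_age": entry,
        "exit_age": entry + follow,
        "event": event,
        "prs_raw": prs,
    })
    for j in range(7):
        df[f"pc{j + 1}"] = rng.normal(0.0, 1.0, n)
    return df, gt


def gen_rates_table(
    ages=(20, 80),
    peak_incidence: float = 0.0019,
    peak_age: float = 47.0,
    width: float = 12.0,
    mortality_coeff: float = 2e-5,
    mortality_growth: float = 0.095,
    constant_incidence: float | None = None,
):
    """Synthetic age-specific incidence and competing-mortality table.

    Incidence is a Gaussian-shaped bump peaking between ages 40 and 50
    (mimicking Asian breast-cancer age curves); competing mortality is
    Gompertz.  ``constant_incidence`` overrides the bump with a flat rate.
    All rates are per person-year.
    """
    from .absrisk import RatesTable

    lo, hi = int(ages[0]), int(ages[1])
    grid = np.arange(lo, hi + 1)
    if constant_incidence is not None:
        inc = np.full(grid.size, float(constant_incidence))
    else:
        inc = peak_incidence * np.exp(-0.5 * ((grid - peak_age) / width) ** 2)
    mort = mortality_coeff * np.exp(mortality_growth * grid)
    if (inc < 0).any() or (mort < 0).any():
        raise ValueError("rates must be non-negative")
    return RatesTable(ages=grid, incidence=inc, competing_mortality=mort)


def gen_effect_panel(
    config: SimulationConfig,
    n_pops: int = 2,
    between_sd: float = 0.08,
    within_sd: float = 0.02,
    se_range: tuple[float, float] = (0.03, 0.15),
):
    """Per-SNP effect-size panel across populations, with known ICC.

    Per-SNP mean effects are drawn N(0, between_sd^2); population-specific
    true effects add N(0, within_sd^2) deviations (``within_sd=0`` is the
    shared-architecture mode: identical true effects everywhere); observed
    estimates add known sampling noise with SEs uniform on ``se_range``
    (the scale of per-SNP log-OR SEs in GWAS of a few thousand cases).
    """
    from .concordance import EffectSizePanel

    rng = _rng(config, 5)
    n = config.n_snps
    alpha = rng.normal(0.0, between_sd, n)
    beta = alpha[:, None] + rng.normal(0.0, within_sd, (n, n_pops))
    se = rng.uniform(se_range[0], se_range[1], (n, n_pops))
    y = beta + se * rng.normal(size=(n, n_pops))
    true_icc = between_sd**2 / (between_sd**2 + within_sd**2) if between_sd > 0 else 0.0
    gt = GroundTruth(true_icc=true_icc, seed=config.seed)
    panel = EffectSizePanel(
        snp_ids=np.array([f"rs{100000 + i}" for i in range(n)]),
        populations=np.array([f"pop{j + 1}" for j in range(n_pops)]),
        estimates=y,
        standard_errors=se,
    )
    return panel, gt
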