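"""Association statistics for PRS evaluation.

Per-SD and percentile-bin odds ratios from covariate-adjusted logistic
regression, prospective hazard ratios from Cox regression with delayed
entry on the age scale, study-adjusted AUC, inverse-variance fixed-effect
meta-analysis with heterogeneity statistics, PRS-by-modifier interaction
tests, family-history attenuation, and rescaling of per-SD odds ratios
between SD conventions.

Cohort tables are plain :class:`pandas.DataFrame` objects carrying at least
``status`` (0/1) plus the PRS and covariate columns named in each call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

Z95 = st.norm.ppf(0.975)

DEFAULT_PCS = tuple(f"pc{i}" for i in range(1, 11))


class AssociationError(ValueError):
    """Degenerate design or unusable input."""


@dataclass(frozen=True)
class EstimateCI:
    """Point estimate with 95% CI, reported on the exponentiated scale."""

    point: float
    lcl: float
    ucl: float
    scale: str = "log-odds"          # or "log-hazard"
    beta: float = float("nan")       # estimate on the log scale
    se: float = float("nan")
    p: float = float("nan")
    n_cases: int | None = None
    n_controls: int | None = None
    events: int | None = None
    person_years: float | None = None
    label: str = ""

    @property
    def log_se(self) -> float:
        """SE on the log scale, recovered from the CI when not stored."""
        if np.isfinite(self.se):
            return self.se
        return (math.log(self.ucl) - math.log(self.lcl)) / (2 * Z95)


@dataclass(frozen=True)
class PercentileBinScheme:
    """Cut points as cumulative control fractions, plus a reference bin."""

    boundaries: tuple = (0.0, 0.01, 0.05, 0.10, 0.20, 0.40,
                         0.60, 0.80, 0.90, 0.95, 0.99, 1.0)
    reference_index: int = 5  # the 40-60% bin

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        if b[0] != 0.0 or b[-1] != 1.0 or (np.diff(b) <= 0).any():
            raise AssociationError("boundaries must increase strictly from 0 to 1")
        if not 0 <= self.reference_index < len(b) - 1:
            raise AssociationError("reference_index out of range")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    @property
    def labels(self) -> list[str]:
        b = self.boundaries
        return [f"{b[i]:g}-{b[i + 1]:g}" for i in range(self.n_bins)]

    def assign(self, values: np.ndarray, controls: np.ndarray) -> np.ndarray:
        """Bin index per value, from control quantiles (type-7).

        Values exactly at a cut point go to the upper bin.
        """
        cuts = np.quantile(np.asarray(controls, float),
                           np.asarray(self.boundaries[1:-1]))
        return np.searchsorted(cuts, np.asarray(values, float), side="right")


@dataclass(frozen=True)
class MetaResult:
    pooled: EstimateCI
    Q: float
    df: int
    I2: float
    p_het: float
    studies: tuple = field(default_factory=tuple)


# --------------------------------------------------------------------------
# design-matrix plumbing

def _design(cohort: pd.DataFrame, columns: Sequence[str],
            stratum_col: str | None) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    for c in columns:
        X[c] = pd.to_numeric(cohort[c], errors="raise")
    if stratum_col is not None and cohort[stratum_col].nunique() > 1:
        dummies = pd.get_dummies(cohort[stratum_col], prefix=stratum_col,
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> sm.Logit:
    if len(np.unique(y)) < 2:
        raise AssociationError("both outcome classes must be present")
    Xv = X.to_numpy(float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise AssociationError("design matrix is rank deficient (collinearity)")
    model = sm.Logit(y, Xv)
    try:
        res = model.fit(disp=0, maxiter=100, tol=1e-8)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise AssociationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise AssociationError("logistic fit did not converge "
                               f"(llf={res.llf:.3g}); possible separation")
    res.exog_names_ = list(X.columns)
    return res


def _wald_ci(res, name: str, scale: str, **extra) -> EstimateCI:
    j = res.exog_names_.index(name)
    b, se = res.params[j], res.bse[j]
    return EstimateCI(
        point=math.exp(b), lcl=math.exp(b - Z95 * se), ucl=math.exp(b + Z95 * se),
        scale=scale, beta=b, se=se, p=2 * st.norm.sf(abs(b) / se), **extra,
    )


# --------------------------------------------------------------------------
# odds ratios

def fit_logistic_per_sd(
    cohort: pd.DataFrame,
    prs_col: str = "prs_std",
    covariates: Sequence[str] = DEFAULT_PCS,
    stratum_col: str | None = "stratum",
) -> EstimateCI:
    """OR per unit of (standardised) PRS with 95% Wald CI.

    Adjusts for the named covariates plus stratum indicators (default: ten
    principal components and study/array/batch stratum).
    """
    y = cohort["status"].to_numpy(int)
    X = _design(cohort, [prs_col, *covariates], stratum_col)
    res = _fit_logit(y, X)
    return _wald_ci(res, prs_col, "log-odds",
                    n_cases=int(y.sum()), n_controls=int((1 - y).sum()))


def percentile_bin_or(
    cohort: pd.DataFrame,
    scheme: PercentileBinScheme = PercentileBinScheme(),
    prs_col: str = "prs_std",
    covariates: Sequence[str] = DEFAULT_PCS,
    stratum_col: str | None = "stratum",
) -> list[EstimateCI]:
    """OR per PRS percentile bin versus the reference (40-60%) bin.

    Bin boundaries are control-distribution quantiles applied to everyone;
    a logistic model with bin indicator variables (reference omitted) plus
    covariates yields one Wald OR per non-reference bin; the reference bin
    is reported with OR exactly 1.
    """
    y = cohort["status"].to_numpy(int)
    prs = cohort[prs_col].to_numpy(float)
    bins = scheme.assign(prs, prs[y == 0])
    counts = np.bincount(bins, minlength=scheme.n_bins)
    if (counts == 0).any():
        raise AssociationError(
            f"empty PRS bin(s): {np.flatnonzero(counts == 0).tolist()}")

    X = _design(cohort, list(covariates), stratum_col)
    names = []
    for b in range(scheme.n_bins):
        if b == scheme.reference_index:
            continue
        name = f"bin{b}"
        X[name] = (bins == b).astype(float)
        names.append((b, name))
    res = _fit_logit(y, X)

    out = []
    for b in range(scheme.n_bins):
        nc = int(y[bins == b].sum())
        nk = int((1 - y)[bins == b].sum())
        if b == scheme.reference_index:
            out.append(EstimateCI(1.0, 1.0, 1.0, "log-odds", 0.0, 0.0, 1.0,
                                  n_cases=nc, n_controls=nk,
                                  label=scheme.labels[b]))
        else:
            name = dict(names)[b]
            est = _wald_ci(res, name, "log-odds", n_cases=nc, n_controls=nk,
                           label=scheme.labels[b])
            out.append(est)
    return out


# --------------------------------------------------------------------------
# prospective hazard ratio

def fit_cox_per_sd(
    cohort: pd.DataFrame,
    prs_col: str = "prs_std",
    covariates: Sequence[str] = tuple(f"pc{i}" for i in range(1, 8)),
) -> EstimateCI:
    """HR per (standardised) PRS unit from a Cox model on the age scale.

    Uses delayed entry (left truncation at entry age), censoring at exit
    age, and Efron handling of tied event times.
    """
    from lifelines import CoxPHFitter

    if int(cohort["event"].sum()) < 1:
        raise AssociationError("no events in prospective cohort")
    if (cohort["exit_age"] <= cohort["entry_age"]).any():
        raise AssociationError("exit_age must exceed entry_age")
    cols = [prs_col, *[c for c in covariates if c in cohort.columns]]
    df = cohort[["entry_age", "exit_age", "event", *cols]].copy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="exit_age", event_col="event",
            entry_col="entry_age")
    b = float(cph.params_[prs_col])
    se = float(cph.standard_errors_[prs_col])
    return EstimateCI(
        point=math.exp(b), lcl=math.exp(b - Z95 * se), ucl=math.exp(b + Z95 * se),
        scale="log-hazard", beta=b, se=se, p=2 * st.norm.sf(abs(b) / se),
        events=int(cohort["event"].sum()),
        person_years=float((cohort["exit_age"] - cohort["entry_age"]).sum()),
    )


# --------------------------------------------------------------------------
# discrimination

def study_adjusted_auc(
    cohort: pd.DataFrame,
    score_col: str = "prs_std",
    stratum_col: str | None = "stratum",
) -> float:
    """AUC restricted to within-stratum case-control pairs.

    Concordance is computed per stratum (ties count 1/2) and pooled with
    case x control pair-count weights; strata lacking a case or a control
    contribute no pairs.
    """
    if stratum_col is None:
        groups = [cohort]
    else:
        groups = [g for _, g in cohort.groupby(stratum_col, sort=False)]
    num = den = 0.0
    for g in groups:
        y = g["status"].to_numpy(int)
        n1, n0 = int(y.sum()), int((1 - y).sum())
        if n1 == 0 or n0 == 0:
            continue
        ranks = st.rankdata(g[score_col].to_numpy(float))
        u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
        num += u
        den += n1 * n0
    if den == 0:
        raise AssociationError("no within-stratum case-control pairs")
    return float(num / den)


# --------------------------------------------------------------------------
# meta-analysis

def fixed_effect_meta(estimates: Sequence[EstimateCI]) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Q, I-squared and p_het.

    SEs are taken from each estimate (or recovered from its CI);
    heterogeneity uses the fixed-effect weights: Q = sum w_i (b_i - b)^2,
    I^2 = max(0, (Q - df)/Q) * 100, p from chi-square with k-1 df.
    """
    if not estimates:
        raise AssociationError("no estimates to pool")
    b = np.array([e.beta if np.isfinite(e.beta) else math.log(e.point)
                  for e in estimates])
    se = np.array([e.log_se for e in estimates])
    if (se <= 0).any() or ~np.isfinite(se).all():
        raise AssociationError("zero-width or invalid CI in meta input")
    w = 1.0 / se**2
    bbar = float(np.sum(w * b) / np.sum(w))
    se_p = float(1.0 / math.sqrt(np.sum(w)))
    Q = float(np.sum(w * (b - bbar) ** 2))
    df = len(estimates) - 1
    I2 = max(0.0, (Q - df) / Q) * 100 if Q > 0 and df > 0 else 0.0
    p_het = float(st.chi2.sf(Q, df)) if df > 0 else 1.0
    scale = estimates[0].scale
    pooled = EstimateCI(
        point=math.exp(bbar), lcl=math.exp(bbar - Z95 * se_p),
        ucl=math.exp(bbar + Z95 * se_p), scale=scale, beta=bbar, se=se_p,
        p=2 * st.norm.sf(abs(bbar) / se_p),
    )
    return MetaResult(pooled, Q, df, I2, p_het, tuple(estimates))


# --------------------------------------------------------------------------
# interactions and family history

def interaction_test(
    cohort: pd.DataFrame,
    modifier: str,
    prs_col: str = "prs_std",
    covariates: Sequence[str] = DEFAULT_PCS,
    stratum_col: str | None = "stratum",
) -> EstimateCI:
    """Wald test of a PRS x modifier product term in the logistic model."""
    mod = pd.to_numeric(cohort[modifier], errors="raise")
    if mod.nunique() < 2:
        raise AssociationError(f"modifier {modifier!r} is constant")
    y = cohort["status"].to_numpy(int)
    X = _design(cohort, [prs_col, modifier, *covariates], stratum_col)
    X["prs_x_mod"] = X[prs_col] * X[modifier]
    res = _fit_logit(y, X)
    return _wald_ci(res, "prs_x_mod", "log-odds",
                    n_cases=int(y.sum()), n_controls=int((1 - y).sum()))


def attenuation_percent(or_unadjusted: float, or_adjusted: float) -> float:
    """Log-scale percentage attenuation between two odds ratios.

    100 * (ln OR_unadj - ln OR_adj) / ln OR_unadj; undefined (raises) when
    the unadjusted OR does not exceed 1.
    """
    if or_unadjusted <= 1.0:
        raise AssociationError(
            "attenuation undefined: unadjusted OR must exceed 1")
    return 100.0 * (math.log(or_unadjusted) - math.log(or_adjusted)) \
        / math.log(or_unadjusted)


@dataclass(frozen=True)
class FHAttenuation:
    or_unadjusted: EstimateCI
    or_adjusted: EstimateCI
    attenuation_pct: float
    defined: bool


def fh_attenuation(
    cohort: pd.DataFrame,
    prs_col: str = "prs_std",
    fh_col: str = "family_history",
    covariates: Sequence[str] = DEFAULT_PCS,
    stratum_col: str | None = "stratum",
) -> FHAttenuation:
    """Family-history OR before and after conditioning on the PRS.

    Rows with missing family history are excluded.  The attenuation
    percentage is on the log scale; when the unadjusted OR is <= 1 the
    percentage is undefined and flagged (``defined=False``, NaN value).
    """
    sub = cohort[cohort[fh_col].notna()].copy()
    sub[fh_col] = sub[fh_col].astype(int)
    y = sub["status"].to_numpy(int)
    X_u = _design(sub, [fh_col, *covariates], stratum_col)
    or_u = _wald_ci(_fit_logit(y, X_u), fh_col, "log-odds")
    X_a = _design(sub, [fh_col, prs_col, *covariates], stratum_col)
    or_a = _wald_ci(_fit_logit(y, X_a), fh_col, "log-odds")
    if or_u.point <= 1.0:
        return FHAttenuation(or_u, or_a, float("nan"), False)
    return FHAttenuation(or_u, or_a,
                         attenuation_percent(or_u.point, or_a.point), True)


def rescale_or(or_value: float, sd_from: float, sd_to: float) -> float:
    """Re-express an OR per ``sd_from`` PRS units as an OR per ``sd_to``.

    exp(ln(OR) * sd_to / sd_from); e.g. OR 1.52 per European-control SD
    0.597 becomes 1.48 per Asian-control SD 0.556.
    """
    if or_value <= 0 or sd_from <= 0 or sd_to <= 0:
        raise AssociationError("OR and SDs must be positive")
    return math.exp(math.log(or_value) * sd_to / sd_from)
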