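"""Absolute risk by PRS percentile group, with competing mortality.

Converts percentile-group relative risks into age-specific absolute risks
constrained to reproduce the population incidence.  On a discrete one-year
age grid with annual hazards,

    AR_g(t) = sum_u lambda_g(u) * S_g(u) * S_m(u),

where lambda_g(u) is the calibrated group hazard, S_g(u) the probability of
remaining breast-cancer free, and S_m(u) the probability of not having died
of a competing (non-breast-cancer) cause.  The calibration requires that
the survivor-weighted average of the group hazards equals the population
incidence at every age:

    lambda*(u) = lambda_pop(u) * sum_g f_g S_g(u) / sum_g f_g S_g(u) r_g,
    lambda_g(u) = r_g * lambda*(u),

evaluated as a forward age recursion (which satisfies the constraint
exactly, so no fixed-point iteration is needed on a discrete grid).
Odds ratios are treated as relative risks, valid while annual risks are
small.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm


class AbsoluteRiskError(ValueError):
    pass


@dataclass(frozen=True)
class RatesTable:
    """Population incidence and competing mortality on an integer age grid.

    Rates are per person-year.  The competing-mortality column must already
    exclude deaths from the disease itself.
    """

    ages: np.ndarray
    incidence: np.ndarray
    competing_mortality: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, int)
        inc = np.asarray(self.incidence, float)
        mort = np.asarray(self.competing_mortality, float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "incidence", inc)
        object.__setattr__(self, "competing_mortality", mort)
        if not (len(ages) == len(inc) == len(mort)):
            raise AbsoluteRiskError("column lengths differ")
        if len(ages) == 0 or (np.diff(ages) != 1).any():
            raise AbsoluteRiskError("age grid must be contiguous integers")
        if (inc < 0).any() or (mort < 0).any():
            raise AbsoluteRiskError("rates must be non-negative")
        if (inc >= 1).any() or (mort >= 1).any():
            raise AbsoluteRiskError("annual rates must be below 1")

    @classmethod
    def from_csv(cls, path: str | Path, per_100k: bool = False) -> "RatesTable":
        """Read a CSV with columns age, incidence, competing_mortality.

        ``per_100k=True`` converts rates given per 100,000 person-years.
        """
        df = pd.read_csv(path)
        need = {"age", "incidence", "competing_mortality"}
        if not need.issubset(df.columns):
            raise AbsoluteRiskError(f"{path}: expected columns {sorted(need)}")
        scale = 1e-5 if per_100k else 1.0
        return cls(df["age"].to_numpy(int),
                   df["incidence"].to_numpy(float) * scale,
                   df["competing_mortality"].to_numpy(float) * scale)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "incidence": self.incidence,
                      "competing_mortality": self.competing_mortality}
                     ).to_csv(path, index=False)

    def index_of(self, age: int) -> int:
        if age < self.ages[0] or age > self.ages[-1]:
            raise AbsoluteRiskError(f"age {age} outside grid "
                                    f"[{self.ages[0]}, {self.ages[-1]}]")
        return int(age - self.ages[0])


@dataclass(frozen=True)
class RiskGroupSet:
    """Population fractions and relative risks of PRS percentile groups."""

    fractions: np.ndarray
    relative_risks: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, float)
        r = np.asarray(self.relative_risks, float)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "relative_risks", r)
        if len(f) != len(r):
            raise AbsoluteRiskError("fractions/relative_risks length mismatch")
        if not np.isclose(f.sum(), 1.0, atol=1e-8):
            raise AbsoluteRiskError("group fractions must sum to 1")
        if (f <= 0).any() or (r <= 0).any():
            raise AbsoluteRiskError("fractions and relative risks must be > 0")
        if not self.labels:
            object.__setattr__(self, "labels",
                               tuple(f"g{i}" for i in range(len(f))))

    @classmethod
    def from_scheme(cls, scheme, gamma: float) -> "RiskGroupSet":
        """Normal-shift relative risks for control-percentile bins.

        For bin [a, b] of the standard-normal control distribution the mean
        relative risk, normalised to population mean 1, is
        (Phi(qb - gamma) - Phi(qa - gamma)) / (Phi(qb) - Phi(qa)).
        """
        b = np.asarray(scheme.boundaries, float)
        q = norm.ppf(b)
        f = np.diff(b)
        r = np.diff(norm.cdf(q - gamma)) / f
        return cls(f, r, tuple(scheme.labels))


@dataclass(frozen=True)
class GroupRiskCurve:
    """Calibrated per-group hazards and survival curves on the age grid."""

    ages: np.ndarray              # (A,)
    hazards: np.ndarray           # (G, A) lambda_g(u)
    surv_disease: np.ndarray      # (G, A) S_g(u), = 1 at the first age
    surv_mortality: np.ndarray    # (A,) S_m(u)
    groups: RiskGroupSet
    population_incidence: np.ndarray  # (A,)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, lab in enumerate(self.groups.labels):
            rows.append(pd.DataFrame({
                "group": lab, "age": self.ages,
                "hazard": self.hazards[gi],
                "surv_disease": self.surv_disease[gi],
                "surv_mortality": self.surv_mortality,
            }))
        return pd.concat(rows, ignore_index=True)


def calibrate_group_hazards(rates: RatesTable, groups: RiskGroupSet
                            ) -> GroupRiskCurve:
    """Group hazards whose survivor-weighted mean is the population incidence.

    Forward age recursion: at each age the baseline hazard is the
    population incidence divided by the survivor-weighted mean relative
    risk; group hazards are r_g times the baseline; disease-free survival
    updates multiplicatively.
    """
    f = groups.fractions
    r = groups.relative_risks
    A = len(rates.ages)
    G = len(f)
    haz = np.empty((G, A))
    surv = np.empty((G, A))
    sm = np.empty(A)
    s = np.ones(G)
    smv = 1.0
    for u in range(A):
        surv[:, u] = s
        sm[u] = smv
        lam_pop = rates.incidence[u]
        base = lam_pop * np.sum(f * s) / np.sum(f * s * r)
        lam = r * base
        if (lam >= 1).any():
            raise AbsoluteRiskError(
                f"group hazard >= 1 at age {rates.ages[u]}; relative risks "
                "too extreme for an annual grid")
        haz[:, u] = lam
        s = s * (1 - lam)
        smv = smv * (1 - rates.competing_mortality[u])
    return GroupRiskCurve(rates.ages.copy(), haz, surv, sm, groups,
                          rates.incidence.copy())


def cumulative_risk(curve: GroupRiskCurve, from_age: int, to_age: int
                    ) -> np.ndarray:
    """Absolute risk per group over [from_age, to_age).

    Survival factors are renormalised to 1 at ``from_age`` (risk conditional
    on being alive and disease-free then).
    """
    if from_age >= to_age:
        raise AbsoluteRiskError("from_age must be below to_age")
    i0 = int(from_age - curve.ages[0])
    i1 = int(to_age - curve.ages[0])
    if i0 < 0 or i1 > len(curve.ages):
        raise AbsoluteRiskError("requested ages outside the grid")
    lam = curve.hazards[:, i0:i1]
    sg = curve.surv_disease[:, i0:i1] / curve.surv_disease[:, i0:i0 + 1]
    sm = curve.surv_mortality[i0:i1] / curve.surv_mortality[i0]
    return np.sum(lam * sg * sm[None, :], axis=1)


def ten_year_risk(curve: GroupRiskCurve, age: int) -> np.ndarray:
    """10-year absolute risk per group, conditional on being risk-free at ``age``."""
    return cumulative_risk(curve, age, age + 10)


NEVER = "NR"


def age_at_threshold(curve: GroupRiskCurve, threshold: float = 0.023,
                     age_range: tuple[int, int] = (20, 70)):
    """First age at which the 10-year risk reaches ``threshold``, per group.

    Returns a list with an integer age or :data:`NEVER` per group.  The
    default threshold 2.3% is the approximate 10-year risk at age 50 for
    women of European ancestry; the default scan covers ages 20-70.
    """
    if not 0.0 < threshold < 1.0:
        raise AbsoluteRiskError("threshold must lie in (0, 1)")
    lo, hi = age_range
    if lo > hi:
        raise AbsoluteRiskError("empty age range")
    lo = max(lo, int(curve.ages[0]))
    hi = min(hi, int(curve.ages[-1]) - 10)
    if lo > hi:
        raise AbsoluteRiskError("age range incompatible with the rate grid")
    G = curve.hazards.shape[0]
    out = [NEVER] * G
    for age in range(lo, hi + 1):
        risks = ten_year_risk(curve, age)
        for g in range(G):
            if out[g] == NEVER and risks[g] >= threshold:
                out[g] = age
    return out


def screening_eligibility(
    model,
    rates: RatesTable,
    threshold: float = 0.023,
    centile_width: float = 0.1,
    age_range: tuple[int, int] = (20, 70),
):
    """Population fraction above a 10-year risk threshold, and cases captured.

    Builds a PRS centile grid (default 0.1%-wide bins), assigns each centile
    its normal-shift relative risk under ``model`` (a
    :class:`~prs_transfer.theory.PolygenicModel`), calibrates hazards to the
    population rates, and flags a centile as screening-eligible if its
    maximum 10-year absolute risk over ``age_range`` reaches ``threshold``.
    The captured-case fraction weights each centile by its share of the
    calibrated incidence (lambda_g S_g S_m summed over the grid).

    Returns ``(fraction_of_population, fraction_of_cases_captured, table)``.
    """
    n = round(100.0 / centile_width)
    if abs(n * centile_width - 100.0) > 1e-9 or n < 1:
        raise AbsoluteRiskError("centile_width must divide 100%")
    edges = np.linspace(0.0, 1.0, n + 1)
    q = norm.ppf(edges)
    f = np.diff(edges)
    r = np.diff(norm.cdf(q - model.gamma)) / f
    groups = RiskGroupSet(f, r)
    curve = calibrate_group_hazards(rates, groups)

    lo = max(age_range[0], int(rates.ages[0]))
    hi = min(age_range[1], int(rates.ages[-1]) - 10)
    if lo > hi:
        raise AbsoluteRiskError("age range incompatible with the rate grid")
    max_risk = np.zeros(n)
    for age in range(lo, hi + 1):
        max_risk = np.maximum(max_risk, ten_year_risk(curve, age))
    eligible = max_risk >= threshold

    case_mass = np.sum(curve.hazards * curve.surv_disease
                       * curve.surv_mortality[None, :], axis=1) * f
    frac_pop = float(f[eligible].sum())
    frac_cases = float(case_mass[eligible].sum() / case_mass.sum())
    table = pd.DataFrame({
        "centile_low": edges[:-1] * 100, "centile_high": edges[1:] * 100,
        "relative_risk": r, "max_10yr_risk": max_risk, "eligible": eligible,
    })
    return frac_pop, frac_cases, table
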