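"""Closed-form consequences of the multiplicative polygenic model.

If the log disease odds are linear in a normally distributed PRS, then with
the PRS expressed in control-SD units (Z ~ N(0,1) among controls) and gamma
the log odds ratio per control SD:

* cases are distributed N(gamma, 1) under the rare-disease approximation
  (normal-shift model);
* the familial relative risk to first-degree relatives attributable to the
  PRS alone is lambda_P = exp(gamma^2 / 2), and the fraction of an assumed
  familial relative risk lambda explained is gamma^2 / (2 ln lambda);
* the OR for a percentile bin [a, b] of the control distribution versus a
  reference bin [c, d] is the ratio of case-to-control mass ratios, with
  bin edges at standard-normal quantiles;
* the AUC of the PRS is Phi(gamma / sqrt(2)).

Note: gamma enters these formulas as a LOG odds ratio.  The corresponding
published estimates are quoted as ORs per SD; convert with
:meth:`PolygenicModel.from_or_per_sd`, which also moves the effect from the
reference-population SD scale to the analysed population's control-SD scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .association import PercentileBinScheme


class TheoryError(ValueError):
    pass


@dataclass(frozen=True)
class PolygenicModel:
    """Log-linear PRS model: log OR ``gamma`` per control SD of the PRS."""

    gamma: float
    control_sd: float = 1.0
    reference_sd: float = 1.0
    prevalence: float = 0.05

    def __post_init__(self) -> None:
        if not (self.control_sd > 0 and self.reference_sd > 0):
            raise TheoryError("SDs must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise TheoryError("prevalence must lie in (0, 1)")

    @classmethod
    def from_or_per_sd(cls, or_per_sd: float, reference_sd: float = 1.0,
                       control_sd: float = 1.0, prevalence: float = 0.05
                       ) -> "PolygenicModel":
        """Model from an OR per reference-SD unit.

        The log OR per *analysed-population* control SD is
        ln(OR) * control_sd / reference_sd (e.g. ln(1.52) * 0.556/0.597).
        """
        if or_per_sd <= 0:
            raise TheoryError("OR must be positive")
        gamma = math.log(or_per_sd) * control_sd / reference_sd
        return cls(gamma=gamma, control_sd=control_sd,
                   reference_sd=reference_sd, prevalence=prevalence)


@dataclass(frozen=True)
class FRRResult:
    lambda_p: float
    fraction_explained: float
    lambda_fam: float


def lambda_p(model: PolygenicModel) -> float:
    """Familial relative risk due to the PRS alone: exp(gamma^2 / 2)."""
    return math.exp(model.gamma**2 / 2.0)


def frr_explained(model: PolygenicModel, lambda_fam: float = 2.0) -> FRRResult:
    """Fraction of the familial relative risk explained by the PRS.

    ln(lambda_P) / ln(lambda) = gamma^2 / (2 ln lambda), with lambda the
    assumed familial relative risk to first-degree relatives (2 for breast
    cancer).
    """
    if lambda_fam <= 1.0:
        raise TheoryError("lambda_fam must exceed 1")
    lp = lambda_p(model)
    return FRRResult(lp, model.gamma**2 / (2.0 * math.log(lambda_fam)),
                     lambda_fam)


def predicted_bin_or(
    model: PolygenicModel,
    scheme: PercentileBinScheme = PercentileBinScheme(),
    exact_prevalence: bool = False,
) -> np.ndarray:
    """Predicted OR per control-percentile bin versus the reference bin.

    Default (rare-disease normal-shift approximation): cases ~ N(gamma, 1),
    controls ~ N(0, 1), bin edges at standard-normal quantiles of the
    scheme boundaries; OR of bin [a,b] vs reference [c,d] is

        {[Phi(b-g) - Phi(a-g)] / [Phi(b) - Phi(a)]}
      / {[Phi(d-g) - Phi(c-g)] / [Phi(d) - Phi(c)]}.

    With ``exact_prevalence=True`` the case/control densities and the
    control quantiles are computed by numerical integration under the
    logistic model at the model's finite prevalence instead.
    """
    g = model.gamma
    bounds = np.asarray(scheme.boundaries, float)
    if not exact_prevalence:
        q = norm.ppf(bounds)
        case_mass = np.diff(norm.cdf(q - g))
        control_mass = np.diff(bounds)
    else:
        case_mass, control_mass = _finite_prevalence_masses(model, bounds)
    ratio = case_mass / control_mass
    ref = scheme.reference_index
    if control_mass[ref] <= 0:
        raise TheoryError("degenerate reference bin")
    return ratio / ratio[ref]


def _finite_prevalence_masses(model: PolygenicModel, bounds: np.ndarray):
    """Case/control bin masses under the logistic model at finite prevalence."""
    z = np.linspace(-8.5, 8.5, 20001)
    phi = norm.pdf(z)
    # intercept such that the marginal prevalence matches
    from scipy.optimize import brentq
    K = model.prevalence

    def marg(a):
        return np.trapezoid(phi * expit(a + model.gamma * z), z) - K

    a = brentq(marg, -40, 40)
    p = expit(a + model.gamma * z)
    f_case = phi * p / K
    f_ctrl = phi * (1 - p) / (1 - K)
    Fc = np.concatenate([[0.0], np.cumsum((f_ctrl[1:] + f_ctrl[:-1]) / 2 * np.diff(z))])
    Fc /= Fc[-1]
    Fa = np.concatenate([[0.0], np.cumsum((f_case[1:] + f_case[:-1]) / 2 * np.diff(z))])
    Fa /= Fa[-1]
    # control quantiles of the boundary fractions
    qz = np.interp(bounds, Fc, z)
    case_mass = np.diff(np.interp(qz, z, Fa))
    control_mass = np.diff(bounds)
    return case_mass, control_mass


def theoretical_auc(model: PolygenicModel) -> float:
    """AUC of the PRS under the normal-shift model: Phi(gamma / sqrt 2)."""
    return float(norm.cdf(model.gamma / math.sqrt(2.0)))
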