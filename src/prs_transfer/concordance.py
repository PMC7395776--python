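"""Cross-population concordance of per-SNP effect sizes.

Per-SNP log odds ratios are estimated separately in each population; the
concordance of the underlying true effects is then summarised by an
intraclass correlation coefficient (ICC) that accounts for the known
sampling error of each estimate, via the hierarchical measurement-error
model

    y_ij = beta_ij + delta_ij,      delta_ij ~ N(0, sigma_ij^2) known,
    beta_ij ~ N(alpha_i, sigma_R^2),

fitted by expectation-maximisation.  In the E-step each estimate is shrunk
toward its SNP mean with precision weights,

    beta_hat_ij = (alpha_i / sigma_R^2 + y_ij / sigma_ij^2)
                / (1 / sigma_R^2 + 1 / sigma_ij^2),

and the M-step updates the variance components.  The SNP means alpha_i are
modelled as mu + a_i with a_i ~ N(0, sigma_A^2), the between-SNP variance:
treating them as free per-SNP parameters would leave their sampling noise
in the between-SNP variance (so the ICC could never approach 0) and, with
only a handful of populations per SNP, would make the residual-variance
MLE inconsistent (a Neyman-Scott problem that drives sigma_R^2 to the zero
boundary whenever the known noise exceeds half the within-SNP spread).
The E-step must also propagate posterior variances into the M-step; the
plug-in variant that treats the shrunken values as exact complete data
contracts both variances every iteration and collapses toward zero.  It is
kept behind ``m_step="plugin"`` only to document that behaviour.

ICC = sigma_A^2 / (sigma_A^2 + sigma_R^2): the fraction of true effect-size
variance that is shared across populations rather than population-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class ConcordanceError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSizePanel:
    """Rectangular SNP x population grid of estimates and standard errors.

    Missing entries (e.g. a SNP monomorphic in one population) are NaN in
    both arrays and handled pairwise-complete.
    """

    snp_ids: np.ndarray          # (n,)
    populations: np.ndarray      # (J,)
    estimates: np.ndarray        # (n, J) log odds ratios
    standard_errors: np.ndarray  # (n, J) known sampling SDs

    def __post_init__(self) -> None:
        y = np.asarray(self.estimates, float)
        s = np.asarray(self.standard_errors, float)
        object.__setattr__(self, "estimates", y)
        object.__setattr__(self, "standard_errors", s)
        object.__setattr__(self, "snp_ids", np.asarray(self.snp_ids))
        object.__setattr__(self, "populations", np.asarray(self.populations))
        if y.shape != s.shape or y.shape != (len(self.snp_ids), len(self.populations)):
            raise ConcordanceError("estimate/SE grids must be SNP x population")
        obs = ~np.isnan(y)
        if (obs != ~np.isnan(s)).any():
            raise ConcordanceError("estimates and SEs must share missingness")
        if np.nanmin(s, initial=np.inf) <= 0:
            raise ConcordanceError("standard errors must be positive")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EffectSizePanel":
        """Long-format TSV with columns snp, population, beta, se."""
        df = pd.read_csv(path, sep="\t")
        wide_b = df.pivot(index="snp", columns="population", values="beta")
        wide_s = df.pivot(index="snp", columns="population", values="se")
        return cls(wide_b.index.to_numpy(), wide_b.columns.to_numpy(),
                   wide_b.to_numpy(float), wide_s.to_numpy(float))

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for i, snp in enumerate(self.snp_ids):
            for j, pop in enumerate(self.populations):
                if not np.isnan(self.estimates[i, j]):
                    rows.append((snp, pop, self.estimates[i, j],
                                 self.standard_errors[i, j]))
        pd.DataFrame(rows, columns=["snp", "population", "beta", "se"]
                     ).to_csv(path, sep="\t", index=False)

    def subset_populations(self, populations: Sequence[str]) -> "EffectSizePanel":
        idx = [list(self.populations).index(p) for p in populations]
        return EffectSizePanel(self.snp_ids, self.populations[idx],
                               self.estimates[:, idx],
                               self.standard_errors[:, idx])


@dataclass(frozen=True)
class ICCFit:
    alpha: np.ndarray        # (n,) fitted per-SNP means
    beta_hat: np.ndarray     # (n, J) shrunken estimates
    sigma2_R: float          # within-SNP (residual) variance
    sigma2_A: float          # noise-corrected between-SNP variance
    icc: float
    n_iterations: int
    converged: bool


def fit_per_snp_effects(
    cohort: pd.DataFrame,
    dosages,
    panel,
    covariates: Sequence[str] = ("age", "pc1", "pc2", "pc3", "pc4", "pc5",
                                 "pc6", "pc7", "pc8", "pc9", "pc10"),
    stratum_col: str | None = "stratum",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP log-OR and SE from one logistic fit per variant.

    Each SNP's effect-allele dosage enters a log-additive logistic model of
    case status with the given covariates and stratum indicators.  SNPs
    monomorphic in the cohort are returned as NaN.
    """
    from .association import _design, _fit_logit, AssociationError

    y = cohort["status"].to_numpy(int)
    base = _design(cohort, list(covariates), stratum_col)
    col_of = dosages.column_index()
    n = len(panel)
    betas = np.full(n, np.nan)
    ses = np.full(n, np.nan)
    for i, vid in enumerate(panel.variant_ids):
        x = dosages.values[:, col_of[vid]]
        if np.std(x) == 0:
            continue
        X = base.copy()
        X["snp"] = x
        try:
            res = _fit_logit(y, X)
        except AssociationError:
            continue
        j = res.exog_names_.index("snp")
        betas[i], ses[i] = res.params[j], res.bse[j]
    return betas, ses


def em_icc(
    panel: EffectSizePanel,
    tol: float = 1e-8,
    max_iter: int = 1000,
    m_step: str = "full",
) -> ICCFit:
    """EM fit of the hierarchical measurement-error model and its ICC.

    Variance components: per-SNP shared effects alpha_i = mu + a_i with
    a_i ~ N(0, sigma_A^2), population-specific deviations
    b_ij ~ N(0, sigma_R^2), and known sampling noise sigma_ij.  The E-step
    computes posterior means of a_i and b_ij — each shrunken estimate
    beta_hat_ij is the precision-weighted mean of y_ij and the SNP mean
    alpha_i, with weights 1/sigma_ij^2 and 1/sigma_R^2 — and the M-step
    updates (mu, sigma_A^2, sigma_R^2) from the posterior moments.
    Iterates until the ICC changes by less than ``tol`` (or ``max_iter``,
    returned with ``converged=False``; near a variance boundary the
    approach is asymptotic and slow, which is harmless for the ICC).

    ``m_step="plugin"`` drops the posterior-variance terms (treating the
    shrunken values as exact complete data); it is degenerate — the
    variances contract every iteration and collapse toward zero — and is
    retained only to document that behaviour.
    """
    if m_step not in ("full", "plugin"):
        raise ConcordanceError("m_step must be 'full' or 'plugin'")
    y = panel.estimates
    s2 = panel.standard_errors**2
    n, J = y.shape
    if J < 2:
        raise ConcordanceError("need at least two populations")
    if n < 3:
        raise ConcordanceError("need at least three SNPs")
    obs = ~np.isnan(y)
    if (obs.sum(axis=1) < 1).any():
        raise ConcordanceError("each SNP needs at least one observation")
    n_j = obs.sum(axis=1)
    n_obs = int(obs.sum())

    # standardise internally so the iteration is exactly scale-equivariant
    c2 = float(np.var(y[obs]))
    c = math.sqrt(c2) if c2 > 0 else 1.0
    y = y / c
    s2 = s2 / (c * c)

    y0 = np.where(obs, y, 0.0)
    s2f = np.where(obs, s2, 1.0)  # placeholder on missing; masked below

    # moment initialisation
    w0 = np.where(obs, 1.0 / s2f, 0.0)
    mu = float(np.sum(w0 * y0) / np.sum(w0))
    snp_means = np.sum(np.where(obs, y0, 0.0), axis=1) / n_j
    sigma2_a = max(float(np.var(snp_means, ddof=1))
                   - float(np.mean(s2[obs])) / J, 1e-4)
    sigma2_r = max(float(np.mean((y0 - snp_means[:, None])[obs] ** 2))
                   - float(np.mean(s2[obs])), 1e-4)

    icc_prev, icc = np.inf, 0.0
    converged = False
    it = 0
    alpha = snp_means
    beta_hat = y0.copy()
    for it in range(1, max_iter + 1):
        d = sigma2_r + s2f                      # var(y | a_i)
        wd = np.where(obs, 1.0 / d, 0.0)
        prec_a = 1.0 / sigma2_a + wd.sum(axis=1)
        m_a = np.sum(wd * (y0 - mu), axis=1) / prec_a
        v_a = 1.0 / prec_a
        alpha = mu + m_a
        shrink = np.where(obs, sigma2_r / d, 0.0)
        e_b = shrink * (y0 - alpha[:, None])
        var_b = (np.where(obs, sigma2_r * s2f / d, 0.0)
                 + shrink**2 * v_a[:, None])
        beta_hat = np.where(obs, alpha[:, None] + e_b, alpha[:, None])

        # M-step
        resid = np.where(obs, y0 - m_a[:, None] - e_b, 0.0)
        mu = float(np.sum(np.where(obs, resid / s2f, 0.0))
                   / np.sum(np.where(obs, 1.0 / s2f, 0.0)))
        if m_step == "full":
            sigma2_a = float(np.mean(m_a**2 + v_a))
            sigma2_r = float(np.sum(np.where(obs, e_b**2 + var_b, 0.0)) / n_obs)
        else:
            sigma2_a = float(np.mean(m_a**2))
            sigma2_r = float(np.sum(np.where(obs, e_b**2, 0.0)) / n_obs)
        sigma2_a = max(sigma2_a, 1e-300)
        sigma2_r = max(sigma2_r, 1e-300)
        total = sigma2_a + sigma2_r
        icc = sigma2_a / total if total > 1e-250 else 0.0
        if abs(icc - icc_prev) < tol:
            converged = True
            break
        icc_prev = icc

    return ICCFit(alpha=alpha * c, beta_hat=beta_hat * c,
                  sigma2_R=sigma2_r * c2, sigma2_A=sigma2_a * c2,
                  icc=float(np.clip(icc, 0.0, 1.0)),
                  n_iterations=it, converged=converged)
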