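"""PRS computation and standardisation.

The score for individual *i* is the weighted allele count

    PRS_i = sum_k beta_k * x_ik,

with ``x_ik`` the dosage (0-2) of the effect allele of SNP *k* and ``beta_k``
its per-allele log odds ratio.  Dosage files may count either allele of a
variant; columns whose counted allele is the panel's *other* allele are
flipped (``x -> 2 - x``) before the weighted sum.

Scores are standardised by dividing by a reference SD (conventionally the
PRS SD among controls of a reference population), with no mean-centering, so
that effect sizes read as odds ratios per reference-control SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosages import DosageMatrix
from .weights import WeightPanel


class ScoringError(ValueError):
    """Variant resolution or allele-orientation failure."""


@dataclass(frozen=True)
class StandardizedPRS:
    """Raw and standardised scores plus the standardisation metadata."""

    raw: np.ndarray
    reference_sd: float
    weight_set: str = "overall"

    def __post_init__(self) -> None:
        if not self.reference_sd > 0:
            raise ScoringError("reference SD must be positive")

    @property
    def values(self) -> np.ndarray:
        return self.raw / self.reference_sd


def compute_prs(
    dosages: DosageMatrix,
    panel: WeightPanel,
    weight_set: str = "overall",
    strict_palindromic: bool = False,
) -> np.ndarray:
    """Raw PRS per individual (weighted sum of effect-allele dosages).

    Every panel variant must resolve, by id, to a dosage column; a column
    whose counted allele is the panel's other allele is flipped.  Variants
    are matched by id first and alleles second, so palindromic (A/T, C/G)
    variants are accepted on the id match unless ``strict_palindromic``.
    """
    col_of = dosages.column_index()
    missing = [v for v in panel.variant_ids if v not in col_of]
    if missing:
        raise ScoringError(f"variants absent from dosages: {missing[:5]}"
                           f" ({len(missing)} total)")
    idx = np.array([col_of[v] for v in panel.variant_ids])
    counted = np.char.upper(dosages.counted_allele[idx].astype(str))
    d_other = np.char.upper(dosages.other_allele[idx].astype(str))
    eff = panel.table["effect_allele"].to_numpy(str)
    oth = panel.table["other_allele"].to_numpy(str)

    direct = counted == eff
    flipped = counted == oth
    bad = ~(direct | flipped)
    if bad.any():
        ids = panel.variant_ids[bad][:5]
        raise ScoringError(f"allele mismatch (neither orientation) for {list(ids)}")
    if strict_palindromic:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        pal = np.array([comp.get(a) == b for a, b in zip(eff, oth)])
        # id matched but the allele pair disagrees with the panel's pair
        pair_mismatch = (direct & (d_other != oth)) | (flipped & (d_other != eff))
        if (pal & pair_mismatch).any():
            ids = panel.variant_ids[pal & pair_mismatch][:5]
            raise ScoringError(f"palindromic allele-pair mismatch for {list(ids)}")

    x = dosages.values[:, idx]
    if np.isnan(x).any():
        raise ScoringError("missing dosages for resolvable variants")
    x = np.where(flipped[None, :], 2.0 - x, x)
    beta = panel.weights(weight_set)
    return x @ beta


def standardize(
    raw: np.ndarray, reference_sd: float, weight_set: str = "overall"
) -> StandardizedPRS:
    """Divide raw scores by a reference-control SD (no mean-centering)."""
    return StandardizedPRS(np.asarray(raw, float), float(reference_sd), weight_set)


def summarize_prs(prs: np.ndarray, grouping) -> pd.DataFrame:
    """n, mean and SD (n-1 denominator) of the PRS per group.

    ``grouping`` is an array-like of group labels aligned with ``prs``.
    Groups of size one cannot yield an SD and raise.
    """
    df = pd.DataFrame({"prs": np.asarray(prs, float), "group": np.asarray(grouping)})
    if df.empty:
        raise ValueError("empty input")
    sizes = df.groupby("group", sort=False)["prs"].size()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"group(s) of size < 2, SD undefined: {small}")
    out = df.groupby("group", sort=False)["prs"].agg(
        n="size", mean="mean", sd=lambda s: s.std(ddof=1)
    )
    return out.reset_index()
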