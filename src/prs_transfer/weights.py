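"""SNP weight panels for polygenic risk scoring.

A weight panel is the per-variant table behind a PRS: variant identifiers,
effect/other alleles, per-allele log-odds weights for overall and
oestrogen-receptor (ER) subtype-specific disease, an imputation-quality
(INFO) score, and allele frequencies in each population of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: mandatory columns of a scoring file, in canonical order
WEIGHT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "weight_overall",
    "weight_erpos",
    "weight_erneg",
    "info",
    "freq_pop1",
    "freq_pop2",
]

#: weight-set tag -> column holding the per-allele log-odds weight
WEIGHT_SETS = {
    "overall": "weight_overall",
    "er_positive": "weight_erpos",
    "er_negative": "weight_erneg",
}


class WeightPanelError(ValueError):
    """Malformed or inconsistent weight panel."""


@dataclass(frozen=True)
class WeightPanel:
    """Immutable wrapper around a validated weight table.

    The underlying table always carries :data:`WEIGHT_COLUMNS`; rows are
    unique by ``variant_id`` and alleles are upper-case single strings.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in WEIGHT_COLUMNS if c not in t.columns]
        if missing:
            raise WeightPanelError(f"weight panel missing columns: {missing}")
        dup = t["variant_id"][t["variant_id"].duplicated()]
        if len(dup):
            raise WeightPanelError(
                f"duplicated variant_id(s): {sorted(set(dup))[:5]}"
            )
        same = t["effect_allele"] == t["other_allele"]
        if same.any():
            bad = t.loc[same, "variant_id"].tolist()[:5]
            raise WeightPanelError(f"effect_allele == other_allele for {bad}")
        for col in ("weight_overall", "weight_erpos", "weight_erneg"):
            if not np.isfinite(t[col].to_numpy(float)).all():
                raise WeightPanelError(f"non-finite values in {col}")
        info = t["info"].to_numpy(float)
        if ((info < 0) | (info > 1)).any():
            raise WeightPanelError("info scores must lie in [0, 1]")
        for col in ("freq_pop1", "freq_pop2"):
            f = t[col].to_numpy(float)
            if ((f < 0) | (f > 1)).any():
                raise WeightPanelError(f"{col} must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["variant_id"].to_numpy()

    def weights(self, weight_set: str = "overall") -> np.ndarray:
        """Per-allele log-odds weights for one weight set."""
        try:
            col = WEIGHT_SETS[weight_set]
        except KeyError:
            raise WeightPanelError(
                f"unknown weight set {weight_set!r}; expected one of {list(WEIGHT_SETS)}"
            ) from None
        return self.table[col].to_numpy(float)

    # ------------------------------------------------------------------ io

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WeightPanel":
        """Read a tab-separated scoring file (see :data:`WEIGHT_COLUMNS`)."""
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
        missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
        if missing:
            raise WeightPanelError(
                f"{path}: missing mandatory column(s) {missing}"
            )
        for col in ("weight_overall", "weight_erpos", "weight_erneg", "info",
                    "freq_pop1", "freq_pop2"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.loc[vals.isna() & df[col].notna(), "variant_id"]
            if len(bad):
                raise WeightPanelError(
                    f"{path}: non-numeric {col} for {bad.tolist()[:5]}"
                )
            df[col] = vals.astype(float)
        df["effect_allele"] = df["effect_allele"].str.upper()
        df["other_allele"] = df["other_allele"].str.upper()
        return cls(df[WEIGHT_COLUMNS].reset_index(drop=True))

    def to_tsv(self, path: str | Path) -> None:
        self.table[WEIGHT_COLUMNS].to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )

    # ------------------------------------------------------- panel algebra

    def filter_by_info(self, threshold: float) -> "WeightPanel":
        """Drop variants with imputation INFO score below ``threshold``.

        Retains exactly the variants with ``info >= threshold``; input order
        is preserved.  An empty result is legal.
        """
        if not 0.0 <= threshold <= 1.0:
            raise WeightPanelError("INFO threshold must lie in [0, 1]")
        keep = self.table["info"].to_numpy(float) >= threshold
        return WeightPanel(self.table.loc[keep].reset_index(drop=True))

    def restrict_to(self, variant_ids) -> "WeightPanel":
        """Keep only panel variants present in ``variant_ids``.

        Used to shrink a panel to the variants a dosage source actually
        carries (e.g. 287 -> 229 when 58 SNPs could not be imputed).
        Weights are deliberately NOT renormalised for the missing variants.
        """
        avail = set(map(str, variant_ids))
        keep = self.table["variant_id"].isin(avail).to_numpy()
        if not keep.any():
            raise WeightPanelError(
                "no panel variant is present in the dosage source"
            )
        return WeightPanel(self.table.loc[keep].reset_index(drop=True))


def filter_by_info(panel: WeightPanel, threshold: float) -> WeightPanel:
    """Functional alias for :meth:`WeightPanel.filter_by_info`."""
    return panel.filter_by_info(threshold)


def restrict_to_available(panel: WeightPanel, dosages) -> WeightPanel:
    """Restrict ``panel`` to variants present and polymorphic in ``dosages``.

    ``dosages`` is a :class:`~prs_transfer.dosages.DosageMatrix`; monomorphic
    columns (zero variance across individuals) are treated as unavailable.
    """
    values = np.asarray(dosages.values, float)
    poly = values.std(axis=0) > 0 if values.shape[0] > 1 else np.ones(values.shape[1], bool)
    ids = np.asarray(dosages.variant_ids)[poly]
    return panel.restrict_to(ids)
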