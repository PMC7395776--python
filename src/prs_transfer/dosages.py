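"""Allele-dosage matrices (individuals x variants, values in [0, 2]).

Dosages come either from a plain tab-separated matrix or from a VCF carrying
the imputed dosage in the ``DS`` FORMAT field.  Each column records which
allele was counted (``counted_allele``) and the alternative
(``other_allele``); the scoring code flips orientation where the counted
allele is the weight panel's other allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class DosageError(ValueError):
    """Malformed dosage input."""


@dataclass
class DosageMatrix:
    samples: np.ndarray          # (n,) sample identifiers
    variant_ids: np.ndarray      # (m,) variant identifiers
    counted_allele: np.ndarray   # (m,) allele whose copies `values` counts
    other_allele: np.ndarray     # (m,)
    values: np.ndarray           # (n, m) float dosages in [0, 2]
    chrom: np.ndarray = field(default=None)  # optional (m,)
    pos: np.ndarray = field(default=None)    # optional (m,)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.variant_ids = np.asarray(self.variant_ids)
        self.counted_allele = np.asarray(self.counted_allele)
        self.other_allele = np.asarray(self.other_allele)
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.samples) != n or len(self.variant_ids) != m:
            raise DosageError("dosage matrix shape does not match labels")
        if len(self.counted_allele) != m or len(self.other_allele) != m:
            raise DosageError("allele metadata length does not match variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0) < 0 or np.nanmax(self.values, initial=0) > 2:
                raise DosageError("dosages must lie in [0, 2]")
        if pd.Series(self.variant_ids).duplicated().any():
            raise DosageError("duplicated variant ids in dosage matrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def column_index(self) -> dict:
        return {v: i for i, v in enumerate(self.variant_ids)}

    # ------------------------------------------------------------------ io

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DosageMatrix":
        """Read a dosage TSV: header rows ``variant_id``, ``counted_allele``,
        ``other_allele`` as the first three lines of metadata columns, then
        one row per sample (first column ``sample_id``)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] < 3:
            raise DosageError(f"{path}: expected allele metadata rows")
        try:
            counted = df.loc["counted_allele"].to_numpy(str)
            other = df.loc["other_allele"].to_numpy(str)
        except KeyError as exc:
            raise DosageError(f"{path}: missing metadata row {exc}") from None
        body = df.drop(index=["counted_allele", "other_allele"])
        values = body.to_numpy(float)
        return cls(
            samples=body.index.to_numpy(str),
            variant_ids=df.columns.to_numpy(str),
            counted_allele=counted,
            other_allele=other,
            values=values,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=pd.Index(self.samples, name="sample_id"),
                          columns=self.variant_ids)
        meta = pd.DataFrame(
            [self.counted_allele, self.other_allele],
            index=["counted_allele", "other_allele"],
            columns=self.variant_ids,
        )
        pd.concat([meta, df]).to_csv(path, sep="\t")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "DosageMatrix":
        """Read dosages from the ``DS`` FORMAT field of a VCF.

        Counts copies of ALT (the counted allele).  Requires ``cyvcf2``.
        Multi-allelic records are rejected.
        """
        try:
            from cyvcf2 import VCF
        except ImportError as exc:  # pragma: no cover - env without cyvcf2
            raise DosageError(
                "reading VCF dosages requires the cyvcf2 package"
            ) from exc
        vcf = VCF(str(path))
        samples = np.asarray(vcf.samples)
        ids, counted, other, chroms, poss, cols = [], [], [], [], [], []
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise DosageError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
            ds = rec.format("DS")
            if ds is None:
                raise DosageError(f"no DS field at {rec.CHROM}:{rec.POS}")
            ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
            counted.append(rec.ALT[0].upper())
            other.append(rec.REF.upper())
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            cols.append(np.asarray(ds, float).reshape(-1))
        vcf.close()
        if not cols:
            raise DosageError(f"{path}: no records")
        return cls(
            samples=samples,
            variant_ids=np.asarray(ids),
            counted_allele=np.asarray(counted),
            other_allele=np.asarray(other),
            values=np.column_stack(cols),
            chrom=np.asarray(chroms),
            pos=np.asarray(poss),
        )

    def to_vcf(self, path: str | Path) -> None:
        """Write an uncompressed VCF with per-sample DS dosages.

        ALT is the counted allele, REF the other allele; GT is omitted.
        """
        chrom = self.chrom if self.chrom is not None else np.repeat("1", self.n_variants)
        pos = self.pos if self.pos is not None else np.arange(1, self.n_variants + 1)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
            for c in pd.unique(np.asarray(chrom)):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(map(str, self.samples)) + "\n")
            for j in range(self.n_variants):
                row = "\t".join(f"{v:.4g}" for v in self.values[:, j])
                fh.write(
                    f"{chrom[j]}\t{pos[j]}\t{self.variant_ids[j]}\t"
                    f"{self.other_allele[j]}\t{self.counted_allele[j]}\t.\t.\t.\tDS\t"
                    + row.replace("\t", "\t") + "\n"
                )


def read_dosages(path: str | Path) -> DosageMatrix:
    """Dispatch on extension: ``.vcf`` -> VCF DS field, otherwise TSV."""
    p = Path(path)
    if p.suffix == ".vcf" or p.name.endswith(".vcf.gz"):
        return DosageMatrix.from_vcf(p)
    return DosageMatrix.from_tsv(p)
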