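"""Readers, writers and validation for dosage matrices and field trials.

Dosage matrices are individuals x biallelic SNPs with integer allele
dosages 0..4 (nulliplex..quadriplex).  CSV layout: header row of SNP ids,
first column the individual id, missing cells written ``NA``.  VCF input is
v4.2 with tetraploid genotypes such as ``0/1/1/1`` (parsed with pysam); an
explicit ``DS`` dosage field, when present, takes precedence over the GT
allele count.  Validation failures are total: nothing is returned from a
file that does not validate.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DosageMatrix",
    "FieldTrial",
    "DosageFormatError",
    "TrialFormatError",
    "read_dosage_csv",
    "write_dosage_csv",
    "read_vcf_tetraploid",
    "write_vcf_tetraploid",
    "impute_missing",
]

PLOIDY = 4
_META_COLS = ("entry", "block", "plot", "is_check")


class DosageFormatError(ValueError):
    """Dosage file failed validation."""


class TrialFormatError(ValueError):
    """Field-trial table failed validation."""


class DosageMatrix:
    """Individuals x SNPs allele-dosage matrix for a fixed ploidy of 4.

    ``dosages`` is a float array with NaN marking missing values; entries
    must be integers in {0..4} unless ``imputed`` is set (mean imputation
    produces real-valued dosages).
    """

    def __init__(
        self,
        ids: Sequence[str],
        snp_ids: Sequence[str],
        dosages: np.ndarray,
        imputed: bool = False,
    ) -> None:
        self.ids = list(map(str, ids))
        self.snp_ids = list(map(str, snp_ids))
        self.dosages = np.asarray(dosages, dtype=float)
        self.imputed = bool(imputed)
        self.ploidy = PLOIDY
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise DosageFormatError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.ids)) != len(self.ids):
            raise DosageFormatError("duplicate individual ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DosageFormatError("duplicate SNP ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > PLOIDY):
            raise DosageFormatError("dosages outside [0, 4]")
        if not self.imputed and vals.size and not np.all(vals == np.round(vals)):
            raise DosageFormatError("non-integer dosage in unimputed matrix")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.snp_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.ids, columns=self.snp_ids)

    def subset(self, ids: Sequence[str]) -> "DosageMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DosageMatrix(ids, self.snp_ids, self.dosages[idx], imputed=self.imputed)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DosageMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


def write_dosage_csv(m: DosageMatrix, path: str | Path) -> None:
    df = m.to_dataframe()
    df.index.name = "id"
    df.to_csv(path, na_rep="NA", float_format=None if m.imputed else "%.0f")


def read_dosage_csv(path: str | Path) -> DosageMatrix:
    """Read a dosage CSV, validating every cell.

    Errors name the offending row and column; a ``NA`` cell becomes missing
    and is counted in the log.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    ids = [str(i) for i in df.index]
    snp_ids = [str(c) for c in df.columns]
    out = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell in ("NA", "", "nan", "NaN"):
                out[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise DosageFormatError(
                    f"{path}: non-numeric dosage {cell!r} at row {ids[i]!r}, "
                    f"column {snp_ids[j]!r}"
                ) from None
            if v != round(v):
                raise DosageFormatError(
                    f"{path}: non-integer dosage {cell!r} at row {ids[i]!r}, "
                    f"column {snp_ids[j]!r}"
                )
            if not 0 <= v <= PLOIDY:
                raise DosageFormatError(
                    f"{path}: dosage {cell!r} out of range 0..4 at row "
                    f"{ids[i]!r}, column {snp_ids[j]!r}"
                )
            out[i, j] = v
    m = DosageMatrix(ids, snp_ids, out)
    if m.n_missing:
        logger.info("read %s: %d missing dosages", path, m.n_missing)
    return m


def read_vcf_tetraploid(path: str | Path) -> DosageMatrix:
    """Read tetraploid genotypes from a VCF into a dosage matrix.

    Dosage is the count of ALT alleles in the 4-allele GT; a per-sample
    ``DS`` field takes precedence when present.  Multi-allelic records are
    rejected, as is any GT whose ploidy is not 4 (``./././.`` is missing).
    """
    import pysam

    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                raise DosageFormatError(
                    f"{path}: record {rec.id or rec.pos} is not biallelic"
                )
            snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            col = np.empty(len(samples), dtype=float)
            for k, s in enumerate(samples):
                sample = rec.samples[s]
                ds = sample.get("DS") if "DS" in sample else None
                if ds is not None:
                    ds = ds[0] if isinstance(ds, tuple) else ds
                    if ds is not None:
                        col[k] = float(ds)
                        continue
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    if gt is not None and len(gt) != PLOIDY:
                        raise DosageFormatError(
                            f"{path}: sample {s} at {snp_ids[-1]} has ploidy "
                            f"{len(gt)}, expected 4"
                        )
                    col[k] = np.nan
                    continue
                if len(gt) != PLOIDY:
                    raise DosageFormatError(
                        f"{path}: sample {s} at {snp_ids[-1]} has ploidy "
                        f"{len(gt)}, expected 4"
                    )
                if any(a is None for a in gt):
                    col[k] = np.nan
                else:
                    col[k] = float(sum(int(a > 0) for a in gt))
            columns.append(col)
    if not snp_ids:
        raise DosageFormatError(f"{path}: no variant records")
    dosages = np.column_stack(columns)
    imputed = bool(np.any(dosages[~np.isnan(dosages)] % 1 != 0))
    return DosageMatrix(samples, snp_ids, dosages, imputed=imputed)


def write_vcf_tetraploid(m: DosageMatrix, path: str | Path, with_ds: bool = False) -> None:
    """Write a minimal VCF v4.2 with tetraploid GT (and optionally DS).

    Integer dosages map to unphased sorted genotypes (3 -> ``0/1/1/1``);
    missing becomes ``./././.``.  Real-valued (imputed) matrices must be
    written with ``with_ds=True``.
    """
    if m.imputed and not with_ds:
        raise DosageFormatError("imputed (real-valued) dosages need with_ds=True")
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if with_ds:
        lines.append(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(m.ids)
    )
    fmt = "GT:DS" if with_ds else "GT"
    for j, snp in enumerate(m.snp_ids):
        fields = ["1", str(j + 1), snp, "A", "T", ".", "PASS", ".", fmt]
        for i in range(m.n_individuals):
            d = m.dosages[i, j]
            if np.isnan(d):
                gt = "./././."
                ds = "."
            else:
                k = int(round(d))
                gt = "/".join(["0"] * (PLOIDY - k) + ["1"] * k)
                ds = f"{d:g}"
            fields.append(f"{gt}:{ds}" if with_ds else gt)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def impute_missing(m: DosageMatrix) -> DosageMatrix:
    """Replace missing dosages by the locus mean (real-valued thereafter).

    Loci that are missing in every individual carry no information and are
    dropped with a logged warning.
    """
    if m.n_missing == 0:
        return m
    dos = m.dosages.copy()
    all_missing = np.isnan(dos).all(axis=0)
    if all_missing.any():
        logger.warning(
            "dropping %d all-missing loci: %s",
            int(all_missing.sum()),
            [s for s, bad in zip(m.snp_ids, all_missing) if bad][:10],
        )
    keep = ~all_missing
    dos = dos[:, keep]
    snp_ids = [s for s, ok in zip(m.snp_ids, keep) if ok]
    col_mean = np.nanmean(dos, axis=0)
    nan_r, nan_c = np.where(np.isnan(dos))
    dos[nan_r, nan_c] = col_mean[nan_c]
    return DosageMatrix(m.ids, snp_ids, dos, imputed=True)


class FieldTrial:
    """Plot records of an augmented design with replicated checks.

    Wraps a DataFrame with columns ``entry, block, plot, is_check`` followed
    by one column per trait.  Invariants enforced on construction:
    (block, plot) unique; every check entry present exactly once in every
    block; every non-check entry in exactly one plot.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise TrialFormatError(f"missing columns: {missing}")
        df = df.copy()
        df["entry"] = df["entry"].astype(str)
        df["is_check"] = df["is_check"].astype(bool)
        if df.duplicated(subset=["block", "plot"]).any():
            dup = df[df.duplicated(subset=["block", "plot"], keep=False)]
            raise TrialFormatError(
                f"duplicate (block, plot) coordinates:\n{dup[['block', 'plot']]}"
            )
        blocks = sorted(df["block"].unique())
        checks = sorted(df.loc[df["is_check"], "entry"].unique())
        for c in checks:
            sub = df[(df["entry"] == c) & df["is_check"]]
            counts = sub["block"].value_counts()
            absent = [b for b in blocks if b not in counts.index]
            if absent or (counts != 1).any():
                raise TrialFormatError(
                    f"check {c!r} must appear exactly once per block; "
                    f"absent from blocks {absent}"
                )
        test_counts = df.loc[~df["is_check"], "entry"].value_counts()
        if (test_counts != 1).any():
            bad = list(test_counts[test_counts != 1].index)
            raise TrialFormatError(f"test entries in more than one plot: {bad}")
        self.df = df

    @property
    def traits(self) -> list[str]:
        return [c for c in self.df.columns if c not in _META_COLS]

    @property
    def blocks(self) -> list:
        return sorted(self.df["block"].unique())

    @property
    def checks(self) -> list[str]:
        return sorted(self.df.loc[self.df["is_check"], "entry"].unique())

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FieldTrial":
        return cls(pd.read_csv(path, sep="\t"))
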