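"""Genomic relationship matrices for autotetraploids from allele dosage.

The additive GRM extends VanRaden's centred cross-product to ploidy 4
(the full-autotetraploid scaling): with dosage matrix X (individuals x
loci) and alternative-allele frequencies p_j,

    W = X - 4 p,      G = W W' / sum_j 4 p_j (1 - p_j)

Under this scaling the expected diagonal of an individual with inbreeding
coefficient F is 1 + 3F (dosage variance 4pq(1+3F)), the entry between a
parent and one of its selfed offspring is 4 * theta = 1 at co-ancestry
theta = 1/4, and unrelated non-inbred individuals average 1 on the
diagonal and 0 off it.

A deliberately mis-scaled ``pseudodiploid`` contrast is provided: dosages
halved onto a 0..2 scale and pushed through the diploid VanRaden formula
with denominator sum 2 p q.

``TetraploidGRM`` wraps the same computation as a scikit-learn transformer
whose :meth:`transform` returns relationship rows against the fitted
training individuals, so it composes with :class:`tetrablup.gblup.GBLUP`
in a Pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DosageMatrix

__all__ = [
    "GRM",
    "GRMError",
    "allele_frequencies",
    "build_grm",
    "expected_relationship_checks",
    "TetraploidGRM",
]

PLOIDY = 4


class GRMError(ValueError):
    pass


def allele_frequencies(m: DosageMatrix) -> np.ndarray:
    """Per-locus alternative-allele frequency p_j = mean dosage / 4."""
    return np.nanmean(m.dosages, axis=0) / PLOIDY


def _center_and_denominator(X, p, method):
    if method == "full_tetraploid":
        W = X - PLOIDY * p
        denom = float(np.sum(PLOIDY * p * (1.0 - p)))
    elif method == "pseudodiploid":
        W = X / 2.0 - 2.0 * p
        denom = float(np.sum(2.0 * p * (1.0 - p)))
    else:
        raise GRMError(f"unknown method {method!r}")
    return W, denom


def _psd_repair(values: np.ndarray) -> np.ndarray:
    """Clamp negative eigenvalues to zero (symmetric reconstruction)."""
    d, U = np.linalg.eigh((values + values.T) / 2.0)
    d = np.clip(d, 0.0, None)
    return (U * d) @ U.T


@dataclass
class GRM:
    """Symmetric genomic relationship matrix over genotyped entries."""

    ids: list[str]
    values: np.ndarray
    method: str
    n_loci_used: int
    freqs: np.ndarray
    repaired: bool = False
    blend: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise GRMError("GRM must be square over ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GRMError("GRM must be symmetric")

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def submatrix(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        ri = [self.ids.index(i) for i in rows]
        ci = [self.ids.index(i) for i in cols]
        return self.values[np.ix_(ri, ci)]

    def write_csv(self, path: str | Path) -> None:
        df = self.dataframe()
        df.index.name = "id"
        df.to_csv(path)

    def write_long_tsv(self, path: str | Path) -> None:
        n = len(self.ids)
        iu = np.triu_indices(n)
        pd.DataFrame(
            {
                "id1": np.asarray(self.ids)[iu[0]],
                "id2": np.asarray(self.ids)[iu[1]],
                "value": self.values[iu],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_csv(cls, path: str | Path, method: str = "unknown") -> "GRM":
        df = pd.read_csv(path, index_col=0)
        return cls(
            ids=[str(i) for i in df.index],
            values=df.to_numpy(dtype=float),
            method=method,
            n_loci_used=0,
            freqs=np.empty(0),
        )


def build_grm(
    m: DosageMatrix,
    method: str = "full_tetraploid",
    maf_min: float = 0.01,
    freqs: np.ndarray | None = None,
    repair: bool = False,
    blend: float = 0.0,
) -> GRM:
    """Build the additive GRM from a dosage matrix.

    Parameters
    ----------
    m : DosageMatrix
        Missing entries must have been imputed first.
    method : "full_tetraploid" or "pseudodiploid"
    maf_min : float
        Loci with minor allele frequency below this are excluded (default
        1%).
    freqs : ndarray, optional
        Externally supplied allele frequencies (e.g. true simulation
        frequencies); defaults to sample frequencies.
    repair : bool
        Clamp negative eigenvalues to zero after construction.
    blend : float
        If positive, return (1 - blend) G + blend I (recorded in metadata);
        0.01 is customary when an invertible matrix is required.
    """
    X = np.asarray(m.dosages, dtype=float)
    if np.isnan(X).any():
        raise GRMError("missing dosages present; run impute_missing first")
    p = allele_frequencies(m) if freqs is None else np.asarray(freqs, dtype=float)
    if p.size != m.n_loci:
        raise GRMError("frequency vector does not match locus count")
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if not keep.any():
        raise GRMError(f"no loci pass the MAF >= {maf_min} filter")
    W, denom = _center_and_denominator(X[:, keep], p[keep], method)
    if denom <= 0:
        raise GRMError("zero denominator: all retained loci are monomorphic")
    G = (W @ W.T) / denom
    repaired = False
    if repair:
        G = _psd_repair(G)
        repaired = True
    if blend:
        G = (1.0 - blend) * G + blend * np.eye(G.shape[0])
    return GRM(
        ids=list(m.ids),
        values=G,
        method=method,
        n_loci_used=int(keep.sum()),
        freqs=p[keep],
        repaired=repaired,
        blend=blend,
    )


def expected_relationship_checks(
    genomes: Mapping[str, "object"],
    pedigree: pd.DataFrame,
    freqs: np.ndarray,
    maf_min: float = 0.0,
) -> dict:
    """Compare realized G entries against pedigree expectations.

    Under the full-autotetraploid scaling (centred at the true simulation
    frequencies): S1 diagonal ~ 1 + 3F = 1.5 at F = 1/6; parent vs selfed
    offspring ~ 4 theta = 1.0; F1-of-unrelated-parents diagonal ~ 1.0;
    parent vs outcross offspring ~ 0.5; unrelated pairs ~ 0.

    ``genomes`` maps id -> LabeledGenome; the pedigree provides generation
    and parent columns.  Returns a dict of realized means alongside their
    expectations.
    """
    ids = list(genomes)
    dosages = np.stack([genomes[i].dosage for i in ids]).astype(float)
    snp_ids = [f"m{j}" for j in range(dosages.shape[1])]
    grm = build_grm(
        DosageMatrix(ids, snp_ids, dosages),
        method="full_tetraploid",
        maf_min=maf_min,
        freqs=freqs,
    )
    G = grm.values
    pos = {i: k for k, i in enumerate(ids)}
    ped = pedigree.set_index("id")

    def mean_or_nan(vals):
        return float(np.mean(vals)) if len(vals) else float("nan")

    s1_diag, f1_diag, parent_self, parent_cross, unrelated = [], [], [], [], []
    founders = [i for i in ids if i in ped.index and ped.loc[i, "generation"] == "S0"]
    for i in ids:
        if i not in ped.index:
            continue
        gen = ped.loc[i, "generation"]
        p1, p2 = ped.loc[i, "parent1"], ped.loc[i, "parent2"]
        if gen == "S1":
            s1_diag.append(G[pos[i], pos[i]])
            if p1 in pos:
                parent_self.append(G[pos[i], pos[p1]])
        elif gen == "F1":
            f1_diag.append(G[pos[i], pos[i]])
            for par in (p1, p2):
                if par in pos:
                    parent_cross.append(G[pos[i], pos[par]])
    for a in range(len(founders)):
        for b in range(a + 1, len(founders)):
            unrelated.append(G[pos[founders[a]], pos[founders[b]]])

    return {
        "s1_mean_diagonal": {"realized": mean_or_nan(s1_diag), "expected": 1.5},
        "f1_mean_diagonal": {"realized": mean_or_nan(f1_diag), "expected": 1.0},
        "parent_selfed_offspring": {
            "realized": mean_or_nan(parent_self),
            "expected": 1.0,
        },
        "parent_outcross_offspring": {
            "realized": mean_or_nan(parent_cross),
            "expected": 0.5,
        },
        "unrelated_founders": {"realized": mean_or_nan(unrelated), "expected": 0.0},
        "n_loci_used": grm.n_loci_used,
    }


class TetraploidGRM(TransformerMixin, BaseEstimator):
    """Dosage-to-relationship kernel transformer (scikit-learn API).

    ``fit`` memorises the training dosages and allele frequencies;
    ``transform(X)`` returns the relationship block between the rows of
    ``X`` and the training individuals, so ``fit_transform`` on training
    data yields the square training GRM expected by
    :class:`tetrablup.gblup.GBLUP`.

    Parameters
    ----------
    method : "full_tetraploid" (default) or "pseudodiploid"
    maf_min : float
        MAF filter computed on the training sample.
    """

    def __init__(self, method: str = "full_tetraploid", maf_min: float = 0.01):
        self.method = method
        self.maf_min = maf_min

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise GRMError("X must be 2-D (individuals x loci)")
        if np.isnan(X).any():
            raise GRMError("missing dosages present; impute first")
        p = X.mean(axis=0) / PLOIDY
        keep = np.minimum(p, 1.0 - p) >= self.maf_min
        if not keep.any():
            raise GRMError(f"no loci pass the MAF >= {self.maf_min} filter")
        W, denom = _center_and_denominator(X[:, keep], p[keep], self.method)
        if denom <= 0:
            raise GRMError("zero denominator: retained loci are monomorphic")
        self.freqs_ = p
        self.keep_ = keep
        self.W_train_ = W
        self.denom_ = denom
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "W_train_"):
            raise GRMError("TetraploidGRM is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise GRMError("locus count differs from fit")
        W, _ = _center_and_denominator(
            X[:, self.keep_], self.freqs_[self.keep_], self.method
        )
        return (W @ self.W_train_.T) / self.denom_
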