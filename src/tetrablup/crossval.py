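"""Cross-validation of GEBV accuracy, random and family-structured.

Accuracy is the Pearson correlation between observed (block-adjusted)
phenotypes and predicted GEBVs in a testing set.  Two protocols:

* :func:`random_cv` -- repeated random partitions (default 50 repetitions,
  70% training / 30% testing), reporting every per-repetition accuracy so
  the distribution can be drawn as a boxplot.
* :func:`scheme_cv` -- the family-structured scheme: within-family cells
  use the random-partition protocol inside the family; cross-family cells
  train on the whole of family A and test on the whole of family B in a
  single fit.  Each cell is annotated with its pedigree relatedness class
  (full-sib within a family; half-sib when the two families share a
  parent; unrelated otherwise).

Partitions are drawn over *sorted* individual ids, so permuting the input
order changes no accuracy.  Cells whose observed or predicted values have
zero variance are recorded as missing (never silently dropped), with a
logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .gblup import GBLUP

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionScheme",
    "CVResult",
    "AccuracyMatrix",
    "random_cv",
    "scheme_cv",
    "relatedness_class",
    "report",
]


@dataclass(frozen=True)
class PartitionScheme:
    """Repeated random-partition protocol (n_reps x train_fraction)."""

    n_reps: int = 50
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class CVResult:
    """Per-repetition accuracies (NaN = undefined) and their summary."""

    accuracies: np.ndarray
    n_train: int
    n_test: int

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.accuracies)) if self.n_valid else math.nan

    @property
    def sd(self) -> float:
        return (
            float(np.nanstd(self.accuracies, ddof=1)) if self.n_valid > 1 else math.nan
        )

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.accuracies)))


def _pearson(obs: np.ndarray, pred: np.ndarray, context: str) -> float:
    if np.std(obs) == 0 or np.std(pred) == 0:
        logger.warning("zero-variance observations or predictions in %s", context)
        return math.nan
    return float(stats.pearsonr(obs, pred)[0])


def random_cv(
    y: np.ndarray,
    K: np.ndarray,
    scheme: PartitionScheme | None = None,
    model: GBLUP | None = None,
    ids: Sequence[str] | None = None,
) -> CVResult:
    """Repeated random 70/30 cross-validation on a precomputed kernel.

    ``y`` and the square kernel ``K`` are aligned; ``ids`` (default
    positional) only fix the partition draw so results are invariant to
    input ordering.
    """
    scheme = scheme or PartitionScheme()
    model = model or GBLUP()
    y = np.asarray(y, dtype=float).ravel()
    K = np.asarray(K, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError(f"need >= 10 individuals for random CV, got {n}")
    if ids is None:
        ids = [f"{i:06d}" for i in range(n)]
    order = np.argsort(np.asarray(ids, dtype=object))
    n_train = int(math.floor(scheme.train_fraction * n))
    rng = np.random.default_rng(scheme.seed)
    accs = np.empty(scheme.n_reps)
    for rep in range(scheme.n_reps):
        pick = rng.choice(n, size=n_train, replace=False)
        train = order[np.sort(pick)]
        mask = np.ones(n, dtype=bool)
        mask[train] = False
        test = np.where(mask)[0]
        fit = clone(model).fit(K[np.ix_(train, train)], y[train])
        pred = fit.predict(K[np.ix_(test, train)])
        accs[rep] = _pearson(y[test], pred, f"random CV rep {rep}")
    return CVResult(accuracies=accs, n_train=n_train, n_test=n - n_train)


def relatedness_class(
    fam_a: str, fam_b: str, family_parents: Mapping[str, set]
) -> str:
    """full-sib (same family), half-sib (shared parent) or unrelated."""
    if fam_a == fam_b:
        return "full-sib"
    if set(family_parents[fam_a]) & set(family_parents[fam_b]):
        return "half-sib"
    return "unrelated"


def family_parent_map(pedigree: pd.DataFrame) -> dict:
    """family label -> set of parent ids, from an offspring pedigree table."""
    out: dict[str, set] = {}
    off = pedigree[pedigree["generation"].isin(["S1", "F1"])]
    for fam, sub in off.groupby("family"):
        out[fam] = set(sub["parent1"]) | set(sub["parent2"])
    return out


@dataclass
class AccuracyMatrix:
    """Training x testing accuracy cells for one trait (long format).

    ``table`` columns: training, testing, trait, accuracy, relatedness,
    n_train, n_test.  Missing accuracies are kept as NaN rows.
    """

    table: pd.DataFrame
    per_rep: dict = field(default_factory=dict)  # (training, testing) -> ndarray

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot(index="training", columns="testing", values="accuracy")

    def cell(self, training: str, testing: str) -> float:
        sub = self.table[
            (self.table["training"] == training) & (self.table["testing"] == testing)
        ]
        return float(sub["accuracy"].iloc[0])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AccuracyMatrix":
        return cls(pd.read_csv(path, sep="\t", na_values=["NA"]))


def scheme_cv(
    y: np.ndarray,
    K: np.ndarray,
    families: Sequence[str],
    family_parents: Mapping[str, set],
    trait: str = "trait",
    model: GBLUP | None = None,
    scheme: PartitionScheme | None = None,
    ids: Sequence[str] | None = None,
) -> AccuracyMatrix:
    """Family-structured training -> testing accuracy matrix.

    Diagonal cells run :func:`random_cv` within the family and report the
    mean; off-diagonal cells are a single fit on all of the training family
    predicting all of the testing family.  Cells that cannot be estimated
    (family too small, zero variance) are reported missing.
    """
    scheme = scheme or PartitionScheme()
    model = model or GBLUP()
    y = np.asarray(y, dtype=float).ravel()
    K = np.asarray(K, dtype=float)
    families = np.asarray(families, dtype=object)
    if ids is None:
        ids = [f"{i:06d}" for i in range(y.size)]
    ids = np.asarray(ids, dtype=object)
    labels = sorted(set(families))
    rows = []
    per_rep: dict[tuple, np.ndarray] = {}
    for fa in labels:
        ia = np.where(families == fa)[0]
        for fb in labels:
            ib = np.where(families == fb)[0]
            rel = relatedness_class(fa, fb, family_parents)
            acc = math.nan
            n_train, n_test = len(ia), len(ib)
            if fa == fb:
                try:
                    res = random_cv(
                        y[ia], K[np.ix_(ia, ia)], scheme, model, ids=ids[ia]
                    )
                    acc = res.mean
                    n_train, n_test = res.n_train, res.n_test
                    per_rep[(fa, fb)] = res.accuracies
                except ValueError:
                    logger.warning("family %s too small for within-family CV", fa)
            else:
                if len(ib) < 2 or len(ia) < 3:
                    logger.warning(
                        "cell (%s -> %s) undefined: family too small", fa, fb
                    )
                else:
                    fit = clone(model).fit(K[np.ix_(ia, ia)], y[ia])
                    pred = fit.predict(K[np.ix_(ib, ia)])
                    acc = _pearson(y[ib], pred, f"cell ({fa} -> {fb})")
            rows.append(
                {
                    "training": fa,
                    "testing": fb,
                    "trait": trait,
                    "accuracy": acc,
                    "relatedness": rel,
                    "n_train": n_train,
                    "n_test": n_test,
                }
            )
    return AccuracyMatrix(table=pd.DataFrame(rows), per_rep=per_rep)


def report(
    matrices: Sequence[AccuracyMatrix],
    outdir: str | Path,
    prefix: str = "accuracy",
) -> dict:
    """Write the long-format accuracy table and boxplot-ready series.

    Returns the paths written.  ``accuracy.tsv`` stacks every trait's cells
    (missing preserved as NA); ``<prefix>_reps.csv`` holds the
    per-repetition accuracies of the within-family cells, one row per
    repetition, boxplot-ready.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long = pd.concat([m.table for m in matrices], ignore_index=True)
    table_path = outdir / f"{prefix}.tsv"
    long.to_csv(table_path, sep="\t", index=False, na_rep="NA")
    rep_rows = []
    for m in matrices:
        trait = m.table["trait"].iloc[0] if len(m.table) else "trait"
        for (fa, fb), accs in m.per_rep.items():
            for k, a in enumerate(accs):
                rep_rows.append(
                    {"trait": trait, "family": fa, "rep": k, "accuracy": a}
                )
    reps_path = outdir / f"{prefix}_reps.csv"
    pd.DataFrame(rep_rows).to_csv(reps_path, index=False, na_rep="NA")
    return {"table": str(table_path), "reps": str(reps_path)}
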