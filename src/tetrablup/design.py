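"""Augmented-design adjustment, check ANOVA, LSD and generation contrasts.

An augmented design replicates a small set of check cultivars in every
incomplete block while each test entry (here: S1 inbred or F1 hybrid
offspring) occupies a single plot.  Checks estimate additive block effects
("correction factors") and the experimental error:

    CF_j  = (mean of check values in block j) - (grand mean of check values)
    Y'_ij = Y_ij - CF_j

The correction factors sum to zero over blocks, so adjusted check means are
unaffected by block effects and equal across blocks.

The check plots form a complete checks x blocks two-way layout whose
interaction mean square is the error estimate with (g-1)(r-1) degrees of
freedom (g checks per block, r blocks).  Least significant differences
follow Federer's standard-error cases for comparing adjusted means:

    two checks                    sqrt(2 MSE / r)
    two tests, same block         sqrt(2 MSE)
    two tests, different blocks   sqrt(2 MSE (1 + 1/g))
    test vs check                 sqrt(MSE (1 + 1/r + 1/g + 1/(g r)))

Generation contrasts (parents vs selfed offspring = inbreeding depression,
parents vs hybrids = average heterosis, selfed vs hybrids) compare adjusted
group means.  Each adjusted group mean is an exact linear combination of
plot values, so the contrast variance is computed from the corresponding
coefficient vectors, Var = MSE * ||c_A - c_B||^2, which accounts for the
error the check-based adjustment itself injects into adjusted test values
and for unequal or unbalanced group sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FieldTrial

__all__ = [
    "DesignError",
    "CorrectionFactors",
    "AdjustedPhenotypes",
    "AnovaResult",
    "ContrastEstimate",
    "GenerationContrasts",
    "CrossRecord",
    "ProgramSummary",
    "compute_correction_factors",
    "adjust",
    "adjust_all",
    "validate_design",
    "anova_and_lsd",
    "generation_contrasts",
    "proportional_inbreeding_depression",
    "summarize_program",
]


class DesignError(ValueError):
    pass


@dataclass
class CorrectionFactors:
    """Per-block correction factors for one trait (sum to zero)."""

    trait: str
    values: dict  # block id -> CF
    g: int  # checks per block
    r: int  # number of blocks
    grand_check_mean: float

    def __getitem__(self, block) -> float:
        return self.values[block]


def compute_correction_factors(trial: FieldTrial, trait: str) -> CorrectionFactors:
    """CF_j = block-j check mean minus the grand check mean."""
    if trait not in trial.traits:
        raise DesignError(f"unknown trait {trait!r}")
    checks = trial.df[trial.df["is_check"]]
    if checks.empty:
        raise DesignError("trial has no check plots")
    # FieldTrial guarantees one plot per check per block, but re-verify so a
    # hand-built frame fails loudly here with the offending (check, block).
    missing = []
    for c in trial.checks:
        present = set(checks.loc[checks["entry"] == c, "block"])
        for b in trial.blocks:
            if b not in present:
                missing.append((c, b))
    if missing:
        raise DesignError(f"checks missing from blocks: {missing}")
    grand = float(checks[trait].mean())
    block_means = checks.groupby("block")[trait].mean()
    values = {b: float(block_means[b] - grand) for b in trial.blocks}
    return CorrectionFactors(
        trait=trait,
        values=values,
        g=len(trial.checks),
        r=trial.n_blocks,
        grand_check_mean=grand,
    )


@dataclass
class AdjustedPhenotypes:
    """Adjusted values Y' = Y - CF for one trait, with provenance.

    ``table`` keeps one row per plot (entry, block, raw, cf, adjusted,
    is_check); ``entry_values`` averages the adjusted check values over
    blocks so every entry maps to a single adjusted phenotype.
    """

    trait: str
    table: pd.DataFrame
    cf: CorrectionFactors
    trial: FieldTrial = field(repr=False)

    @property
    def entry_values(self) -> pd.Series:
        return self.table.groupby("entry")["adjusted"].mean()


def adjust(trial: FieldTrial, cf: CorrectionFactors) -> AdjustedPhenotypes:
    """Apply Y' = Y - CF(block) to every plot (checks and tests)."""
    df = trial.df
    rows = pd.DataFrame(
        {
            "entry": df["entry"],
            "block": df["block"],
            "is_check": df["is_check"],
            "raw": df[cf.trait],
            "cf": df["block"].map(cf.values),
        }
    )
    rows["adjusted"] = rows["raw"] - rows["cf"]
    return AdjustedPhenotypes(trait=cf.trait, table=rows, cf=cf, trial=trial)


def adjust_all(trial: FieldTrial) -> pd.DataFrame:
    """Adjusted entry values for every trait (entries x traits)."""
    out = {}
    for t in trial.traits:
        out[t] = adjust(trial, compute_correction_factors(trial, t)).entry_values
    return pd.DataFrame(out)


@dataclass
class DesignCheck:
    passed: bool
    bound: float
    message: str

    def __bool__(self) -> bool:
        return self.passed


def validate_design(c: int, r: int) -> DesignCheck:
    """Error-df rule for an augmented design: require r > 10/(c-1) + 1.

    With c checks and r blocks the check error has (c-1)(r-1) degrees of
    freedom, which should exceed 10.
    """
    if c < 2:
        return DesignCheck(False, math.inf, f"{c} check(s): need at least 2")
    bound = 10.0 / (c - 1) + 1.0
    ok = r > bound
    msg = (
        f"r={r} blocks with c={c} checks: error df = {(c - 1) * (r - 1)}; "
        f"rule requires r > {bound:g} -> {'pass' if ok else 'fail'}"
    )
    return DesignCheck(ok, bound, msg)


@dataclass
class AnovaResult:
    """Check-based two-way ANOVA and LSDs for one trait."""

    trait: str
    ss_blocks: float
    ss_checks: float
    ss_error: float
    df_error: int
    mse: float
    t_crit: float
    lsd: dict  # comparison case -> LSD at alpha
    alpha: float = 0.05

    @property
    def lsd_0_05(self) -> float:
        """Headline LSD: two test entries in different blocks."""
        return self.lsd["tests_diff_block"]


def anova_and_lsd(trial: FieldTrial, trait: str, alpha: float = 0.05) -> AnovaResult:
    """Two-way (checks x blocks) ANOVA on check plots; Federer LSD cases."""
    checks = trial.df[trial.df["is_check"]]
    g = len(trial.checks)
    r = trial.n_blocks
    df_error = (g - 1) * (r - 1)
    if df_error <= 0:
        raise DesignError(
            f"error df = (g-1)(r-1) = {df_error} with g={g}, r={r}; not estimable"
        )
    y = checks[trait].to_numpy(dtype=float)
    grand = y.mean()
    bm = checks.groupby("block")[trait].mean()
    cm = checks.groupby("entry")[trait].mean()
    ss_blocks = g * float(((bm - grand) ** 2).sum())
    ss_checks = r * float(((cm - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = max(ss_total - ss_blocks - ss_checks, 0.0)
    mse = ss_error / df_error
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df_error))
    lsd = {
        "checks": t_crit * math.sqrt(2.0 * mse / r),
        "tests_same_block": t_crit * math.sqrt(2.0 * mse),
        "tests_diff_block": t_crit * math.sqrt(2.0 * mse * (1.0 + 1.0 / g)),
        "test_vs_check": t_crit
        * math.sqrt(mse * (1.0 + 1.0 / r + 1.0 / g + 1.0 / (g * r))),
    }
    return AnovaResult(
        trait=trait,
        ss_blocks=ss_blocks,
        ss_checks=ss_checks,
        ss_error=ss_error,
        df_error=df_error,
        mse=mse,
        t_crit=t_crit,
        lsd=lsd,
        alpha=alpha,
    )


def _entry_coefficients(adjusted: AdjustedPhenotypes) -> dict:
    """Per-entry coefficient vectors over plots for adjusted values.

    The adjusted value of a test entry is Y - CF(block), i.e. +1 on its own
    plot, -1/g on each check plot of its block and +1/(g r) on every check
    plot.  The block-averaged adjusted value of a check reduces to the plain
    mean of its plots because the CFs sum to zero over blocks.
    """
    df = adjusted.trial.df.reset_index(drop=True)
    n = len(df)
    is_check = df["is_check"].to_numpy()
    block = df["block"].to_numpy()
    g = adjusted.cf.g
    r = adjusted.cf.r
    check_plot = np.where(is_check)[0]
    coefs: dict[str, np.ndarray] = {}
    for entry, sub in df.groupby("entry"):
        c = np.zeros(n)
        if bool(sub["is_check"].iloc[0]):
            c[sub.index] = 1.0 / len(sub)
        else:
            i = int(sub.index[0])
            c[i] = 1.0
            same_block_checks = check_plot[block[check_plot] == block[i]]
            c[same_block_checks] -= 1.0 / g
            c[check_plot] += 1.0 / (g * r)
        coefs[str(entry)] = c
    return coefs


@dataclass
class ContrastEstimate:
    name: str
    estimate: float
    se: float
    df: int
    t: float
    p_value: float


@dataclass
class GenerationContrasts:
    trait: str
    group_means: dict  # generation -> adjusted group mean
    group_sizes: dict
    contrasts: dict  # "S0_vs_S1" etc -> ContrastEstimate
    proportional_inbreeding_depression: float
    heterosis: dict  # F1 family -> dict(mid_parent, best_parent, frac_above_best)


def proportional_inbreeding_depression(
    s0_means: Sequence[float], s1_means: Sequence[float]
) -> float:
    """Proportional loss of selfed-family means relative to their parents.

    ``1 - mean(S1 family means) / mean(S0 parent means)``; e.g. group mean
    totals of the selfed families against the corresponding parent
    cultivars.
    """
    s0 = float(np.mean(np.asarray(s0_means, dtype=float)))
    s1 = float(np.mean(np.asarray(s1_means, dtype=float)))
    if s0 == 0:
        raise DesignError("S0 mean is zero; proportional loss undefined")
    return 1.0 - s1 / s0


def generation_contrasts(
    adjusted: AdjustedPhenotypes,
    pedigree: pd.DataFrame,
    anova: AnovaResult | None = None,
    s1_families: Iterable[str] | None = None,
) -> GenerationContrasts:
    """S0 vs S1 (inbreeding depression), S0 vs F1 (average heterosis), S1 vs F1.

    Contrasts are differences of adjusted group means tested with a t
    statistic against the check-derived error mean square; variances come
    from the exact plot-coefficient representation of each group mean.
    ``s1_families`` optionally restricts the S1 group (e.g. to families
    whose parent is among the checks).
    """
    if anova is None:
        anova = anova_and_lsd(adjusted.trial, adjusted.trait)
    ped = pedigree.set_index("id")
    df = adjusted.trial.df
    present = set(df["entry"])
    gen_of = ped["generation"]

    members: dict[str, list[str]] = {"S0": [], "S1": [], "F1": []}
    for entry in sorted(present):
        if entry not in gen_of.index:
            continue
        gen = gen_of[entry]
        if gen == "S1" and s1_families is not None:
            if ped.loc[entry, "family"] not in set(s1_families):
                continue
        if gen in members:
            members[gen].append(entry)
    for gen, ids in members.items():
        if not ids:
            raise DesignError(f"no {gen} entries present in the trial")

    coefs = _entry_coefficients(adjusted)
    y = df[adjusted.trait].to_numpy(dtype=float)
    group_vec = {
        gen: np.mean([coefs[e] for e in ids], axis=0) for gen, ids in members.items()
    }
    entry_vals = adjusted.entry_values
    group_means = {gen: float(entry_vals[ids].mean()) for gen, ids in members.items()}

    contrasts = {}
    for a, b in (("S0", "S1"), ("S0", "F1"), ("S1", "F1")):
        diff = group_vec[a] - group_vec[b]
        est = float(diff @ y)
        se = math.sqrt(anova.mse * float(diff @ diff)) if anova.mse > 0 else 0.0
        if se > 0:
            tval = est / se
            p = 2.0 * float(stats.t.sf(abs(tval), anova.df_error))
        else:
            tval = 0.0 if est == 0 else math.copysign(math.inf, est)
            p = 1.0 if est == 0 else 0.0
        contrasts[f"{a}_vs_{b}"] = ContrastEstimate(
            f"{a}_vs_{b}", est, se, anova.df_error, tval, p
        )

    prop_id = proportional_inbreeding_depression(
        [group_means["S0"]], [group_means["S1"]]
    )

    # per-F1-family heterosis against the (adjusted) parent check means
    heterosis = {}
    fam_col = ped.loc[members["F1"], "family"]
    for fam in sorted(fam_col.unique()):
        ids = [e for e in members["F1"] if ped.loc[e, "family"] == fam]
        p1, p2 = ped.loc[ids[0], ["parent1", "parent2"]]
        if p1 not in entry_vals.index or p2 not in entry_vals.index:
            continue
        fam_mean = float(entry_vals[ids].mean())
        mp = float((entry_vals[p1] + entry_vals[p2]) / 2.0)
        bp = float(max(entry_vals[p1], entry_vals[p2]))
        heterosis[fam] = {
            "mid_parent": (fam_mean - mp) / mp if mp != 0 else math.nan,
            "best_parent": (fam_mean - bp) / bp if bp != 0 else math.nan,
            "frac_above_best_parent": float((entry_vals[ids] > bp).mean()),
        }

    return GenerationContrasts(
        trait=adjusted.trait,
        group_means=group_means,
        group_sizes={g: len(ids) for g, ids in members.items()},
        contrasts=contrasts,
        proportional_inbreeding_depression=prop_id,
        heterosis=heterosis,
    )


@dataclass
class CrossRecord:
    """One pollination record of the crossing block."""

    parent: str
    flowers: int
    berries: int
    seeds: float | None = None
    type: str = "cross"  # "self" or "cross"


@dataclass
class ProgramSummary:
    crossing_success_pct: float
    per_parent_berry_pct: dict
    seed_set: dict  # type -> {"mean": float, "sd": float | nan, "n": int}


def summarize_program(records: Sequence[CrossRecord]) -> ProgramSummary:
    """Crossing-program descriptive rates.

    Overall crossing success is 100 x total berries / total flowers; berry
    set is reported per parent; seed set (seeds per berry harvest record) is
    summarised mean +- sd by pollination type.  A single record per type has
    an undefined sd, reported as NaN.
    """
    if not records:
        raise DesignError("no crossing records")
    flowers = sum(rec.flowers for rec in records)
    if flowers <= 0:
        raise DesignError("total flowers must be positive")
    for rec in records:
        if rec.flowers <= 0:
            raise DesignError(f"record for {rec.parent!r} has zero flowers")
        if rec.berries < 0 or rec.berries > rec.flowers:
            raise DesignError(f"record for {rec.parent!r}: berries out of range")
    berries = sum(rec.berries for rec in records)
    success = 100.0 * berries / flowers

    per_parent = {}
    by_parent: dict[str, list[CrossRecord]] = {}
    for rec in records:
        by_parent.setdefault(rec.parent, []).append(rec)
    for parent, recs in by_parent.items():
        f = sum(r.flowers for r in recs)
        b = sum(r.berries for r in recs)
        per_parent[parent] = 100.0 * b / f

    seed_set = {}
    for typ in sorted({rec.type for rec in records}):
        vals = [r.seeds for r in records if r.type == typ and r.seeds is not None]
        if vals:
            arr = np.asarray(vals, dtype=float)
            seed_set[typ] = {
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
                "n": int(arr.size),
            }
    return ProgramSummary(success, per_parent, seed_set)
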