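"""Forward simulation of tetrasomic inheritance and an augmented field trial.

Autotetraploid potato segregates tetrasomically: the four homologous
chromosome copies pair at random, so a gamete receives 2 of the parent's 4
allele copies at each locus.  Every founder allele copy carries a unique
integer label, which makes identity-by-descent (IBD) exactly observable in
the simulated material: the realized inbreeding coefficient of an individual
is the fraction of the 6 within-individual allele pairs at a locus that
share a founder label, averaged over loci.  One round of selfing of a
non-inbred parent gives an expected F of 1/6 under pure bivalent pairing.

Double reduction -- a gamete carrying two copies of the same parental allele
-- is exposed through :class:`GameteModel` with probability ``alpha`` per
locus (default 0, i.e. pure random bivalent segregation).

Phenotypes are generated on an augmented design (Federer): the founder
cultivars are replicated as checks in every incomplete block while each
selfed (S1) or hybrid (F1) offspring occupies a single plot.  A plot value
is

    intercept + block effect + sum(dosage * additive effect)
    - id_coefficient * realized homozygosity + Gaussian residual

so directional inbreeding depression arises mechanically from the IBD
homozygosity created by selfing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledGenome",
    "Gamete",
    "GameteModel",
    "TraitModel",
    "StudyDesignConfig",
    "simulate_founders",
    "make_gamete",
    "self_fertilize",
    "cross",
    "simulate_study",
    "default_trait_models",
    "realized_homozygosity",
    "coancestry",
]

# the 6 unordered pairs among 4 allele copies
_PAIRS = np.array(list(itertools.combinations(range(4), 2)))


class SimulationError(ValueError):
    """Invalid simulation parameter or configuration."""


@dataclass(frozen=True)
class GameteModel:
    """Per-locus gamete sampling rule.

    With probability ``1 - double_reduction_alpha`` the gamete takes 2 of the
    parent's 4 allele copies without replacement (all 6 pairs equiprobable);
    with probability ``double_reduction_alpha`` it takes two copies of one
    uniformly chosen parental allele (double reduction).
    """

    double_reduction_alpha: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.double_reduction_alpha <= 1.0:
            raise SimulationError(
                f"double_reduction_alpha must be in [0, 1], got "
                f"{self.double_reduction_alpha}"
            )


@dataclass
class LabeledGenome:
    """A tetraploid genome with founder-labelled allele copies.

    Parameters
    ----------
    id : str
        Individual identifier.
    states : ndarray of shape (n_loci, 4)
        Allele states, 0 (reference) or 1 (alternative).
    labels : ndarray of shape (n_loci, 4)
        Integer founder labels; two allele copies at the same locus are IBD
        iff their labels are equal.  Labels are unique at founder creation.
    """

    id: str
    states: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[1] != 4:
            raise SimulationError("states must have shape (n_loci, 4)")
        if self.states.shape != self.labels.shape:
            raise SimulationError("states and labels shapes differ")

    @property
    def n_loci(self) -> int:
        return self.states.shape[0]

    @property
    def dosage(self) -> np.ndarray:
        """Per-locus count of alternative alleles, in {0..4}."""
        return self.states.sum(axis=1).astype(np.int64)


@dataclass
class Gamete:
    """Half-genome: 2 allele records per locus."""

    states: np.ndarray  # (n_loci, 2)
    labels: np.ndarray  # (n_loci, 2)

    @property
    def dosage(self) -> np.ndarray:
        return self.states.sum(axis=1).astype(np.int64)


def realized_homozygosity(genome: LabeledGenome) -> float:
    """Fraction of within-individual allele pairs that are IBD.

    Computed as the proportion of the 6 unordered pairs of allele copies per
    locus sharing a founder label, averaged over loci.  This is the realized
    inbreeding coefficient F of the individual.
    """
    lab = genome.labels
    eq = lab[:, _PAIRS[:, 0]] == lab[:, _PAIRS[:, 1]]
    return float(eq.mean())


def coancestry(a: LabeledGenome, b: LabeledGenome) -> float:
    """Realized co-ancestry: P(random allele from each individual is IBD).

    Averaged over loci and over the 16 cross pairs of allele copies.
    """
    eq = a.labels[:, :, None] == b.labels[:, None, :]
    return float(eq.mean())


def simulate_founders(
    n_founders: int,
    n_loci: int,
    maf_min: float,
    seed: int,
    return_freqs: bool = False,
):
    """Draw unrelated, non-inbred tetraploid founder genomes.

    Per-locus alternative-allele frequencies are uniform on
    ``[maf_min, 1 - maf_min]`` and each founder's 4 allele copies are drawn
    independently at that frequency (Hardy-Weinberg-like independence; no
    linkage).  The realized sample MAF at a locus is *not* guaranteed to
    exceed ``maf_min``, but loci with zero dosage variance across founders
    are resampled so every locus segregates.

    Returns a list of :class:`LabeledGenome` (and, if ``return_freqs``, the
    true per-locus frequencies used).
    """
    if not 0.0 < maf_min < 0.5:
        raise SimulationError(f"maf_min must be in (0, 0.5), got {maf_min}")
    if n_loci < 1 or n_founders < 1:
        raise SimulationError("n_founders and n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_min, 1.0 - maf_min, size=n_loci)
    states = (rng.random((n_founders, n_loci, 4)) < p[None, :, None]).astype(np.uint8)
    # resample non-segregating loci (possible at extreme p with few founders)
    for _ in range(1000):
        total = states.sum(axis=(0, 2))
        dead = (total == 0) | (total == 4 * n_founders)
        if not dead.any():
            break
        k = int(dead.sum())
        p[dead] = rng.uniform(maf_min, 1.0 - maf_min, size=k)
        states[:, dead, :] = (
            rng.random((n_founders, k, 4)) < p[dead][None, :, None]
        ).astype(np.uint8)
    labels = np.arange(n_founders * n_loci * 4, dtype=np.int64).reshape(
        n_founders, n_loci, 4
    )
    founders = [
        LabeledGenome(f"P{i + 1}", states[i], labels[i]) for i in range(n_founders)
    ]
    if return_freqs:
        return founders, p
    return founders


def _sample_gametes(
    states: np.ndarray,
    labels: np.ndarray,
    n: int,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised gamete draw: returns (n, n_loci, 2) states and labels."""
    n_loci = states.shape[0]
    if alpha > 0:
        dr = rng.random((n, n_loci)) < alpha
    else:
        dr = np.zeros((n, n_loci), dtype=bool)
    pair = rng.integers(0, 6, size=(n, n_loci))
    i1 = _PAIRS[pair, 0]
    i2 = _PAIRS[pair, 1]
    if alpha > 0:
        single = rng.integers(0, 4, size=(n, n_loci))
        i1 = np.where(dr, single, i1)
        i2 = np.where(dr, single, i2)
    loci = np.arange(n_loci)[None, :]
    g_states = np.stack([states[loci, i1], states[loci, i2]], axis=-1)
    g_labels = np.stack([labels[loci, i1], labels[loci, i2]], axis=-1)
    return g_states, g_labels


def _rng_from(model: GameteModel, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(model.rng_seed)


def make_gamete(
    parent: LabeledGenome,
    model: GameteModel,
    rng: np.random.Generator | None = None,
) -> Gamete:
    """Sample one gamete (2 allele records per locus) from ``parent``."""
    rng = _rng_from(model, rng)
    gs, gl = _sample_gametes(
        parent.states, parent.labels, 1, model.double_reduction_alpha, rng
    )
    return Gamete(gs[0], gl[0])


def _offspring_batch(
    s1: np.ndarray, l1: np.ndarray, s2: np.ndarray, l2: np.ndarray, ids: Sequence[str]
) -> list[LabeledGenome]:
    states = np.concatenate([s1, s2], axis=-1)
    labels = np.concatenate([l1, l2], axis=-1)
    return [LabeledGenome(i, states[k], labels[k]) for k, i in enumerate(ids)]


def self_fertilize(
    parent: LabeledGenome,
    n_offspring: int,
    model: GameteModel,
    rng: np.random.Generator | None = None,
    id_prefix: str | None = None,
) -> list[LabeledGenome]:
    """Self ``parent``: each offspring is the union of two independent gametes."""
    if n_offspring < 1:
        raise SimulationError(f"n_offspring must be >= 1, got {n_offspring}")
    rng = _rng_from(model, rng)
    a = model.double_reduction_alpha
    s1, l1 = _sample_gametes(parent.states, parent.labels, n_offspring, a, rng)
    s2, l2 = _sample_gametes(parent.states, parent.labels, n_offspring, a, rng)
    prefix = id_prefix or f"S1-{parent.id}"
    ids = [f"{prefix}-{k + 1:03d}" for k in range(n_offspring)]
    return _offspring_batch(s1, l1, s2, l2, ids)


def cross(
    p1: LabeledGenome,
    p2: LabeledGenome,
    n_offspring: int,
    model: GameteModel,
    rng: np.random.Generator | None = None,
    id_prefix: str | None = None,
) -> list[LabeledGenome]:
    """Cross two parents: each offspring takes one gamete from each."""
    if n_offspring < 1:
        raise SimulationError(f"n_offspring must be >= 1, got {n_offspring}")
    if p1.n_loci != p2.n_loci:
        raise SimulationError("parents have different locus counts")
    rng = _rng_from(model, rng)
    a = model.double_reduction_alpha
    s1, l1 = _sample_gametes(p1.states, p1.labels, n_offspring, a, rng)
    s2, l2 = _sample_gametes(p2.states, p2.labels, n_offspring, a, rng)
    prefix = id_prefix or f"F1-{p1.id}x{p2.id}"
    ids = [f"{prefix}-{k + 1:03d}" for k in range(n_offspring)]
    return _offspring_batch(s1, l1, s2, l2, ids)


@dataclass
class TraitModel:
    """Generative model for one plot-level trait.

    ``id_coefficient`` is the penalty per unit realized IBD homozygosity
    (directional-dominance proxy for inbreeding depression): a positive
    value depresses inbred offspring, a negative one models traits that
    worsen (increase) under inbreeding, e.g. reducing sugars.
    """

    name: str
    additive_effects: np.ndarray
    id_coefficient: float
    block_effects: np.ndarray
    residual_sd: float
    intercept: float

    def __post_init__(self) -> None:
        self.additive_effects = np.asarray(self.additive_effects, dtype=float)
        self.block_effects = np.asarray(self.block_effects, dtype=float)
        if self.residual_sd < 0:
            raise SimulationError("residual_sd must be >= 0")

    def genotypic_value(self, genome: LabeledGenome) -> float:
        """Expected plot value net of block and residual effects."""
        if genome.n_loci != self.additive_effects.size:
            raise SimulationError("trait effects do not match locus count")
        g = float(genome.dosage @ self.additive_effects)
        return self.intercept + g - self.id_coefficient * realized_homozygosity(genome)


@dataclass
class StudyDesignConfig:
    """Study-scale configuration mirroring the trial this package emulates.

    Defaults: 4 founder cultivars genotyped at ~2000 SNPs (MAF >= 1%), one
    S1 family per founder, two F1 families sharing founder P1 as the common
    female parent (half-sibs), and 9 incomplete blocks each holding one plot
    of every check plus up to 100 unreplicated test plots.
    """

    n_founders: int = 4
    n_loci: int = 2000
    maf_min: float = 0.01
    n_blocks: int = 9
    checks_per_block: int | None = None  # default: all founders are checks
    test_plots_per_block: int = 100
    s1_family_sizes: tuple[int, ...] | int = 100
    f1_crosses: tuple[tuple[int, int], ...] = ((0, 1), (0, 2))
    f1_family_sizes: tuple[int, ...] | int = 100
    seed: int = 2020

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_loci", "n_blocks", "test_plots_per_block"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be positive")
        if not 0.0 < self.maf_min < 0.5:
            raise SimulationError("maf_min must be in (0, 0.5)")
        if isinstance(self.s1_family_sizes, int):
            self.s1_family_sizes = (self.s1_family_sizes,) * self.n_founders
        if isinstance(self.f1_family_sizes, int):
            self.f1_family_sizes = (self.f1_family_sizes,) * len(self.f1_crosses)
        if len(self.s1_family_sizes) != self.n_founders:
            raise SimulationError("need one S1 family size per founder")
        if len(self.f1_family_sizes) != len(self.f1_crosses):
            raise SimulationError("need one F1 family size per cross")
        for a, b in self.f1_crosses:
            if not (0 <= a < self.n_founders and 0 <= b < self.n_founders):
                raise SimulationError("f1_crosses indexes founders out of range")


_TRAIT_SPECS = [
    # name, intercept, genetic sd, residual sd, id drop at F=1/6 (units)
    ("weight_lt25mm", 45.0, 15.0, 20.0, -15.0),
    ("weight_25_40mm", 400.0, 90.0, 120.0, 120.0),
    ("weight_40_50mm", 800.0, 180.0, 220.0, 450.0),
    ("weight_50_60mm", 1000.0, 250.0, 280.0, 750.0),
    ("weight_gt60mm", 500.0, 180.0, 200.0, 420.0),
    ("weight_total", 2800.0, 450.0, 500.0, 2100.0),
    ("shape_uniformity", 5.6, 0.5, 0.7, 0.05),
    ("size_uniformity", 5.6, 0.5, 0.7, 1.0),
    ("eye_depth", 5.2, 0.5, 0.6, 0.9),
    ("reducing_sugar", 0.10, 0.15, 0.20, -0.35),
]


def default_trait_models(
    n_loci: int,
    n_blocks: int,
    seed: int,
    freqs: np.ndarray | None = None,
) -> list[TraitModel]:
    """Ten tuber traits with additive genetics and directional inbreeding load.

    Scales follow a four-plant-plot potato trial: total tuber weight of
    ~2800 g per plot with plot-level h2 near 0.4, heavy inbreeding
    depression on the weight traits (the selfed generation loses most of its
    large-tuber yield), mild effects on the 1-9 uniformity/eye-depth scores,
    and *negative* penalties where inbreeding increases the trait (small
    tubers, reducing sugars).  Additive marker effects are i.i.d. normal,
    scaled so the founder-population genetic variance hits the target.
    """
    rng = np.random.default_rng(seed)
    if freqs is None:
        var_per_locus = 0.68  # E[4p(1-p)] for p ~ U(0.01, 0.99)
        dosage_var = var_per_locus * n_loci
    else:
        dosage_var = float(np.sum(4.0 * freqs * (1.0 - freqs)))
    models = []
    for name, intercept, g_sd, e_sd, drop in _TRAIT_SPECS:
        effects = rng.normal(0.0, g_sd / np.sqrt(dosage_var), size=n_loci)
        if freqs is not None:
            # centre the additive values so the founder-population mean sits
            # at the intercept (keeps proportional statistics interpretable)
            intercept = intercept - float((4.0 * freqs) @ effects)
        blocks = rng.normal(0.0, 0.3 * e_sd, size=n_blocks)
        models.append(
            TraitModel(
                name=name,
                additive_effects=effects,
                id_coefficient=drop * 6.0,  # penalty per unit F; F(S1)=1/6
                block_effects=blocks,
                residual_sd=e_sd,
                intercept=intercept,
            )
        )
    return models


def simulate_study(
    config: StudyDesignConfig,
    trait_models: list[TraitModel] | None = None,
    gamete_model: GameteModel | None = None,
):
    """Simulate the full study: genotypes, augmented field trial, pedigree.

    Builds founders, one S1 family per founder and the configured F1
    families (default: two sharing a common female parent, hence half-sibs),
    lays them out on the augmented design and generates plot phenotypes.

    Returns
    -------
    (DosageMatrix, FieldTrial, pandas.DataFrame)
        Genotypes of all individuals, the plot-level trial and a pedigree
        table with columns id, parent1, parent2, generation, family,
        is_check.
    """
    from .io import DosageMatrix, FieldTrial

    gamete_model = gamete_model or GameteModel()
    rng = np.random.default_rng(config.seed)
    founders, freqs = simulate_founders(
        config.n_founders,
        config.n_loci,
        config.maf_min,
        seed=int(rng.integers(2**31)),
        return_freqs=True,
    )
    if trait_models is None:
        trait_models = default_trait_models(
            config.n_loci, config.n_blocks, seed=int(rng.integers(2**31)), freqs=freqs
        )
    for tm in trait_models:
        if tm.additive_effects.size != config.n_loci:
            raise SimulationError(f"trait {tm.name}: effect count != n_loci")
        if tm.block_effects.size != config.n_blocks:
            raise SimulationError(f"trait {tm.name}: block effect count != n_blocks")

    pedigree_rows = []
    for f in founders:
        pedigree_rows.append((f.id, "", "", "S0", "S0", True))

    offspring: list[LabeledGenome] = []
    for i, f in enumerate(founders):
        fam = self_fertilize(f, config.s1_family_sizes[i], gamete_model, rng=rng)
        for g in fam:
            pedigree_rows.append((g.id, f.id, f.id, "S1", f"S1-{f.id}", False))
        offspring.extend(fam)
    for k, (a, b) in enumerate(config.f1_crosses):
        fam = cross(founders[a], founders[b], config.f1_family_sizes[k], gamete_model, rng=rng)
        for g in fam:
            pedigree_rows.append(
                (g.id, founders[a].id, founders[b].id, "F1",
                 f"F1-{founders[a].id}x{founders[b].id}", False)
            )
        offspring.extend(fam)

    n_tests = len(offspring)
    capacity = config.n_blocks * config.test_plots_per_block
    if n_tests > capacity:
        raise SimulationError(
            f"{n_tests} test entries exceed {capacity} available test plots"
        )

    everyone = founders + offspring
    dosages = np.stack([g.dosage for g in everyone]).astype(float)
    snp_ids = [f"snp{j + 1:05d}" for j in range(config.n_loci)]
    dm = DosageMatrix([g.id for g in everyone], snp_ids, dosages)

    genos = {g.id: g for g in everyone}
    gvals = {
        tm.name: {g.id: tm.genotypic_value(g) for g in everyone} for tm in trait_models
    }

    # layout: each check once per block, each test entry exactly one plot
    order = rng.permutation(n_tests)
    plots = []
    cursor = 0
    per_block = int(np.ceil(n_tests / config.n_blocks))
    for j in range(config.n_blocks):
        plot_no = 1
        for f in founders:
            plots.append((f.id, j + 1, plot_no, True))
            plot_no += 1
        take = min(per_block, config.test_plots_per_block, n_tests - cursor)
        for t in range(take):
            g = offspring[order[cursor]]
            plots.append((g.id, j + 1, plot_no, False))
            plot_no += 1
            cursor += 1
    assert cursor == n_tests

    records = []
    for entry, block, plot, is_check in plots:
        row = {"entry": entry, "block": block, "plot": plot, "is_check": is_check}
        for tm in trait_models:
            val = (
                gvals[tm.name][entry]
                + tm.block_effects[block - 1]
                + (rng.normal(0.0, tm.residual_sd) if tm.residual_sd > 0 else 0.0)
            )
            row[tm.name] = val
        records.append(row)
    trial = FieldTrial(pd.DataFrame.from_records(records))
    pedigree = pd.DataFrame(
        pedigree_rows,
        columns=["id", "parent1", "parent2", "generation", "family", "is_check"],
    )
    return dm, trial, pedigree
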