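"""Tetrasomic gamete law, IBD bookkeeping and study-generator invariants."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tetrablup.simulate import (
    GameteModel,
    LabeledGenome,
    SimulationError,
    StudyDesignConfig,
    TraitModel,
    coancestry,
    cross,
    default_trait_models,
    make_gamete,
    realized_homozygosity,
    self_fertilize,
    simulate_founders,
    simulate_study,
)


def exact_gamete_dosage_pmf(parent_states: np.ndarray, alpha: float) -> dict:
    """Enumeration oracle: gamete dosage law for one locus.

    With prob 1-alpha each of the C(4,2)=6 unordered pairs is equally
    likely; with prob alpha the gamete doubles one of the 4 allele copies.
    """
    pmf = {0: 0.0, 1: 0.0, 2: 0.0}
    for i, j in itertools.combinations(range(4), 2):
        pmf[int(parent_states[i] + parent_states[j])] += (1.0 - alpha) / 6.0
    for i in range(4):
        pmf[int(2 * parent_states[i])] += alpha / 4.0
    return pmf


def _single_locus_parent(states4) -> LabeledGenome:
    states = np.array([states4], dtype=np.uint8)
    labels = np.arange(4, dtype=np.int64)[None, :]
    return LabeledGenome("p", states, labels)


class TestFounders:
    def test_shapes_dosage_range_and_determinism(self):
        a = simulate_founders(4, 300, 0.01, seed=1)
        b = simulate_founders(4, 300, 0.01, seed=1)
        assert len(a) == 4 and a[0].n_loci == 300
        for g in a:
            assert g.dosage.min() >= 0 and g.dosage.max() <= 4
        assert all(
            np.array_equal(x.states, y.states) and np.array_equal(x.labels, y.labels)
            for x, y in zip(a, b)
        )

    def test_every_locus_segregates(self):
        founders = simulate_founders(4, 500, 0.01, seed=3)
        total = sum(g.dosage for g in founders)
        assert (total > 0).all() and (total < 16).all()

    def test_founder_labels_unique_and_f_zero(self):
        founders = simulate_founders(3, 50, 0.1, seed=2)
        labs = np.concatenate([g.labels.ravel() for g in founders])
        assert len(np.unique(labs)) == labs.size
        assert all(realized_homozygosity(g) == 0.0 for g in founders)

    @pytest.mark.parametrize("bad", [0.6, 0.0, -0.1, 0.5])
    def test_invalid_maf_rejected(self, bad):
        with pytest.raises(SimulationError):
            simulate_founders(4, 10, bad, seed=1)


class TestGameteLaw:
    # representative allele arrangements for each dosage class
    ARRANGEMENTS = {
        0: (0, 0, 0, 0),
        1: (1, 0, 0, 0),
        2: (1, 1, 0, 0),
        3: (1, 1, 1, 0),
        4: (1, 1, 1, 1),
    }

    def test_duplex_exact_pmfs(self):
        duplex = np.array([1, 1, 0, 0])
        assert exact_gamete_dosage_pmf(duplex, 0.0) == {
            0: pytest.approx(1 / 6),
            1: pytest.approx(4 / 6),
            2: pytest.approx(1 / 6),
        }
        assert exact_gamete_dosage_pmf(duplex, 1.0) == {
            0: pytest.approx(1 / 2),
            1: 0.0,
            2: pytest.approx(1 / 2),
        }

    @pytest.mark.parametrize("dosage", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_simulated_matches_enumeration(self, dosage, alpha):
        parent = _single_locus_parent(self.ARRANGEMENTS[dosage])
        model = GameteModel(double_reduction_alpha=alpha)
        rng = np.random.default_rng(100 + dosage)
        n = 4000
        counts = np.zeros(3)
        draws = np.array(
            [make_gamete(parent, model, rng).dosage[0] for _ in range(n)]
        )
        for d in range(3):
            counts[d] = (draws == d).sum()
        pmf = exact_gamete_dosage_pmf(parent.states[0], alpha)
        expected = np.array([pmf[d] * n for d in range(3)])
        keep = expected > 0
        assert counts[~keep].sum() == 0  # impossible classes never drawn
        if keep.sum() > 1:
            p = stats.chisquare(counts[keep], expected[keep]).pvalue
            assert p > 1e-3

    def test_quadriplex_gamete_always_duplex(self):
        parent = _single_locus_parent((1, 1, 1, 1))
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert make_gamete(parent, GameteModel(0.3), rng).dosage[0] == 2


class TestOffspring:
    def test_offspring_dosage_is_gamete_sum_and_in_range(self):
        founders = simulate_founders(2, 80, 0.1, seed=5)
        rng = np.random.default_rng(1)
        kids = cross(founders[0], founders[1], 30, GameteModel(0.2), rng=rng)
        for kid in kids:
            d = kid.dosage
            assert d.min() >= 0 and d.max() <= 4
            # each half of the genome came from one parent
            assert np.array_equal(
                d, kid.states[:, :2].sum(axis=1) + kid.states[:, 2:].sum(axis=1)
            )

    def test_nulliplex_by_quadriplex_gives_duplex(self):
        L = 30
        p0 = LabeledGenome("a", np.zeros((L, 4)), np.arange(4 * L).reshape(L, 4))
        p1 = LabeledGenome(
            "b", np.ones((L, 4)), (np.arange(4 * L) + 4 * L).reshape(L, 4)
        )
        kids = cross(p0, p1, 5, GameteModel(), rng=np.random.default_rng(0))
        for kid in kids:
            assert (kid.dosage == 2).all()

    def test_nulliplex_selfed_stays_nulliplex(self):
        L = 25
        p = LabeledGenome("a", np.zeros((L, 4)), np.arange(4 * L).reshape(L, 4))
        kids = self_fertilize(p, 10, GameteModel(), rng=np.random.default_rng(0))
        assert all((k.dosage == 0).all() for k in kids)

    @pytest.mark.parametrize("n", [0, -3])
    def test_offspring_count_must_be_positive(self, n):
        (p,) = simulate_founders(1, 10, 0.1, seed=1)
        with pytest.raises(SimulationError):
            self_fertilize(p, n, GameteModel())
        with pytest.raises(SimulationError):
            cross(p, p, n, GameteModel())

    def test_selfing_inbreeding_one_sixth(self):
        """Label-counting oracle: E[F] of S1 from a non-inbred tetrasomic
        parent is 1/6 under bivalent pairing."""
        (p,) = simulate_founders(1, 200, 0.1, seed=7)
        kids = self_fertilize(p, 2000, GameteModel(), rng=np.random.default_rng(2))
        f = np.array([realized_homozygosity(k) for k in kids])
        se = f.std(ddof=1) / np.sqrt(f.size)
        assert abs(f.mean() - 1 / 6) < 3 * se

    def test_inbreeding_monotone_in_double_reduction(self):
        (p,) = simulate_founders(1, 150, 0.1, seed=8)
        means = []
        for alpha in (0.0, 0.5, 1.0):
            kids = self_fertilize(
                p, 1500, GameteModel(alpha), rng=np.random.default_rng(3)
            )
            means.append(np.mean([realized_homozygosity(k) for k in kids]))
        assert means[0] < means[1] < means[2]

    def test_outcross_f_zero_and_parent_child_coancestry(self):
        founders = simulate_founders(2, 150, 0.1, seed=9)
        rng = np.random.default_rng(4)
        kids = cross(founders[0], founders[1], 800, GameteModel(), rng=rng)
        f = np.array([realized_homozygosity(k) for k in kids])
        assert f.mean() == 0.0  # parental labels are all distinct
        # each selfed-child allele copies exactly one of the parent's 4
        # distinct labels, so realized theta is exactly 4/16 = 1/4
        selfed = self_fertilize(founders[0], 50, GameteModel(), rng=rng)
        theta = np.array([coancestry(founders[0], k) for k in selfed])
        assert theta == pytest.approx(0.25)
        # an outcross child carries 2 alleles from each parent: theta = 1/8
        theta_x = np.array([coancestry(founders[0], k) for k in kids[:50]])
        assert theta_x == pytest.approx(0.125)


class TestStudy:
    def test_layout_invariants(self, small_study):
        cfg, dm, trial, ped = small_study
        df = trial.df
        checks = df[df["is_check"]]
        # every check exactly once per block
        counts = checks.groupby(["entry", "block"]).size()
        assert (counts == 1).all()
        assert set(checks["entry"]) == {"P1", "P2", "P3", "P4"}
        # test entries exactly once overall
        tests = df[~df["is_check"]]
        assert tests["entry"].value_counts().eq(1).all()
        assert len(tests) == 4 * 18 + 2 * 18

    def test_halfsib_f1_families_share_female_parent(self, small_study):
        _, _, _, ped = small_study
        f1 = ped[ped["generation"] == "F1"]
        assert set(f1["parent1"]) == {"P1"}
        assert set(f1["family"]) == {"F1-P1xP2", "F1-P1xP3"}

    def test_determinism(self):
        cfg = dict(n_loci=60, s1_family_sizes=5, f1_family_sizes=5,
                   test_plots_per_block=5, seed=3)
        a = simulate_study(StudyDesignConfig(**cfg))
        b = simulate_study(StudyDesignConfig(**cfg))
        assert a[0] == b[0]
        assert a[1].df.equals(b[1].df)
        assert a[2].equals(b[2])

    def test_capacity_error(self):
        cfg = StudyDesignConfig(
            n_loci=30, s1_family_sizes=50, f1_family_sizes=50,
            test_plots_per_block=10, seed=1,
        )
        with pytest.raises(SimulationError, match="exceed"):
            simulate_study(cfg)

    def test_noise_free_plot_values_are_exactly_additive(self):
        cfg = StudyDesignConfig(
            n_loci=40, s1_family_sizes=4, f1_family_sizes=4,
            test_plots_per_block=8, n_blocks=3, seed=5,
        )
        rng = np.random.default_rng(0)
        effects = rng.normal(0, 0.1, 40)
        tm = TraitModel(
            name="t", additive_effects=effects, id_coefficient=0.0,
            block_effects=np.zeros(3), residual_sd=0.0, intercept=1.5,
        )
        dm, trial, ped = simulate_study(cfg, trait_models=[tm])
        dos = dm.to_dataframe()
        for _, row in trial.df.iterrows():
            expected = 1.5 + float(dos.loc[row["entry"]].to_numpy() @ effects)
            assert row["t"] == pytest.approx(expected, abs=1e-10)

    def test_inbreeding_penalty_depresses_s1_family_means(self):
        """With a positive ID coefficient and no residual noise, every S1
        family mean falls below its parent's genotypic value."""
        cfg = StudyDesignConfig(
            n_loci=80, s1_family_sizes=200, f1_family_sizes=4,
            test_plots_per_block=100, seed=6,
        )
        rng = np.random.default_rng(1)
        tm = TraitModel(
            name="t", additive_effects=rng.normal(0, 0.05, 80),
            id_coefficient=30.0, block_effects=np.zeros(9),
            residual_sd=0.0, intercept=10.0,
        )
        dm, trial, ped = simulate_study(cfg, trait_models=[tm])
        df = trial.df.set_index("entry")
        ped = ped.set_index("id")
        for parent in ("P1", "P2", "P3", "P4"):
            parent_value = float(df.loc[parent, "t"].mean())
            fam = [i for i in ped.index
                   if ped.loc[i, "family"] == f"S1-{parent}"]
            fam_mean = float(df.loc[fam, "t"].mean())
            assert fam_mean < parent_value

    def test_trait_model_validation(self):
        with pytest.raises(SimulationError):
            TraitModel("t", np.zeros(5), 0.0, np.zeros(2), residual_sd=-1.0,
                       intercept=0.0)
        models = default_trait_models(100, 9, seed=1)
        assert len(models) == 10
        assert all(m.additive_effects.size == 100 for m in models)
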