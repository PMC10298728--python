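"""Augmented-design adjustment, ANOVA, contrasts and program summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tetrablup.design import (
    CrossRecord,
    DesignError,
    adjust,
    anova_and_lsd,
    compute_correction_factors,
    generation_contrasts,
    proportional_inbreeding_depression,
    summarize_program,
    validate_design,
)
from tetrablup.io import FieldTrial


def make_trial(check_values, test_values=None, rng=None):
    """Build a trial from a (checks x blocks) array of check plot values.

    ``test_values`` optionally maps entry -> (block, value).
    """
    check_values = np.asarray(check_values, dtype=float)
    g, r = check_values.shape
    rows = []
    for i in range(g):
        for j in range(r):
            rows.append(
                {"entry": f"c{i + 1}", "block": j + 1, "plot": i + 1,
                 "is_check": True, "y": check_values[i, j]}
            )
    plot = g + 1
    for entry, (block, value) in (test_values or {}).items():
        rows.append(
            {"entry": entry, "block": block, "plot": plot, "is_check": False,
             "y": value}
        )
        plot += 1
    return FieldTrial(pd.DataFrame.from_records(rows))


class TestCorrectionFactors:
    def test_hand_computed_two_by_two(self):
        # block check means 12 and 8, grand mean 10 -> CF = {+2, -2}
        trial = make_trial([[10, 6], [14, 10]], {"t1": (1, 20.0)})
        cf = compute_correction_factors(trial, "y")
        assert cf.values == {1: pytest.approx(2.0), 2: pytest.approx(-2.0)}
        adj = adjust(trial, cf)
        t1 = adj.table[adj.table["entry"] == "t1"]
        assert t1["adjusted"].iloc[0] == pytest.approx(18.0)

    def test_identical_checks_give_zero_cf(self):
        trial = make_trial([[5, 5, 5], [7, 7, 7]])
        cf = compute_correction_factors(trial, "y")
        assert all(v == pytest.approx(0.0) for v in cf.values.values())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**32 - 1))
    def test_cf_sums_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        g, r = rng.integers(2, 6, size=2)
        trial = make_trial(rng.normal(10, 3, size=(g, r)))
        cf = compute_correction_factors(trial, "y")
        assert sum(cf.values.values()) == pytest.approx(0.0, abs=1e-9)

    def test_per_block_shift_leaves_adjusted_tests_unchanged(self):
        rng = np.random.default_rng(7)
        checks = rng.normal(10, 2, size=(3, 4))
        tests = {f"t{k}": (k % 4 + 1, float(rng.normal(12, 2))) for k in range(8)}
        base = adjust(
            make_trial(checks, tests), compute_correction_factors(make_trial(checks, tests), "y")
        )
        shifted_checks = checks.copy()
        shifted_checks[:, 1] += 5.0  # block 2 uniformly shifted
        shifted_tests = {
            k: (b, v + (5.0 if b == 2 else 0.0)) for k, (b, v) in tests.items()
        }
        trial2 = make_trial(shifted_checks, shifted_tests)
        shifted = adjust(trial2, compute_correction_factors(trial2, "y"))
        a = base.table.set_index("entry")["adjusted"]
        b = shifted.table.set_index("entry")["adjusted"]
        # the block shift is absorbed by its CF up to the grand-check-mean
        # term k/r, which moves every adjusted value by the same constant,
        # so all comparisons among adjusted entries are invariant
        deltas = np.array([b[k] - a[k] for k in tests])
        assert deltas == pytest.approx(deltas[0])
        assert deltas[0] == pytest.approx(5.0 / 4.0)

    def test_adjusted_check_means_equal_across_blocks(self):
        rng = np.random.default_rng(3)
        trial = make_trial(rng.normal(0, 1, size=(4, 5)))
        adj = adjust(trial, compute_correction_factors(trial, "y"))
        # after adjustment the block means of the checks coincide
        blk = adj.table[adj.table["is_check"]].groupby("block")["adjusted"].mean()
        assert blk.std() == pytest.approx(0.0, abs=1e-9)


class TestDesignRule:
    @pytest.mark.parametrize(
        "c,r,expected", [(3, 9, True), (3, 6, False), (2, 11, False), (2, 12, True)]
    )
    def test_error_df_rule(self, c, r, expected):
        assert bool(validate_design(c, r)) is expected


class TestAnova:
    def test_zero_residual_checks_give_zero_mse_and_lsd(self):
        # additive check and block effects, no noise
        checks = np.add.outer([1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0])
        res = anova_and_lsd(make_trial(checks), "y")
        assert res.mse == pytest.approx(0.0, abs=1e-18)
        assert res.lsd_0_05 == pytest.approx(0.0, abs=1e-9)

    def test_matches_statsmodels_two_way_anova(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(11)
        checks = rng.normal(10, 2, size=(3, 4))
        trial = make_trial(checks)
        res = anova_and_lsd(trial, "y")
        df = trial.df[trial.df["is_check"]]
        fit = smf.ols("y ~ C(entry) + C(block)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.ss_checks == pytest.approx(tab.loc["C(entry)", "sum_sq"])
        assert res.ss_blocks == pytest.approx(tab.loc["C(block)", "sum_sq"])
        assert res.ss_error == pytest.approx(tab.loc["Residual", "sum_sq"])
        assert res.df_error == int(tab.loc["Residual", "df"])

    def test_mse_within_chi2_interval_of_true_variance(self):
        sigma = 1.7
        rng = np.random.default_rng(5)
        g, r = 4, 9
        checks = (
            np.add.outer(rng.normal(0, 3, g), rng.normal(0, 2, r))
            + rng.normal(0, sigma, size=(g, r))
        )
        res = anova_and_lsd(make_trial(checks), "y")
        df = res.df_error
        lo = sigma**2 * stats.chi2.ppf(0.005, df) / df
        hi = sigma**2 * stats.chi2.ppf(0.995, df) / df
        assert lo < res.mse < hi

    def test_single_block_has_no_error_df(self):
        with pytest.raises(DesignError, match="df"):
            anova_and_lsd(make_trial([[1.0], [2.0]]), "y")


def _null_trial(rng, g=3, r=6, tests_per_block=6):
    """A trial with no genetic signal: block effects + iid noise only."""
    blocks = rng.normal(0, 2, r)
    checks = blocks[None, :] + rng.normal(0, 1, size=(g, r))
    tests = {}
    k = 0
    for j in range(r):
        for _ in range(tests_per_block):
            tests[f"t{k}"] = (j + 1, float(blocks[j] + rng.normal(0, 1)))
            k += 1
    return make_trial(checks, tests)


def _null_pedigree(trial):
    rows = []
    for c in trial.checks:
        rows.append((c, "", "", "S0", "S0", True))
    tests = sorted(trial.df.loc[~trial.df["is_check"], "entry"])
    half = len(tests) // 2
    for i, t in enumerate(tests):
        gen = "S1" if i < half else "F1"
        rows.append((t, "c1", "c2", gen, f"{gen}-fam", False))
    return pd.DataFrame(
        rows, columns=["id", "parent1", "parent2", "generation", "family", "is_check"]
    )


class TestContrasts:
    def test_identical_groups_give_zero_contrast(self):
        rng = np.random.default_rng(0)
        trial = _null_trial(rng)
        # overwrite: every plot takes the same value
        df = trial.df.copy()
        df["y"] = 5.0
        trial = FieldTrial(df)
        ped = _null_pedigree(trial)
        adj = adjust(trial, compute_correction_factors(trial, "y"))
        an = anova_and_lsd(trial, "y")
        gc = generation_contrasts(adj, ped, anova=an)
        for c in gc.contrasts.values():
            assert c.estimate == pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_near_nominal_under_null(self):
        """With no group differences, each contrast rejects at ~5%."""
        rng = np.random.default_rng(42)
        n_sim = 200
        rejections = np.zeros(3)
        for _ in range(n_sim):
            trial = _null_trial(rng)
            ped = _null_pedigree(trial)
            adj = adjust(trial, compute_correction_factors(trial, "y"))
            gc = generation_contrasts(adj, ped)
            for k, c in enumerate(gc.contrasts.values()):
                rejections[k] += c.p_value < 0.05
        rate = rejections / n_sim
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert np.all(np.abs(rate - 0.05) < 3 * se + 1e-9), rate

    def test_simulated_inbreeding_depression_detected(self, small_study):
        _, _, trial, ped = small_study
        adj = adjust(trial, compute_correction_factors(trial, "weight_total"))
        gc = generation_contrasts(adj, ped)
        c = gc.contrasts["S0_vs_S1"]
        assert c.estimate > 0 and c.p_value < 0.01
        assert 0 < gc.proportional_inbreeding_depression < 1

    def test_proportional_id_arithmetic(self):
        assert proportional_inbreeding_depression([4.0], [1.0]) == pytest.approx(0.75)
        with pytest.raises(DesignError):
            proportional_inbreeding_depression([0.0], [1.0])

    def test_heterosis_fractions(self, small_study):
        _, _, trial, ped = small_study
        adj = adjust(trial, compute_correction_factors(trial, "weight_total"))
        gc = generation_contrasts(adj, ped)
        assert set(gc.heterosis) == {"F1-P1xP2", "F1-P1xP3"}
        for h in gc.heterosis.values():
            assert 0.0 <= h["frac_above_best_parent"] <= 1.0

    def test_s1_family_filter(self, small_study):
        _, _, trial, ped = small_study
        adj = adjust(trial, compute_correction_factors(trial, "weight_total"))
        full = generation_contrasts(adj, ped)
        subset = generation_contrasts(adj, ped, s1_families=["S1-P1", "S1-P2"])
        assert subset.group_sizes["S1"] < full.group_sizes["S1"]


class TestProgramSummary:
    def test_overall_crossing_success(self):
        s = summarize_program([CrossRecord("any", flowers=434, berries=170)])
        assert s.crossing_success_pct == pytest.approx(100 * 170 / 434)
        assert round(s.crossing_success_pct) == 39

    def test_per_parent_and_seed_set(self):
        recs = [
            CrossRecord("A", 100, 82, seeds=120, type="self"),
            CrossRecord("B", 50, 50, seeds=90, type="self"),
            CrossRecord("A", 60, 45, seeds=150, type="cross"),
        ]
        s = summarize_program(recs)
        assert s.per_parent_berry_pct["A"] == pytest.approx(100 * (82 + 45) / 160)
        assert s.seed_set["self"]["mean"] == pytest.approx(105.0)
        assert s.seed_set["self"]["n"] == 2
        assert math.isnan(s.seed_set["cross"]["sd"])  # single record

    def test_zero_flowers_rejected(self):
        with pytest.raises(DesignError):
            summarize_program([CrossRecord("A", 0, 0)])
        with pytest.raises(DesignError):
            summarize_program([])
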