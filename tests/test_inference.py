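"""Covariate regression, permutation testing, FDR, and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from fibergraph import (
    CohortConfig,
    compare_global,
    compare_local,
    compare_regional,
    fdr_correct,
    generate_cohort,
    permutation_test,
    regress_covariates,
)

from _oracles import bh_stepup


@pytest.fixture
def covariates(rng):
    n = 42
    return pd.DataFrame(
        {
            "age": rng.normal(70, 7, n),
            "gender": rng.integers(0, 2, n),
            "education": rng.normal(10, 3, n),
            "icv": rng.normal(1.45e6, 1.3e5, n),
        }
    )


class TestRegression:
    def test_residuals_orthogonal_to_covariates(self, rng, covariates):
        y = rng.normal(size=len(covariates))
        resid = regress_covariates(y, covariates)
        assert abs(resid.mean()) < 1e-10
        for col in covariates:
            x = covariates[col].to_numpy(dtype=float)
            assert abs(np.corrcoef(resid, x)[0, 1]) < 1e-10

    def test_planted_age_effect_removed(self, rng, covariates):
        y = 2.0 * covariates["age"].to_numpy() + rng.normal(0, 0.5, len(covariates))
        resid = regress_covariates(y, covariates)
        assert abs(np.corrcoef(resid, covariates["age"])[0, 1]) < 1e-10
        assert resid.std() < 1.0  # the age signal is gone

    def test_constant_measure_gives_zero_residuals(self, covariates):
        resid = regress_covariates(np.full(len(covariates), 3.7), covariates)
        assert np.allclose(resid, 0, atol=1e-10)

    def test_collinear_design_rejected_with_names(self, rng, covariates):
        covariates = covariates.copy()
        covariates["icv"] = 2.0 * covariates["age"]
        with pytest.raises(ValueError, match="age.*icv|icv.*age"):
            regress_covariates(rng.normal(size=len(covariates)), covariates)

    def test_cohort_too_small_rejected(self, covariates):
        small = covariates.iloc[:5]
        with pytest.raises(ValueError, match="too small"):
            regress_covariates(np.zeros(5), small)


class TestPermutationTest:
    def test_zero_difference_gives_p_one(self):
        resid = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        groups = ["A", "B", "A", "B", "A", "B"]
        resid = resid - resid.mean()
        # construct exact zero observed difference
        resid = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])
        p, diff = permutation_test(resid, groups, n_perm=500, seed=3)
        assert diff == pytest.approx(0.0)
        assert p == 1.0

    def test_extreme_separation_reaches_minimum_p(self, rng):
        groups = ["A"] * 10 + ["B"] * 10
        resid = np.concatenate([rng.normal(0, 1, 10), rng.normal(100, 1, 10)])
        n_perm = 400
        p, diff = permutation_test(resid, groups, n_perm=n_perm, seed=5)
        assert diff < 0 or diff > 0
        assert p == pytest.approx(1 / (n_perm + 1))

    def test_reproducible_and_affine_invariant(self, rng):
        groups = ["A"] * 8 + ["B"] * 8
        resid = rng.normal(size=16)
        p1, _ = permutation_test(resid, groups, n_perm=300, seed=11)
        p2, _ = permutation_test(resid, groups, n_perm=300, seed=11)
        assert p1 == p2
        p3, _ = permutation_test(3.5 * resid + 2.0, groups, n_perm=300, seed=11)
        assert p3 == p1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two group"):
            permutation_test(np.zeros(6), ["A"] * 6, n_perm=10, seed=1)

    def test_null_p_values_roughly_uniform(self, rng):
        """Type-I calibration at reduced scale (the acceptance suite runs
        the full 200-cohort version)."""
        groups = ["A"] * 16 + ["B"] * 26
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            resid = rng.normal(size=42)
            p, _ = permutation_test(resid, groups, n_perm=200, seed=rep)
            rejections += p < 0.05
        assert 0.0 <= rejections / n_rep <= 0.12


class TestFdr:
    def test_empty_input_gives_empty_output(self):
        assert fdr_correct(np.array([])).size == 0

    def test_all_tiny_p_all_significant(self):
        assert fdr_correct(np.full(10, 0.001), q=0.05).all()

    def test_all_p_one_none_significant(self):
        assert not fdr_correct(np.ones(10), q=0.05).any()

    def test_matches_stepup_oracle(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.26])
        expected = bh_stepup(p, 0.05)
        assert np.array_equal(fdr_correct(p, q=0.05), expected)
        # frozen from the oracle: only the two smallest survive step-up
        assert expected.tolist() == [True, True, False, False, False]

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0.001, 1, size=50)
        flags = fdr_correct(p, q=0.1)
        if flags.any():
            assert p[flags].max() <= p[~flags].min() or not (~flags).any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.0, 0.5]))


def _cohort(seed, **kw):
    return generate_cohort(CohortConfig(seed=seed, **kw))


class TestCompareGlobal:
    def test_planted_deficit_detected_with_negative_sign(self):
        cohort = _cohort(
            101,
            n_ad=20,
            n_nc=20,
            affected_nodes=tuple(range(1, 11)),
            effect_multiplier=0.5,
        )
        table = compare_global(
            cohort,
            measures=("e_glob", "e_loc"),
            n_nulls=0,
            n_perm=1000,
            seed=5,
        )
        eg = table[table.measure == "e_glob"].iloc[0]
        assert eg["mean_AD"] < eg["mean_NC"]
        assert eg["difference"] < 0
        assert eg["p_value"] < 0.05

    def test_single_group_rejected(self):
        cohort = [s for s in _cohort(102, n_ad=6, n_nc=2) if s.group == "AD"]
        with pytest.raises(ValueError, match="two group"):
            compare_global(cohort, measures=("e_glob",), n_nulls=0, n_perm=50, seed=1)

    def test_small_world_measures_need_nulls(self):
        cohort = _cohort(103, n_ad=4, n_nc=4)
        with pytest.raises(ValueError, match="n_nulls"):
            compare_global(cohort, measures=("sigma",), n_nulls=0, n_perm=50, seed=1)

    def test_reproducible_under_fixed_seed(self):
        cohort = _cohort(104, n_ad=5, n_nc=5)
        kw = dict(measures=("e_glob", "e_loc"), n_nulls=0, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(
            compare_global(cohort, **kw), compare_global(cohort, **kw)
        )


class TestCompareRegional:
    def test_identical_matrices_give_p_one(self):
        cohort = _cohort(105, n_ad=5, n_nc=5, noise_sd=0.0)
        # zero noise and no covariate effect -> all matrices identical
        cfg_subjects = []
        template = cohort[0].matrix
        from dataclasses import replace

        for s in cohort:
            cfg_subjects.append(replace(s, matrix=template))
        table, _ = compare_regional(cfg_subjects, n_perm=200, seed=3)
        assert (table["p_value"] == 1.0).all()
        assert not table["significant"].any()

    def test_planted_nodes_recovered(self):
        planted = tuple(range(1, 11))
        cohort = _cohort(
            106, n_ad=15, n_nc=15, affected_nodes=planted, effect_multiplier=0.5
        )
        table, hubs = compare_regional(cohort, n_perm=1000, seed=4)
        sig_nodes = set(table[table.significant]["node"])
        assert len(sig_nodes & set(planted)) >= 8
        # deficits are negative in the patient group
        planted_rows = table[table.node.isin(planted)]
        assert (planted_rows["difference"] < 0).all()
        assert set(hubs) == {"AD", "NC"}

    def test_hub_lists_are_one_based_indices(self):
        cohort = _cohort(107, n_ad=4, n_nc=4)
        _, hubs = compare_regional(cohort, n_perm=50, seed=5)
        for nodes in hubs.values():
            assert all(1 <= n <= 90 for n in nodes)


class TestCompareLocal:
    def test_planted_edges_recovered_with_direction(self):
        planted_edges = tuple((i, i + 20) for i in range(1, 21))
        cohort = _cohort(
            108,
            n_ad=15,
            n_nc=15,
            affected_edges=planted_edges,
            effect_multiplier=0.5,
        )
        present = {
            (i, j)
            for i, j in planted_edges
            if cohort[0].matrix.weights[i - 1, j - 1] > 0
        }
        table = compare_local(cohort, n_perm=1000, seed=6)
        sig = table[table.significant_uncorrected]
        found = {
            (r.node_a, r.node_b)
            for r in sig.itertuples()
            if (r.node_a, r.node_b) in present
        }
        assert len(found) >= 0.8 * len(present)
        weak = sig[sig.apply(lambda r: (r.node_a, r.node_b) in present, axis=1)]
        assert (weak["direction"] == "weaker in AD").all()

    def test_absent_edges_excluded_from_testing(self):
        cohort = _cohort(109, n_ad=5, n_nc=5)
        table = compare_local(cohort, n_perm=50, seed=7)
        tested = {(r.node_a, r.node_b) for r in table.itertuples()}
        w = cohort[0].matrix.weights
        for i, j in [(a, b) for a in range(1, 91) for b in range(a + 1, 91)][:200]:
            if all(s.matrix.weights[i - 1, j - 1] == 0 for s in cohort):
                assert (i, j) not in tested

    def test_effect_free_cohort_false_positive_rate(self):
        cohort = _cohort(110, n_ad=13, n_nc=13)
        table = compare_local(cohort, n_perm=400, seed=8)
        rate = table["significant_uncorrected"].mean()
        assert rate < 0.12  # ~5% expected under the null
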