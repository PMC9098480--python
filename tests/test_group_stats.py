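"""Repeated-measures ANOVA, FDR, post-hocs, effect sizes, correlations."""

import numpy as np
import pytest
from scipy import stats

from fcdtools import synthetic
from fcdtools.datatypes import ConditionDataset
from fcdtools.group_stats import (
    behavior_correlation,
    bh_fdr,
    cohens_d_map,
    posthoc_pairwise,
    rm_anova,
    subgroup_difference,
)


def brute_force_rm_anova(table):
    """Definitional sums-of-squares decomposition with explicit loops."""
    s, c = table.shape
    grand = table.mean()
    ss_cond = sum(s * (table[:, j].mean() - grand) ** 2 for j in range(c))
    ss_subj = sum(c * (table[i].mean() - grand) ** 2 for i in range(s))
    ss_total = sum((table[i, j] - grand) ** 2 for i in range(s) for j in range(c))
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = c - 1, (c - 1) * (s - 1)
    return (ss_cond / df1) / (ss_err / df2), df1, df2


def brute_force_bh(p, alpha):
    """Step-up rule straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * alpha:
            k_max = rank
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q, reject


def dataset_from_cube(cube, **kw):
    cube = np.asarray(cube, float)
    return ConditionDataset(
        values=cube,
        condition_names=[f"c{i}" for i in range(cube.shape[1])],
        region_ids=np.arange(1, cube.shape[2] + 1),
        **kw,
    )


class TestRmAnova:
    def test_study_design_degrees_of_freedom(self):
        ds = synthetic.make_condition_study(15, 3, np.zeros((3, 10)), seed=0)
        tab = rm_anova(ds)
        assert (tab["df1"] == 2).all()
        assert (tab["df2"] == 28).all()

    def test_zero_condition_variance_gives_zero_f(self):
        rng = np.random.default_rng(0)
        # remove condition means exactly: zero condition SS, nonzero error SS
        cube = rng.normal(size=(8, 3, 5))
        cube -= cube.mean(axis=0, keepdims=True)
        tab = rm_anova(dataset_from_cube(cube))
        np.testing.assert_allclose(tab["F"], 0.0, atol=1e-18)
        # fully degenerate case: conditions literally identical per subject
        flat = np.repeat(rng.normal(size=(8, 1, 5)), 3, axis=1)
        np.testing.assert_allclose(rm_anova(dataset_from_cube(flat))["F"], 0.0, atol=1e-18)

    def test_matches_hand_computed_sums_of_squares(self):
        rng = np.random.default_rng(5)
        cube = rng.normal(size=(3, 3, 1))
        tab = rm_anova(dataset_from_cube(cube))
        f, df1, df2 = brute_force_rm_anova(cube[:, :, 0])
        assert tab["F"].iloc[0] == pytest.approx(f, abs=1e-10)
        assert (tab["df1"].iloc[0], tab["df2"].iloc[0]) == (df1, df2)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        cube = rng.normal(size=(10, 3, 2)) + np.array([0.0, 0.4, 0.1])[None, :, None]
        tab = rm_anova(dataset_from_cube(cube))
        for region in range(2):
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(10), 3),
                    "condition": np.tile(np.arange(3), 10),
                    "y": cube[:, :, region].ravel(),
                }
            )
            ref = pingouin.rm_anova(
                data=long, dv="y", within="condition", subject="subject", correction=False
            )
            assert tab["F"].iloc[region] == pytest.approx(ref["F"].iloc[0], rel=1e-8)
            assert tab["p"].iloc[region] == pytest.approx(ref["p_unc"].iloc[0], rel=1e-6)

    def test_invariant_to_subject_and_global_offsets(self):
        rng = np.random.default_rng(2)
        cube = rng.normal(size=(9, 3, 4))
        shifted = cube + rng.normal(size=(9, 1, 1)) * 5 + 3.0
        np.testing.assert_allclose(
            rm_anova(dataset_from_cube(cube))["F"],
            rm_anova(dataset_from_cube(shifted))["F"],
            rtol=1e-10,
            atol=1e-10,
        )

    def test_missing_cell_named(self):
        cube = np.random.default_rng(0).normal(size=(4, 3, 2))
        cube[2, 1, 0] = np.nan
        with pytest.raises(ValueError, match="subject 2, condition 1, region 0"):
            rm_anova(dataset_from_cube(cube))


class TestBhFdr:
    def test_single_small_p_rejected(self):
        q, reject = bh_fdr([0.03], alpha=0.05)
        assert reject[0]
        assert q[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        q, reject = bh_fdr([0.01, 0.02, 0.03, 0.9], alpha=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_keep_null(self):
        q, reject = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()
        np.testing.assert_allclose(q, 1.0)

    def test_empty_list(self):
        q, reject = bh_fdr([])
        assert q.size == 0 and reject.size == 0

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            alpha = rng.choice([0.01, 0.05, 0.1])
            q, reject = bh_fdr(p, alpha=alpha)
            q_ref, reject_ref = brute_force_bh(p, alpha)
            np.testing.assert_allclose(q, q_ref, atol=1e-12)
            np.testing.assert_array_equal(reject, reject_ref)

    def test_rejections_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        p = rng.random(30)
        prev = np.zeros(30, bool)
        for alpha in (0.01, 0.05, 0.1, 0.2):
            _, reject = bh_fdr(p, alpha=alpha)
            assert np.all(reject >= prev)
            prev = reject


class TestPosthocPairwise:
    def test_degenerate_constant_shift_flagged(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 1, 2))
        cube = np.concatenate([a, a + 1.0], axis=1)
        tab = posthoc_pairwise(dataset_from_cube(cube))
        assert tab["degenerate_variance"].all()
        np.testing.assert_allclose(tab["p_raw"], 0.0)

    def test_bonferroni_capped_at_one(self):
        rng = np.random.default_rng(3)
        cube = rng.normal(size=(10, 3, 3))
        tab = posthoc_pairwise(dataset_from_cube(cube))
        assert (tab["p_bonferroni"] <= 1.0).all()
        big = tab[tab["p_raw"] > 0.5]
        assert (big["p_bonferroni"] == 1.0).any() or len(big) == 0

    def test_transient_increase_pattern_detected(self):
        # planted rise at the middle condition, return at the last; the
        # offset is scaled so the paired effect size dz is 1.5 (the
        # difference of two unit-variance cells has SD sqrt(2))
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(10_000 + seed)
            noise = rng.normal(size=(15, 3, 1))
            cube = noise + np.array([0.0, 1.5 * np.sqrt(2), 0.0])[None, :, None]
            tab = posthoc_pairwise(dataset_from_cube(cube))
            up = tab[(tab["pair"] == "c0 vs c1")].iloc[0]
            down = tab[(tab["pair"] == "c1 vs c2")].iloc[0]
            if (
                up["p_bonferroni"] < 0.05
                and up["direction"] == "increase"
                and down["p_bonferroni"] < 0.05
                and down["direction"] == "decrease"
            ):
                hits += 1
        assert hits >= 0.95 * n_runs

    def test_too_few_subjects_rejected(self):
        cube = np.zeros((1, 2, 2))
        with pytest.raises(ValueError, match="2 subjects"):
            posthoc_pairwise(dataset_from_cube(cube))


class TestCohensD:
    def test_identical_conditions_give_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 1, 3))
        cube = np.concatenate([a, a.copy()], axis=1)
        # perturb to avoid zero SD of differences
        cube[:, 1, :] += rng.normal(scale=1e-6, size=(8, 3))
        tab = cohens_d_map(dataset_from_cube(cube), ("c0", "c1"))
        assert np.abs(tab["d"]).max() < 1.5  # mean diff ~ 0 relative to its SD

    def test_antisymmetric_in_pair_order(self):
        rng = np.random.default_rng(1)
        ds = dataset_from_cube(rng.normal(size=(10, 3, 4)))
        fwd = cohens_d_map(ds, ("c0", "c1"))["d"]
        back = cohens_d_map(ds, ("c1", "c0"))["d"]
        np.testing.assert_allclose(fwd, -back, atol=1e-12)

    def test_paired_dz_hand_example(self):
        base = np.zeros((3, 1, 1))
        cube = np.concatenate([base, np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)], axis=1)
        tab = cohens_d_map(dataset_from_cube(cube), ("c0", "c1"))
        assert tab["d"].iloc[0] == pytest.approx(2.0)

    def test_pooled_variant_recorded(self):
        rng = np.random.default_rng(4)
        ds = dataset_from_cube(rng.normal(size=(8, 2, 2)))
        tab = cohens_d_map(ds, ("c0", "c1"), variant="pooled")
        assert (tab["variant"] == "pooled").all()

    def test_sign_agrees_with_posthoc_direction(self):
        rng = np.random.default_rng(6)
        cube = rng.normal(size=(12, 3, 6)) + np.array([0.0, 0.8, -0.3])[None, :, None]
        ds = dataset_from_cube(cube)
        d = cohens_d_map(ds, ("c0", "c1")).set_index("region_id")["d"]
        ph = posthoc_pairwise(ds)
        ph = ph[ph["pair"] == "c0 vs c1"].set_index("region_id")
        for rid in d.index:
            direction = ph.loc[rid, "direction"]
            assert (d[rid] > 0) == (direction == "increase")


class TestBehaviorCorrelation:
    def test_exact_negative_relation(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=(10, 3))
        tab = behavior_correlation(prof, -prof[:, 0])
        assert tab["r"].iloc[0] == pytest.approx(-1.0)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(1000):
            x = rng.normal(size=(15, 1))
            y = rng.normal(size=15)
            pvals.append(behavior_correlation(x, y)["p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(2)
        rs = []
        rho = -0.5
        for _ in range(500):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=15)
            rs.append(behavior_correlation(z[:, [0]], z[:, 1])["r"].iloc[0])
        assert np.mean(rs) == pytest.approx(rho, abs=0.1)

    def test_zero_variance_flagged(self):
        tab = behavior_correlation(np.zeros((6, 2)), np.arange(6.0))
        assert tab["degenerate"].all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="4 subjects"):
            behavior_correlation(np.zeros((3, 1)), np.zeros(3))


class TestSubgroupDifference:
    def test_null_rate_near_nominal(self):
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(100):
            deltas = rng.normal(size=(16, 10))
            groups = np.array(["a"] * 8 + ["b"] * 8)
            tab = subgroup_difference(deltas, groups)
            rates.append((tab["p"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.03)

    def test_extreme_separation_detected(self):
        rng = np.random.default_rng(1)
        deltas = rng.normal(size=(12, 5))
        deltas[6:] += 5.0
        groups = np.array(["a"] * 6 + ["b"] * 6)
        tab = subgroup_difference(deltas, groups)
        assert (tab["p"] < 0.001).all()

    def test_zero_variance_flagged(self):
        deltas = np.zeros((6, 1))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        tab = subgroup_difference(deltas, groups)
        assert tab["degenerate_variance"].iloc[0]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            subgroup_difference(np.zeros((3, 2)), np.array(["a", "b", "b"]))
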