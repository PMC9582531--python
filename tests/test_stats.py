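import numpy as np
import pytest
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from gaitgpm import stats
from gaitgpm.stats import (
    ConditionMaps,
    StatsParams,
    cluster_effect_size,
    cluster_permutation_test,
    cohens_d_paired,
    effect_maps,
    holm_correction,
    rm_anova_2x2,
    wilcoxon_signed_rank,
)


def _maps(rng, n=8, nf=6, np_=10):
    return {c: rng.normal(0, 1, (n, nf, np_)) for c in stats.CONDITION_ORDER}


class TestEffectMaps:
    def test_identical_maps_zero_differences(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (8, 6, 10))
        cmaps = ConditionMaps({c: m for c in stats.CONDITION_ORDER},
                              np.arange(6.0, 18.0, 2.0))
        for effect in stats.EFFECTS:
            a, b = effect_maps(cmaps, effect)
            assert np.abs(a - b).max() < 1e-12

    def test_additive_model_has_no_interaction(self):
        rng = np.random.default_rng(1)
        terrain_eff = rng.normal(0, 1, (8, 6, 10))
        task_eff = rng.normal(0, 1, (8, 6, 10))
        base = rng.normal(0, 1, (8, 6, 10))
        m = {
            "even_ST": base, "even_DT": base + task_eff,
            "uneven_ST": base + terrain_eff,
            "uneven_DT": base + terrain_eff + task_eff,
        }
        a, b = effect_maps(ConditionMaps(m, np.arange(6.0, 18.0, 2.0)),
                           "interaction")
        assert np.abs(a - b).max() < 1e-12

    def test_pure_interaction_pattern(self):
        c = 0.7
        shape = (4, 3, 5)
        m = {
            "even_ST": np.full(shape, +c), "even_DT": np.full(shape, -c),
            "uneven_ST": np.full(shape, -c), "uneven_DT": np.full(shape, +c),
        }
        cmaps = ConditionMaps(m, np.arange(6.0, 12.0, 2.0))
        for effect in ("terrain", "task"):
            a, b = effect_maps(cmaps, effect)
            assert np.abs(a - b).max() < 1e-12
        a, b = effect_maps(cmaps, "interaction")
        assert np.allclose(a - b, 2 * c)

    def test_missing_condition_errors(self):
        rng = np.random.default_rng(2)
        m = _maps(rng)
        del m["uneven_DT"]
        with pytest.raises(ValueError, match="missing conditions"):
            ConditionMaps(m, np.arange(6.0, 18.0, 2.0))

    def test_unknown_effect_errors(self):
        rng = np.random.default_rng(3)
        cmaps = ConditionMaps(_maps(rng), np.arange(6.0, 18.0, 2.0))
        with pytest.raises(ValueError, match="unknown effect"):
            effect_maps(cmaps, "gait")


class TestClusterPermutation:
    def test_identical_pairs_no_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (8, 6, 10))
        res = cluster_permutation_test((a, a.copy()),
                                       StatsParams(n_permutations=200))
        assert res.clusters == []
        assert res.min_p == 1.0

    def test_injected_effect_recovered(self):
        # power / recovery simulation: d ~ 1.5 effect over a known support
        rng = np.random.default_rng(1)
        support = np.zeros((10, 20), dtype=bool)
        support[5:9, 0:4] = True  # mimics ~20-30 Hz, 0-15 % phase
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            diff = rng.normal(0, 1, (19, 10, 20))
            diff[:, support] += 1.5
            res = cluster_permutation_test(
                (diff, np.zeros_like(diff)),
                StatsParams(n_permutations=500, seed=rep))
            sig = res.significant(0.05)
            if not sig:
                continue
            best = max(sig, key=lambda c: abs(c.mass))
            overlap = (best.mask & support).sum() / support.sum()
            if overlap >= 0.5:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_p_value_bounds_and_masks_disjoint(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.3, 1, (10, 6, 10))
        res = cluster_permutation_test((a, np.zeros_like(a)),
                                       StatsParams(n_permutations=300))
        total = np.zeros((6, 10), dtype=int)
        for c in res.clusters:
            assert 1 / 301 <= c.p_value <= 1.0
            total += c.mask
        assert total.max() <= 1

    def test_too_few_subjects(self):
        a = np.zeros((1, 4, 4))
        with pytest.raises(ValueError, match="at least 2 subjects"):
            cluster_permutation_test((a, a), StatsParams(n_permutations=100))


class TestClusterEffectSize:
    def test_degenerate_sd_guarded(self):
        a = np.full((4, 3, 3), 2.0)
        mask = np.ones((3, 3), dtype=bool)
        es = cluster_effect_size((a, np.zeros_like(a)), mask)
        assert es.degenerate and np.isinf(es.value)

    def test_antisymmetric_means_zero_d(self):
        a = np.stack([np.full((2, 2), 1.0), np.full((2, 2), -1.0)])
        es = cluster_effect_size((a, np.zeros_like(a)), np.ones((2, 2), bool))
        assert es.value == 0.0

    def test_d_equals_t_over_sqrt_n(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.5, 1, (12, 4, 5))
        b = rng.normal(0.0, 1, (12, 4, 5))
        mask = np.zeros((4, 5), dtype=bool)
        mask[1:3, 2:4] = True
        es = cluster_effect_size((a, b), mask)
        per_subj = (a - b)[:, mask].mean(axis=1)
        t = sstats.ttest_rel(per_subj, np.zeros_like(per_subj)).statistic
        assert es.value == pytest.approx(t / np.sqrt(12), abs=1e-12)

    def test_empty_mask_errors(self):
        a = np.zeros((4, 3, 3))
        with pytest.raises(ValueError, match="empty cluster"):
            cluster_effect_size((a, a), np.zeros((3, 3), bool))


def _brute_force_rm_anova(values):
    """Textbook two-way within-subject ANOVA decomposition (oracle)."""
    n = values.shape[0]
    y = values.reshape(n, 2, 2)  # (subject, terrain, task)
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    a_m = y.mean(axis=(0, 2))   # terrain level means
    b_m = y.mean(axis=(0, 1))   # task level means
    as_m = y.mean(axis=2)       # subject x terrain
    bs_m = y.mean(axis=1)       # subject x task
    ss_a = 2 * n * ((a_m - grand) ** 2).sum()
    ss_b = 2 * n * ((b_m - grand) ** 2).sum()
    ss_as = 2 * ((as_m - subj[:, None] - a_m[None, :] + grand) ** 2).sum()
    ss_bs = 2 * ((bs_m - subj[:, None] - b_m[None, :] + grand) ** 2).sum()
    ab_m = y.mean(axis=0)
    ss_ab = n * ((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2).sum()
    resid = (y - as_m[:, :, None] - bs_m[:, None, :] - ab_m[None]
             + subj[:, None, None] + a_m[None, :, None] + b_m[None, None, :]
             - grand)
    ss_abs = (resid ** 2).sum()
    out = {}
    for name, ss_eff, ss_err in (("terrain", ss_a, ss_as),
                                 ("task", ss_b, ss_bs),
                                 ("interaction", ss_ab, ss_abs)):
        F = (ss_eff / 1) / (ss_err / (n - 1))
        out[name] = {"F": F, "partial_eta_sq": ss_eff / (ss_eff + ss_err)}
    return out


class TestRmAnova:
    def test_identical_conditions_zero_F(self):
        vals = np.tile(np.random.default_rng(0).normal(0, 1, (10, 1)), (1, 4))
        res = rm_anova_2x2(vals)
        for eff in stats.EFFECTS:
            assert res[eff]["F"] == pytest.approx(0.0, abs=1e-20)
            assert res[eff]["partial_eta_sq"] == pytest.approx(0.0, abs=1e-20)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            vals = rng.normal(0, 1, (9, 4)) + rng.normal(0, 1, (9, 1))
            res = rm_anova_2x2(vals)
            oracle = _brute_force_rm_anova(vals)
            for eff in stats.EFFECTS:
                assert res[eff]["F"] == pytest.approx(oracle[eff]["F"], abs=1e-9)
                assert res[eff]["partial_eta_sq"] == pytest.approx(
                    oracle[eff]["partial_eta_sq"], abs=1e-9)

    def test_F_equals_t_squared_and_eta_identity(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (10, 4))
        vals[:, 2:] += 1.0
        res = rm_anova_2x2(vals)
        even = vals[:, :2].mean(axis=1)
        uneven = vals[:, 2:].mean(axis=1)
        t = sstats.ttest_rel(even, uneven).statistic
        n = 10
        assert res["terrain"]["F"] == pytest.approx(t ** 2, abs=1e-9)
        assert res["terrain"]["partial_eta_sq"] == pytest.approx(
            res["terrain"]["F"] / (res["terrain"]["F"] + n - 1), abs=1e-12)

    def test_subject_constant_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (8, 4))
        shifted = vals + rng.normal(0, 5, (8, 1))
        a, b = rm_anova_2x2(vals), rm_anova_2x2(shifted)
        for eff in stats.EFFECTS:
            assert a[eff]["F"] == pytest.approx(b[eff]["F"], abs=1e-8)

    def test_incomplete_design_errors(self):
        with pytest.raises(ValueError):
            rm_anova_2x2(np.zeros((10, 3)))
        bad = np.zeros((10, 4))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x2(bad)


class TestCohensD:
    def test_equal_samples_zero(self):
        x = np.random.default_rng(0).normal(0, 1, 10)
        assert cohens_d_paired(x, x.copy()).value == 0.0

    def test_constant_differences_flagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        es = cohens_d_paired(x + 1.0, x)
        assert es.degenerate and np.isinf(es.value)

    def test_d_times_sqrt_n_is_t(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        es = cohens_d_paired(x, y)
        t = sstats.ttest_rel(x, y).statistic
        assert es.value * np.sqrt(15) == pytest.approx(t, abs=1e-12)

    def test_reproduces_published_conversion(self):
        # F = 102.15 with df (1, 18) corresponds to |t| = sqrt(F) and
        # |d| = t / sqrt(19) ~ 2.32 for the terrain stride-time effect
        assert np.sqrt(102.15) / np.sqrt(19) == pytest.approx(2.32, abs=0.005)
        # F = 27.10 -> |d| ~ 1.19 for the task effect
        assert np.sqrt(27.10) / np.sqrt(19) == pytest.approx(1.19, abs=0.005)


class TestWilcoxon:
    def test_19_all_positive(self):
        x = np.arange(1.0, 20.0)
        res = wilcoxon_signed_rank(x, np.zeros_like(x))
        assert res["T"] == 190.0
        assert res["R"] == 1.0
        assert res["p"] < 0.001

    def test_18_positive_one_zero(self):
        x = np.arange(0.0, 19.0)  # first difference is exactly zero
        res = wilcoxon_signed_rank(x, np.zeros_like(x))
        assert res["T"] == 171.0
        assert res["R"] == 1.0
        assert res["p"] < 0.001
        assert res["n"] == 18

    def test_mirrored_differences_R_zero(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = wilcoxon_signed_rank(x, np.zeros_like(x))
        assert res["R"] == pytest.approx(0.0)

    def test_closed_form_all_positive(self):
        for n in range(2, 31):
            x = np.arange(1.0, n + 1.0)
            res = wilcoxon_signed_rank(x, np.zeros_like(x))
            assert res["T"] == n * (n + 1) / 2

    def test_all_zero_differences_error(self):
        x = np.ones(5)
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(x, x.copy())


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_correction([0.03]) == pytest.approx([0.03])

    def test_hand_stepped_example(self):
        adj = holm_correction([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones(self):
        assert holm_correction([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_against_statsmodels(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.uniform(0, 1, rng.integers(2, 8))
            ours = holm_correction(p)
            theirs = multipletests(p, method="holm")[1]
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 6)
        adj = holm_correction(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(1.0, p * len(p)) + 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_correction([0.5, 1.2])
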