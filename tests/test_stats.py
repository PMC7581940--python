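"""Group statistics: ANOVA, Tukey HSD, compact letters, effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mepflux import (
    TreatmentGroups,
    compact_letters,
    effect_summary,
    one_way_anova,
    shapiro_wilk,
    tukey_hsd,
)
from mepflux.stats_report import letters_from_tukey, report_table


def groups_of(*arrays, labels=None):
    labels = labels or tuple(f"g{i}" for i in range(len(arrays)))
    return TreatmentGroups(tuple(labels),
                           tuple(np.asarray(a, dtype=float) for a in arrays))


class TestAnova:
    def test_identical_groups_give_null_f(self):
        g = groups_of([1, 2, 3], [1, 2, 3], [1, 2, 3])
        f, p, _ = one_way_anova(g)
        assert f == 0.0 and p == 1.0

    def test_hand_worked_decomposition(self):
        # groups {1,2,3},{2,3,4},{3,4,5}: SSB = 6 on 2 df, SSW = 6 on 6 df
        g = groups_of([1, 2, 3], [2, 3, 4], [3, 4, 5])
        f, p, df = one_way_anova(g)
        assert f == pytest.approx(3.0, abs=1e-12)
        assert df == (2, 6)
        assert 0 < p < 1

    def test_matches_scipy_reference(self, rng):
        from scipy.stats import f_oneway

        arrays = [rng.normal(i * 0.5, 1.0, size=6) for i in range(3)]
        f, p, _ = one_way_anova(groups_of(*arrays))
        ref = f_oneway(*arrays)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_shift_invariance_and_scaling(self, rng):
        arrays = [rng.normal(i, 1.0, size=5) for i in range(3)]
        f0, _, _ = one_way_anova(groups_of(*arrays))
        f_shift, _, _ = one_way_anova(groups_of(*[a + 100 for a in arrays]))
        f_scale, _, _ = one_way_anova(groups_of(*[a * 7.0 for a in arrays]))
        assert f_shift == pytest.approx(f0, rel=1e-9)
        assert f_scale == pytest.approx(f0, rel=1e-9)

    def test_label_permutation_preserves_null_f_distribution(self, rng):
        # resampling sanity check: permuting labels of null data leaves the
        # empirical F distribution unchanged (compare quartiles)
        data = rng.normal(size=(2000, 9))

        def f_of(cols):
            return np.array([
                one_way_anova(groups_of(row[cols[0]], row[cols[1]], row[cols[2]]))[0]
                for row in data
            ])

        split_a = [slice(0, 3), slice(3, 6), slice(6, 9)]
        perm = rng.permutation(9)
        split_b = [perm[0:3], perm[3:6], perm[6:9]]
        qa = np.quantile(f_of(split_a), [0.25, 0.5, 0.75])
        qb = np.quantile(f_of(split_b), [0.25, 0.5, 0.75])
        assert np.allclose(qa, qb, atol=0.15)

    def test_type_one_error_near_alpha(self, rng):
        n_rep, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_rep):
            arrays = rng.normal(size=(3, 5))
            _, p, _ = one_way_anova(groups_of(*arrays))
            rejections += p < alpha
        rate = rejections / n_rep
        # 3-sigma binomial band around alpha
        band = 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) < band

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            groups_of([1.0], [2.0, 3.0])


class TestTukey:
    def test_identical_groups_not_significant(self):
        tk = tukey_hsd(groups_of([1, 2, 3, 4], [1, 2, 3, 4]))
        assert not tk["significant"].any()

    def test_extreme_separation_significant(self):
        a = np.array([0.0, 0.1, -0.1, 0.05, -0.05])
        tk = tukey_hsd(groups_of(a, a + 100.0))
        assert tk["significant"].all()

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        arrays = [rng.normal(i * 1.2, 1.0, size=5) for i in range(3)]
        ours = tukey_hsd(groups_of(*arrays))
        values = np.concatenate(arrays)
        labels = np.repeat(["g0", "g1", "g2"], 5)
        ref = pairwise_tukeyhsd(values, labels, alpha=0.05)
        assert np.allclose(ours["p_adj"].to_numpy(), ref.pvalues, atol=1e-6)


def brute_force_letter_check(letters, sig):
    """Definition check: share a letter <=> pair not significant."""
    k = len(letters)
    for i, j in itertools.combinations(range(k), 2):
        shared = bool(set(letters[i]) & set(letters[j]))
        if shared == bool(sig[i, j]):
            return False
    return True


class TestCompactLetters:
    def test_all_pairs_significant(self):
        sig = ~np.eye(3, dtype=bool)
        disp = compact_letters(sig, ("a", "b", "c"))
        assert disp.letters == ("a", "b", "c")

    def test_no_pair_significant(self):
        sig = np.zeros((3, 3), dtype=bool)
        disp = compact_letters(sig, ("x", "y", "z"))
        assert disp.letters == ("a", "a", "a")

    def test_chain_pattern(self):
        # 1 != 3 but 1 == 2 and 2 == 3 -> a, ab, b
        sig = np.zeros((3, 3), dtype=bool)
        sig[0, 2] = sig[2, 0] = True
        disp = compact_letters(sig, ("g1", "g2", "g3"))
        assert disp.letters == ("a", "ab", "b")

    @pytest.mark.parametrize("k", [3, 4])
    def test_exhaustive_consistency_up_to_four_groups(self, k):
        # every possible significance pattern yields a consistent display
        pairs = list(itertools.combinations(range(k), 2))
        for bits in itertools.product([False, True], repeat=len(pairs)):
            sig = np.zeros((k, k), dtype=bool)
            for (i, j), b in zip(pairs, bits):
                sig[i, j] = sig[j, i] = b
            disp = compact_letters(sig, tuple(f"g{i}" for i in range(k)))
            assert brute_force_letter_check(disp.letters, sig), bits

    def test_asymmetric_matrix_rejected(self):
        sig = np.zeros((3, 3), dtype=bool)
        sig[0, 1] = True
        with pytest.raises(ValueError):
            compact_letters(sig, ("a", "b", "c"))

    def test_pipeline_from_tukey(self, rng):
        arrays = [rng.normal(0, 1, 5), rng.normal(0.2, 1, 5), rng.normal(30, 1, 5)]
        disp = letters_from_tukey(groups_of(*arrays))
        d = disp.as_dict()
        assert set(d["g0"]) & set(d["g1"])  # similar means share a letter
        assert not set(d["g0"]) & set(d["g2"])  # distant mean differs


class TestShapiroWilk:
    def test_too_small_or_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])

    def test_null_pvalues_roughly_uniform(self, rng):
        from scipy.stats import kstest

        pvals = [shapiro_wilk(rng.normal(size=25))[1] for _ in range(400)]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_bimodal_sample_rejected_as_non_normal(self, rng):
        x = np.concatenate([np.zeros(25), np.ones(25)]) + rng.normal(0, 1e-3, 50)
        _, p = shapiro_wilk(x)
        assert p < 0.05


class TestEffectSummary:
    def test_no_change(self):
        g = TreatmentGroups(("control", "trt"),
                            (np.array([10.0, 10, 10]), np.array([10.0, 10, 10])))
        eff = effect_summary(g).set_index("group")
        assert eff.loc["trt", "percent_change_vs_control"] == 0.0
        assert eff.loc["trt", "fold_change_vs_control"] == 1.0

    def test_decrease_and_fold_increase(self):
        g = TreatmentGroups(
            ("control", "moderate", "severe"),
            (np.array([10.0, 10, 10]), np.array([3.0, 3, 3]), np.array([0.4, 0.4, 0.4])),
        )
        eff = effect_summary(g).set_index("group")
        assert eff.loc["moderate", "percent_change_vs_control"] == pytest.approx(70.0)
        assert eff.loc["severe", "percent_change_vs_control"] == pytest.approx(96.0)
        g2 = TreatmentGroups(("control", "trt"),
                             (np.array([2.0, 2, 2]), np.array([13.4, 13.4, 13.4])))
        eff2 = effect_summary(g2).set_index("group")
        assert eff2.loc["trt", "fold_change_vs_control"] == pytest.approx(6.7)

    def test_zero_control_flagged(self):
        g = TreatmentGroups(("control", "trt"),
                            (np.array([0.0, 0.0]), np.array([1.0, 2.0])))
        with pytest.warns(UserWarning, match="undefined"):
            eff = effect_summary(g)
        assert eff["percent_change_vs_control"].isna().iloc[1]

    def test_missing_control_rejected(self):
        g = groups_of([1, 2], [3, 4])
        with pytest.raises(ValueError):
            effect_summary(g)


def test_report_table_per_variable(rng):
    rows = []
    for var, means in [("photo", (100, 30, 4)), ("aba", (10, 67, 128))]:
        for trt, mu in zip(("control", "moderate", "severe"), means):
            for i in range(5):
                rows.append({"variable_id": var, "treatment": trt,
                             "tree_id": f"{trt}_{i}",
                             "value": mu * (1 + rng.normal(0, 0.05))})
    table = report_table(pd.DataFrame(rows))
    assert set(table["variable_id"]) == {"photo", "aba"}
    photo = table[(table.variable_id == "photo")].set_index("group")
    assert photo.loc["moderate", "percent_change_vs_control"] == pytest.approx(70, abs=8)
    assert photo["anova_p"].iloc[0] < 0.05
    # all three treatments separated -> three distinct letters
    assert len(set(photo["letters"])) == 3
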