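"""SING scoring and the normality/variance-gated decision tree."""

import warnings

import numpy as np
import pytest

from crescan.behavior import (
    GroupComparison,
    SingTrialBlock,
    analyse_genotype,
    anderson_darling_normal,
    decision_tree,
    dual_control_rule,
    dunn_sidak_alpha,
    hartley_fmax_critical,
    normality_gate,
    read_trials,
    sing_score,
    tube_averages,
    variance_gate,
)


class TestSingScore:
    def test_all_climb(self):
        block = SingTrialBlock("g", "f", [10] * 15)
        assert sing_score(block) == 10.0

    def test_none_climb(self):
        assert sing_score(SingTrialBlock("g", "f", [0] * 15)) == 0.0

    def test_alternating_counts(self):
        counts = [4, 6] * 7 + [4]  # eight 4s, seven 6s
        assert sing_score(SingTrialBlock("g", "f", counts)) == pytest.approx(74 / 15)

    def test_wrong_trial_count_warns_not_errors(self):
        block = SingTrialBlock("g", "f", [5] * 12, n_trials=12)
        with pytest.warns(UserWarning, match="12 trials"):
            assert sing_score(block) == 5.0

    def test_count_above_group_size_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SingTrialBlock("g", "f", [11] + [5] * 14)


class TestNormalityGate:
    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 5"):
            anderson_darling_normal([1.0, 2.0, 3.0])

    def test_type_one_rate_near_alpha(self):
        """Normal data should pass at roughly the 1 - alpha rate."""
        rng = np.random.default_rng(0)
        passes = sum(
            anderson_darling_normal(rng.normal(5, 1, 30)) for _ in range(1000)
        )
        assert passes / 1000 == pytest.approx(0.95, abs=0.03)

    def test_exponential_group_detected(self):
        rng = np.random.default_rng(1)
        rejects = sum(
            not anderson_darling_normal(rng.exponential(1.0, 30)) for _ in range(1000)
        )
        assert rejects / 1000 >= 0.90

    def test_any_failing_group_fails_overall(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.exponential(1, 30) ** 3]
        overall, per = normality_gate(groups)
        assert overall is False and per[2] is False


class TestVarianceGate:
    def test_identical_groups_fmax_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        ok, fmax = variance_gate([g, g, g])
        assert ok is True and fmax == pytest.approx(1.0)

    def test_fmax_arithmetic(self):
        g1 = [0.0, 2.0, 4.0, 6.0]  # var 20/3... use ddof=1
        g2 = [0.0, 1.0, 2.0, 3.0]
        _ok, fmax = variance_gate([g1, g2])
        assert fmax == pytest.approx(4.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, s, 10).tolist() for s in (1.0, 1.5, 2.0)]
        _ok1, f1 = variance_gate(groups)
        _ok2, f2 = variance_gate(groups[::-1])
        assert f1 == pytest.approx(f2)

    def test_zero_variance_group_fails_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            ok, _ = variance_gate([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]])
        assert ok is False

    def test_critical_values_match_published_table(self):
        # classical alpha=0.05 table: k=2,df=9 -> 4.03; k=3,df=9 -> 5.34
        assert hartley_fmax_critical(2, 9) == pytest.approx(4.03, rel=0.02)
        assert hartley_fmax_critical(3, 9) == pytest.approx(5.34, rel=0.02)

    def test_out_of_range_falls_back(self):
        with pytest.raises(ValueError):
            hartley_fmax_critical(11, 9)


class TestDunnSidak:
    def test_closed_form_three_comparisons(self):
        assert dunn_sidak_alpha(0.05, 3) == pytest.approx(1 - 0.95 ** (1 / 3), abs=1e-12)
        assert dunn_sidak_alpha(0.05, 3) == pytest.approx(0.016952, abs=1e-5)


class TestDecisionTree:
    def test_identical_normal_groups_null(self):
        rng = np.random.default_rng(4)
        any_sig = 0
        for _ in range(50):
            g = [rng.normal(5, 1, 10) for _ in range(3)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = decision_tree(*g)
            if dual_control_rule(comp):
                any_sig += 1
        assert any_sig <= 5

    def test_shifted_experimental_group_detected(self):
        rng = np.random.default_rng(5)
        sig = 0
        branches = {"anova_tukey": 0, "kw_mwu": 0}
        n = 100
        for _ in range(n):
            e = rng.normal(8, 1, 30)
            c1, c2 = rng.normal(5, 1, 30), rng.normal(5, 1, 30)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = decision_tree(e, c1, c2)
            branches[comp.branch_taken] += 1
            if dual_control_rule(comp):
                sig += 1
        assert sig / n >= 0.90
        assert branches["anova_tukey"] > branches["kw_mwu"]

    def test_exponential_group_takes_nonparametric_branch(self):
        rng = np.random.default_rng(6)
        kw = 0
        for _ in range(50):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = decision_tree(
                    rng.exponential(1, 30), rng.normal(5, 1, 30), rng.normal(5, 1, 30)
                )
            kw += comp.branch_taken == "kw_mwu"
        assert kw / 50 >= 0.90

    def test_branch_recorded_and_omnibus_gates_pairwise(self):
        rng = np.random.default_rng(7)
        g = [rng.normal(5, 1, 12) for _ in range(3)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = decision_tree(*g)
        assert comp.branch_taken in ("anova_tukey", "kw_mwu")
        if comp.omnibus_p >= 0.05:
            assert not any(comp.pairwise_significant.values())


class TestDualControlRule:
    @pytest.mark.parametrize(
        "sig_triple,expected",
        [
            ((True, True, False), True),   # the stated rule
            ((True, False, False), False),
            ((False, True, False), False),
            ((True, True, True), False),   # control disagreement vetoes
            ((False, False, False), False),
        ],
    )
    def test_truth_table(self, sig_triple, expected):
        comp = GroupComparison(branch_taken="anova_tukey", omnibus_p=0.01)
        for key, s in zip(GroupComparison.PAIRS, sig_triple):
            comp.pairwise_significant[key] = s
        assert dual_control_rule(comp) is expected


class TestTrialIO:
    def _write_trials(self, path, shift=0.0):
        rng = np.random.default_rng(8)
        rows = ["genotype\tsex\ttube_id\ttrial_index\tcount_above_mark"]
        for genotype, mu in (("exp", 5 + shift), ("c_uas", 5.0), ("c_gal4", 5.0)):
            for sex in ("f", "m"):
                for tube in range(10):
                    base = rng.normal(mu, 1.0)
                    for trial in range(15):
                        c = int(np.clip(round(base + rng.normal(0, 1)), 0, 10))
                        rows.append(f"{genotype}\t{sex}\t{tube}\t{trial}\t{c}")
        path.write_text("\n".join(rows) + "\n")

    def test_tube_averages_shape(self, tmp_path):
        p = tmp_path / "trials.tsv"
        self._write_trials(p)
        df = read_trials(p)
        tubes = tube_averages(df)
        assert len(tubes) == 3 * 2 * 10
        assert tubes["sing_score"].between(0, 10).all()

    def test_analyse_genotype_pooled_and_by_sex(self, tmp_path):
        p = tmp_path / "trials.tsv"
        self._write_trials(p, shift=3.0)
        df = read_trials(p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled = analyse_genotype(df, "exp", "c_uas", "c_gal4")
            females = analyse_genotype(df, "exp", "c_uas", "c_gal4", sex="f")
        assert pooled["significant"] in (True, False)
        assert pooled["sex"] == "pooled" and females["sex"] == "f"
        assert pooled["significant"] is True  # +3 SD shift is unmissable

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("genotype\tsex\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_trials(p)
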