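"""Stratification, Fisher association, group comparisons and correlations."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

import ifnsig
from ifnsig import ContingencyTable2x2, ValidationError
from ifnsig.stratify import FISHER_REL_TOL


class TestControlCutoff:
    def test_degenerate_controls(self):
        med, sd, cut = ifnsig.control_cutoff([1, 1, 1, 1])
        assert (med, sd, cut) == (1.0, 0.0, 1.0)

    def test_hand_calculation(self):
        med, sd, cut = ifnsig.control_cutoff([0.8, 1.0, 1.2])
        assert med == pytest.approx(1.0)
        assert sd == pytest.approx(0.2)
        assert cut == pytest.approx(1.4)

    def test_translation_equivariance(self, rng):
        x = rng.uniform(0.5, 2, size=20)
        _, _, cut = ifnsig.control_cutoff(x)
        _, _, cut_shift = ifnsig.control_cutoff(x + 5.0)
        assert cut_shift == pytest.approx(cut + 5.0)

    def test_needs_two_controls(self):
        with pytest.raises(ValidationError):
            ifnsig.control_cutoff([1.0])

    def test_robust_flag_uses_mad(self):
        med, sd, _ = ifnsig.control_cutoff([1, 1, 1, 1, 100], robust=True)
        assert med == 1.0 and sd == 0.0  # MAD ignores the outlier


class TestClassifyHighLow:
    def test_boundary_score_is_low(self):
        strat = ifnsig.classify_high_low({"a": 1.4, "b": 1.41}, cutoff=1.4)
        assert strat.labels == {"a": "low", "b": "high"}

    def test_all_below_gives_zero_high(self):
        strat = ifnsig.classify_high_low({"a": 0.1, "b": 0.2}, cutoff=1.0)
        assert strat.ids("high") == []

    def test_constructed_8_high_9_low(self):
        scores = {f"hi_{i}": 2.0 + i for i in range(8)}
        scores.update({f"lo_{i}": 0.5 + 0.05 * i for i in range(9)})
        strat = ifnsig.classify_high_low(scores, cutoff=1.5)
        assert len(strat.ids("high")) == 8
        assert len(strat.ids("low")) == 9

    def test_stratify_combines_cutoff_and_labels(self, rng):
        scores = {f"c{i}": v for i, v in enumerate(rng.normal(1, 0.1, size=10))}
        scores["patient"] = 5.0
        strat = ifnsig.stratify(scores, control_ids=[f"c{i}" for i in range(10)])
        med, sd, cut = ifnsig.control_cutoff([scores[f"c{i}"] for i in range(10)])
        assert strat.cutoff == pytest.approx(cut)
        assert strat.labels["patient"] == "high"
        with pytest.raises(ValidationError):
            ifnsig.stratify(scores, control_ids=["missing"])


def fisher_fraction_oracle(a, b, c, d):
    """Exact-arithmetic two-sided Fisher p with the point-probability rule.

    Point probabilities as Fractions; a table is included when its
    probability is below the observed one up to the same relative tolerance
    the implementation applies.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    obs = probs[a]
    cut = obs * (Fraction(1) + Fraction(FISHER_REL_TOL).limit_denominator(10**12))
    return float(sum(p for p in probs.values() if p <= cut))


class TestFisherExact:
    def test_gpp_flares_worked_example(self):
        p = ifnsig.fisher_exact_2x2([[7, 1], [3, 6]])
        assert p == pytest.approx(1210 / 24310, rel=1e-9)
        assert f"{p:.3g}" == "0.0498"

    def test_degenerate_column(self):
        assert ifnsig.fisher_exact_2x2([[0, 5], [0, 5]]) == 1.0

    def test_diagonal_table(self):
        assert ifnsig.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(
            2 / comb(10, 5), rel=1e-9
        )

    def test_full_sweep_small_totals(self):
        # every table with total <= 12 against the exact-fraction oracle
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        p = ifnsig.fisher_exact_2x2([[a, b], [c, d]])
                        assert p == pytest.approx(
                            fisher_fraction_oracle(a, b, c, d), rel=1e-9
                        ), (a, b, c, d)

    def test_symmetry_invariances(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            p = ifnsig.fisher_exact_2x2([[a, b], [c, d]])
            assert ifnsig.fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p)
            assert ifnsig.fisher_exact_2x2([[d, c], [b, a]]) == pytest.approx(p)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, size=4)
            if a + b + c + d == 0:
                continue
            ours = ifnsig.fisher_exact_2x2([[a, b], [c, d]])
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 0, 0, 1)


class TestAssociate:
    def test_reconstructed_flares_table(self, gpp_sample_table):
        labels = {f"hi_{i}": "high" for i in range(8)}
        labels.update({f"lo_{i}": "low" for i in range(9)})
        strat = ifnsig.StratificationResult(
            cutoff=1.5, labels=labels, control_median=1.0, control_sd=0.25
        )
        table, p = ifnsig.associate(strat, gpp_sample_table, "flares")
        assert (table.a, table.b, table.c, table.d) == (7, 1, 3, 6)
        assert p == pytest.approx(1210 / 24310, rel=1e-9)

    def test_all_missing_flag_degenerates(self, gpp_sample_table):
        strat = ifnsig.StratificationResult(
            cutoff=1.0, labels={"c0": "low", "c1": "low"},
            control_median=1.0, control_sd=0.0,
        )
        with pytest.warns(UserWarning):
            _, p = ifnsig.associate(strat, gpp_sample_table, "flares")
        assert p == 1.0

    def test_null_association_is_super_uniform(self):
        # flag independent of stratum: P(p <= alpha) <= alpha (+ MC slack)
        rng = np.random.default_rng(42)
        n_rep, alpha = 400, 0.05
        rejections = 0
        for _ in range(n_rep):
            labels = {f"s{i}": ("high" if i < 8 else "low") for i in range(17)}
            flags = {f"s{i}": bool(rng.random() < 0.4) for i in range(17)}
            samples = ifnsig.SampleTable(
                sample_ids=list(labels),
                group=["case"] * 17,
                cohort=["x"] * 17,
                flags={"f": flags},
            )
            strat = ifnsig.StratificationResult(
                cutoff=0, labels=labels, control_median=0, control_sd=0
            )
            _, p = ifnsig.associate(strat, samples, "f")
            rejections += p <= alpha
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejections / n_rep <= alpha + 3 * se


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        res = ifnsig.compare_groups([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.test == "t"
        assert res.p_value == pytest.approx(1.0)

    def test_single_treatment_dunnett_reduces_to_t(self, rng):
        x = rng.normal(0, 1, size=12)
        y = rng.normal(0.8, 1, size=12)
        t_p = stats.ttest_ind(x, y, equal_var=True).pvalue
        res = ifnsig.compare_groups(
            np.concatenate([x, y, rng.normal(0, 1, 12)]),
            ["ctrl"] * 12 + ["trt"] * 12 + ["other"] * 12,
            control_label="ctrl",
        )
        # drop to exactly one treatment group for the reduction check
        res2 = ifnsig.compare_groups(
            np.concatenate([x, y]), ["ctrl"] * 12 + ["trt"] * 12
        )
        assert res2.p_value == pytest.approx(t_p)
        assert set(res.dunnett_p) == {"trt", "other"}

    def test_dunnett_single_family_matches_t(self, rng):
        # 3-group call but compare the Dunnett machinery at family size 1
        x = rng.normal(0, 1, size=15)
        y = rng.normal(1.0, 1, size=15)
        d = stats.dunnett(y, control=x, random_state=np.random.default_rng(0))
        t_p = stats.ttest_ind(y, x, equal_var=True).pvalue
        assert float(d.pvalue[0]) == pytest.approx(t_p, abs=0.01)

    def test_shifted_group_detected(self, rng):
        pooled = 1.0
        groups = {
            "ctrl": rng.normal(0, pooled, 10),
            "null": rng.normal(0, pooled, 10),
            "shift": rng.normal(3 * pooled, pooled, 10),
        }
        values = np.concatenate(list(groups.values()))
        labels = sum(([k] * 10 for k in groups), [])
        res = ifnsig.compare_groups(values, labels, control_label="ctrl", seed=5)
        assert res.test == "anova"
        assert res.dunnett_p["shift"] < 0.01
        assert res.dunnett_p["null"] > 0.1

    def test_type_one_error_in_band(self):
        # 2000 null replicates of the two-group t at alpha = 0.05
        rng = np.random.default_rng(314)
        n_rep = 2000
        x = rng.normal(size=(n_rep, 9))
        y = rng.normal(size=(n_rep, 7))
        p = stats.ttest_ind(x, y, axis=1, equal_var=True).pvalue
        rate = float(np.mean(p < 0.05))
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - half_width <= rate <= 0.05 + half_width

    def test_errors(self):
        with pytest.raises(ValidationError):
            ifnsig.compare_groups([1, 2, 3], ["a", "a", "b"])  # group of 1
        with pytest.raises(ValidationError):
            ifnsig.compare_groups([1, 2, 3, 4, 5, 6],
                                  ["a", "a", "b", "b", "c", "c"])  # no control


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = [0.3, 1.2, 2.4, 5.5, 9.1]
        rho, p = ifnsig.spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)  # minimum attainable two-sided

    def test_reversed_gives_minus_one(self):
        rho, _ = ifnsig.spearman([1, 2, 3, 4], [9, 6, 4, 1])
        assert rho == pytest.approx(-1.0)

    def test_exact_enumeration_example(self):
        # full enumeration of the 120 rank permutations: 16 reach |rho| >= 0.8
        rho, p = ifnsig.spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)
        assert p == pytest.approx(16 / 120)

    def test_exact_matches_direct_enumeration(self, rng):
        x = rng.normal(size=7)
        y = 0.5 * x + rng.normal(size=7)
        rho, p = ifnsig.spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rhos = [
            np.corrcoef(rx, perm)[0, 1]
            for perm in itertools.permutations(ry)
        ]
        expected = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = ifnsig.spearman(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho)
        assert p == pytest.approx(ref_p)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            ifnsig.spearman([1, 1, 1], [1, 2, 3])


class TestPairedNonparametric:
    def test_identical_conditions_friedman_null(self):
        data = np.tile([[1.0, 1.0, 1.0]], (5, 1)) * np.arange(1, 6)[:, None]
        res = ifnsig.paired_nonparametric(data)
        assert res.test == "friedman"
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_wilcoxon_exact_shift(self):
        a = np.array([3.0, 5.0, 1.0, 9.0, 2.0, 7.0])
        res = ifnsig.paired_nonparametric(np.column_stack([a, a + 1]))
        assert res.test == "wilcoxon"
        assert res.p_value == pytest.approx(2 / 64)  # enumeration of 2^6 signs

    def test_dominant_condition_has_smallest_dunn_p(self, rng):
        base = rng.normal(5, 1, size=(8, 1))
        data = np.hstack([
            base + rng.normal(0, 0.2, size=(8, 1)),
            base + rng.normal(0, 0.2, size=(8, 1)),
            base + 3.0 + rng.normal(0, 0.2, size=(8, 1)),
        ])
        res = ifnsig.paired_nonparametric(data, ["a", "b", "big"])
        assert res.test == "friedman"
        ph = res.posthoc
        big_rows = ph[(ph["condition_a"] == "big") | (ph["condition_b"] == "big")]
        other = ph[(ph["condition_a"] != "big") & (ph["condition_b"] != "big")]
        assert big_rows["p_value"].max() <= other["p_value"].min()

    def test_missing_cells_rejected(self):
        data = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 4.0]])
        with pytest.raises(ValidationError, match="missing"):
            ifnsig.paired_nonparametric(data)

    def test_needs_three_donors(self):
        with pytest.raises(ValidationError):
            ifnsig.paired_nonparametric(np.ones((2, 2)))
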