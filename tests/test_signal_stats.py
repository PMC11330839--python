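import math

import numpy as np
import pandas as pd
import pytest

from faersig.signal_stats import (
    ContingencyTable,
    SignalEstimates,
    bcpnn_moments,
    bonferroni,
    build_all_tables,
    build_contingency,
    compute_ebgm,
    compute_ic,
    compute_prr_chi2,
    compute_ror,
    compute_signal_estimates,
    evaluate_criteria,
    screen_terms,
)

T_EXAMPLE = ContingencyTable(10, 90, 100, 9900)
T_NULL = ContingencyTable(5, 5, 50, 50)  # proportional rows: independence


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=["primaryid", "pt"]).astype(str)


class TestBuildContingency:
    def test_direct_counting(self):
        target = pairs_frame([("1", "Cough")])  # case 2 is target but term-free
        allp = pairs_frame([("1", "Cough"), ("2", "Pyrexia"), ("3", "Cough")])
        t = build_contingency("Cough", target, allp, target_case_count=2,
                              total_case_count=100)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 97)

    def test_absent_term(self):
        t = build_contingency("Zeta", pairs_frame([]), pairs_frame([]), 10, 100)
        assert (t.a, t.c) == (0, 0) and t.n == 100

    def test_conservation_across_terms(self):
        target = pairs_frame([("1", "Cough"), ("1", "Pyrexia"), ("2", "Cough")])
        allp = pairs_frame([("1", "Cough"), ("1", "Pyrexia"), ("2", "Cough"),
                            ("3", "Pyrexia"), ("4", "Cough")])
        tables = build_all_tables(target, allp, 2, 50)
        for t in tables.values():
            assert t.n == 50

    def test_inconsistent_counts_rejected(self):
        target = pairs_frame([("1", "Cough"), ("2", "Cough")])
        with pytest.raises(Exception):
            build_contingency("Cough", target, target, target_case_count=1,
                              total_case_count=100)


class TestRor:
    def test_independent_table_is_one(self):
        assert compute_ror(T_NULL)[0] == pytest.approx(1.0)

    def test_example_table(self):
        ror, lo, hi = compute_ror(T_EXAMPLE)
        assert ror == pytest.approx(11.0)
        # frozen from direct arithmetic: sqrt(1/10+1/90+1/100+1/9900)=0.348155
        assert lo == pytest.approx(5.559514928894626, rel=1e-12)
        assert hi == pytest.approx(21.76448872744693, rel=1e-12)

    def test_zero_cell_undefined_without_correction(self):
        ror, lo, hi = compute_ror(ContingencyTable(3, 0, 5, 100))
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)

    def test_continuity_shift_makes_zero_cell_finite(self):
        t = ContingencyTable(3, 0, 5, 100).shifted(0.5)
        assert compute_ror(t)[0] > 0


class TestPrrChi2:
    def test_independence(self):
        prr, chi2, p = compute_prr_chi2(T_NULL)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_example_table(self):
        prr, chi2, p = compute_prr_chi2(T_EXAMPLE)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.44717444717445, rel=1e-12)
        assert 0 < p < 1e-15

    def test_zero_c_undefined(self):
        assert all(math.isnan(v) for v in compute_prr_chi2(ContingencyTable(5, 5, 0, 100)))

    def test_chi2_equals_pearson_expected_count_form(self):
        """Oracle: sum (O-E)^2/E over the four cells with product-margin E."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 400, 4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            n = t.n
            obs = np.array([[a, b], [c, d]], dtype=float)
            rows = obs.sum(1, keepdims=True)
            cols = obs.sum(0, keepdims=True)
            exp = rows @ cols / n
            pearson = float(((obs - exp) ** 2 / exp).sum())
            assert compute_prr_chi2(t)[1] == pytest.approx(pearson, rel=1e-10)


class TestIcEbgm:
    def test_independent_table_ic_zero_ebgm_one(self):
        assert compute_ic(T_NULL)[0] == pytest.approx(0.0)
        assert compute_ebgm(T_NULL)[0] == pytest.approx(1.0)

    def test_example_table(self):
        ic, ic025 = compute_ic(T_EXAMPLE)
        ebgm, ebgm05 = compute_ebgm(T_EXAMPLE)
        assert ebgm == pytest.approx(101000 / 11000, rel=1e-12)
        assert ebgm05 == pytest.approx(4.640586841474027, rel=1e-12)
        assert ic == pytest.approx(math.log2(101000 / 11000), rel=1e-12)
        assert ic025 < ic

    def test_ebgm_is_two_to_the_ic(self):
        """Point estimates share one observed/expected formula."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 500, 4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            assert compute_ebgm(t)[0] == pytest.approx(2 ** compute_ic(t)[0], rel=1e-12)

    def test_ic025_below_ic_for_positive_a(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 1000, 4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            ic, ic025 = compute_ic(t)
            assert ic025 < ic + 1e-12

    def test_a_zero_undefined(self):
        assert math.isnan(compute_ic(ContingencyTable(0, 10, 10, 100))[0])
        assert math.isnan(compute_ebgm(ContingencyTable(0, 10, 10, 100))[0])

    def test_ebgm_point_survives_zero_bcd(self):
        ebgm, ebgm05 = compute_ebgm(ContingencyTable(3, 0, 2, 100))
        assert ebgm > 0 and math.isnan(ebgm05)

    @pytest.mark.parametrize("table", [(10, 90, 100, 9900), (5, 5, 50, 50),
                                       (3, 7, 40, 950), (50, 450, 500, 49000)])
    def test_moments_match_monte_carlo_posterior(self, table):
        """Independent oracle: sample the Beta posteriors of the joint cell and
        the two margins and average log2(p11/(p1*p2)).  The closed form is a
        moment approximation, so agreement is to approximation accuracy."""
        a, b, c, d = table
        n = a + b + c + d
        n1, n2 = a + b, a + c
        gamma = (n + 2) * (n + 2) / ((n1 + 1) * (n2 + 1))
        rng = np.random.default_rng(12)
        m = 200_000
        p11 = rng.beta(a + 1, n - a + gamma - 1, m)
        p1 = rng.beta(n1 + 1, n - n1 + 1, m)
        p2 = rng.beta(n2 + 1, n - n2 + 1, m)
        ic = np.log2(p11 / (p1 * p2))
        e_cf, v_cf = bcpnn_moments(ContingencyTable(a, b, c, d))
        assert e_cf == pytest.approx(float(ic.mean()), abs=0.15)
        assert math.sqrt(v_cf) == pytest.approx(float(ic.std()), rel=0.15)


class TestAlgebraicRelations:
    def test_ror_over_prr_identity(self):
        """ROR/PRR = (d/(c+d)) / (b/(a+b)) for every all-positive table."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 500, 4))
            t = ContingencyTable(a, b, c, d)
            ror = compute_ror(t)[0]
            prr = compute_prr_chi2(t)[0]
            assert ror / prr == pytest.approx((d / (c + d)) / (b / (a + b)), rel=1e-12)

    def test_monotone_in_a(self):
        b, c, d = 50, 80, 5000
        prev = None
        for a in range(1, 30):
            t = ContingencyTable(a, b, c, d)
            vals = (compute_ror(t)[0], compute_prr_chi2(t)[0],
                    compute_ic(t)[0], compute_ebgm(t)[0])
            if prev is not None:
                assert all(v > p for v, p in zip(vals, prev))
            prev = vals


class TestCoverage:
    def test_ror_interval_covers_true_odds_ratio(self):
        """Draw 600 multinomial databases from fixed cell probabilities and
        check the 95% CI covers the true odds ratio about 95% of the time."""
        rng = np.random.default_rng(7)
        p = np.array([0.004, 0.046, 0.05, 0.90])
        true_or = (p[0] * p[3]) / (p[1] * p[2])
        n = 20_000
        covered = 0
        runs = 600
        for _ in range(runs):
            a, b, c, d = rng.multinomial(n, p)
            if min(a, b, c, d) == 0:
                runs -= 1
                continue
            _, lo, hi = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            covered += lo <= true_or <= hi
        assert 0.92 <= covered / runs <= 0.98


class TestCriteriaAndScreening:
    def test_small_n_gates_ror_and_prr(self):
        e = SignalEstimates(term="x", level="PT", n=2, table=ContingencyTable(2, 8, 5, 985),
                            ror_lo=50.0, prr=30.0, chi2=100.0)
        flags = evaluate_criteria(e)
        assert not flags["ror"] and not flags["prr"]

    def test_all_four_flags_on_strong_signal(self):
        e = compute_signal_estimates("x", "PT", T_EXAMPLE)
        assert e.flags == {"ror": True, "prr": True, "bcpnn": True, "mgps": True}
        assert e.flagged_by_all

    def test_independent_table_flags_nothing(self):
        e = compute_signal_estimates("x", "PT", T_NULL)
        assert not any(e.flags.values())

    def test_undefined_statistics_never_flag(self):
        e = compute_signal_estimates("x", "PT", ContingencyTable(5, 0, 0, 100))
        assert not e.flags["ror"] and not e.flags["prr"]

    def make_estimates(self):
        ests = []
        for i, flags in enumerate([
            {"ror": True, "prr": True, "bcpnn": True, "mgps": True},
            {"ror": True, "prr": True, "bcpnn": True, "mgps": True},
            {"ror": True, "prr": False, "bcpnn": False, "mgps": False},
            {"ror": False, "prr": False, "bcpnn": False, "mgps": False},
        ]):
            e = SignalEstimates(term=f"t{i}", level="PT", n=20 - 10 * (i == 1),
                                table=ContingencyTable(5, 5, 5, 5), soc=f"s{i}")
            e.flags = flags
            e.flagged_by_all = all(flags.values())
            ests.append(e)
        return ests

    def test_intersection_and_min_n_cut(self):
        res = screen_terms(self.make_estimates(), min_n=11)
        assert [e.term for e in res.intersection] == ["t0", "t1"]
        assert [e.term for e in res.reported] == ["t0"]  # t1 has n=10 < 11

    def test_venn_counts_partition_flagged_terms(self):
        res = screen_terms(self.make_estimates())
        assert sum(res.venn.values()) == 3  # terms with >=1 flag
        assert res.venn[("ror", "prr", "bcpnn", "mgps")] == 2
        assert res.venn[("ror",)] == 1


class TestBonferroni:
    def est(self, term, n, p):
        e = SignalEstimates(term=term, level="PT", n=n, table=ContingencyTable(n, 5, 5, 5))
        e.chi2_p = p
        return e

    def test_threshold_alpha_over_m(self):
        ests = [self.est("a", 5, 0.001), self.est("b", 5, 0.04)]
        bonferroni(ests, alpha=0.05)
        assert ests[0].bonferroni_significant  # 0.001 <= 0.025
        assert not ests[1].bonferroni_significant  # 0.04 > 0.025

    def test_family_excludes_small_n(self):
        ests = [self.est("a", 2, 1e-9), self.est("b", 5, 0.01)]
        bonferroni(ests, alpha=0.05)
        assert not ests[0].bonferroni_significant  # below the n >= 3 gate
        assert ests[1].bonferroni_significant  # m = 1, cutoff 0.05

    def test_matches_adjusted_p_oracle(self):
        rng = np.random.default_rng(8)
        ests = [self.est(f"t{i}", int(rng.integers(1, 30)), float(rng.uniform(0, 0.2)))
                for i in range(20)]
        bonferroni(ests, alpha=0.05)
        m = sum(e.n >= 3 for e in ests)
        for e in ests:
            expected = e.n >= 3 and e.chi2_p * m <= 0.05
            assert e.bonferroni_significant == expected

    def test_empty_family_warns_and_noop(self):
        ests = [self.est("a", 1, 0.001)]
        with pytest.warns(UserWarning):
            bonferroni(ests)
        assert not ests[0].bonferroni_significant
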