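import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from tauread import (
    ContingencyCounts,
    ReadMatrix,
    analytic_fleiss_kappa,
    build_agreement_report,
    cohen_kappa,
    contingency_from_reads,
    evaluate_success_criteria,
    fleiss_kappa,
    fleiss_kappa_from_summary,
    majority_contingency,
    majority_read,
    ppa_npa,
    simulate_reader_panel,
    wilson_interval,
)
from tauread.schema import validate_report


def _wilson_oracle(successes: int, n: int, level: float) -> tuple[float, float]:
    """Invert the score test by root finding, independently of the closed form."""
    z = stats.norm.ppf(0.5 + level / 2)
    phat = successes / n

    def score(p, sign):
        return (phat - p) - sign * z * np.sqrt(p * (1 - p) / n)

    eps = 1e-12
    # brackets avoid the trivial root at p = phat when phat is 0 or 1
    low = (
        0.0
        if successes == 0
        else optimize.brentq(lambda p: score(p, 1), eps, min(phat, 1 - eps))
    )
    high = (
        1.0
        if successes == n
        else optimize.brentq(lambda p: score(p, -1), max(phat, eps), 1 - eps)
    )
    return low, high


class TestWilson:
    @given(
        n=st.integers(1, 500),
        frac=st.floats(0, 1),
        level=st.sampled_from([0.8, 0.9, 0.95, 0.99]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_score_test_inversion_and_contains_point(self, n, frac, level):
        successes = int(round(frac * n))
        low, high = wilson_interval(successes, n, level)
        o_low, o_high = _wilson_oracle(successes, n, level)
        assert low == pytest.approx(o_low, abs=1e-10)
        assert high == pytest.approx(o_high, abs=1e-10)
        assert low <= successes / n <= high

    def test_zero_successes_lower_bound_is_zero(self):
        low, high = wilson_interval(0, 50)
        assert low == 0.0 and high > 0

    def test_width_shrinks_with_n_at_fixed_proportion(self):
        widths = [np.diff(wilson_interval(k, n))[0] for k, n in ((7, 10), (70, 100), (700, 1000))]
        assert widths[0] > widths[1] > widths[2]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 4)


class TestContingencyAndEndpoints:
    def test_three_scan_enumeration(self):
        matrix = ReadMatrix(
            ["s1", "s2", "s3"], ["r1"],
            np.array([[True], [True], [False]]),
            truth=[True, False, False],
        )
        c = contingency_from_reads(matrix, "r1")
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 0)

    def test_perfect_reader_has_no_errors(self):
        truth = [True, False, True, False]
        matrix = ReadMatrix(
            [f"s{i}" for i in range(4)], ["r1"],
            np.array(truth).reshape(-1, 1), truth=truth,
        )
        c = contingency_from_reads(matrix, "r1")
        assert c.fp == c.fn == 0

    def test_truthless_scan_excluded_and_counted(self):
        matrix = ReadMatrix(
            ["s1", "s2", "s3"], ["r1"],
            np.array([[True], [True], [False]]),
            truth=[True, None, False],
        )
        c = contingency_from_reads(matrix, "r1")
        assert c.n_excluded == 1
        assert c.total == 2 and (c.tp, c.tn) == (1, 1)

    def test_ppa_npa_formulas(self):
        e = ppa_npa(ContingencyCounts(tp=60, fp=8, tn=62, fn=10))
        assert e.ppa.point_pct == pytest.approx(100 * 60 / 70)
        assert e.npa.point_pct == pytest.approx(100 * 62 / 70)
        assert e.overall.point_pct == pytest.approx(100 * 122 / 140)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="PPA undefined"):
            ppa_npa(ContingencyCounts(tp=0, fp=1, tn=1, fn=0))

    def test_unknown_reader_rejected(self):
        matrix = ReadMatrix(["s1"], ["r1"], np.array([[True]]), truth=[True])
        with pytest.raises(KeyError):
            contingency_from_reads(matrix, "r9")


def _random_matrix(seed: int, n_scans=30, n_readers=5) -> ReadMatrix:
    rng = np.random.default_rng(seed)
    calls = rng.random((n_scans, n_readers)) < 0.5
    # guarantee both categories occur
    calls[0, :], calls[1, :] = True, False
    return ReadMatrix(
        [f"s{i}" for i in range(n_scans)],
        [f"r{j}" for j in range(n_readers)],
        calls,
    )


def _summary_of(matrix: ReadMatrix):
    n = matrix.n_readers
    splits: dict[tuple[int, int], int] = {}
    for k in matrix.calls.sum(axis=1):
        key = (max(int(k), n - int(k)), min(int(k), n - int(k)))
        splits[key] = splits.get(key, 0) + 1
    return splits, matrix.calls.sum(axis=0).tolist(), matrix.n_scans


class TestFleissKappa:
    def test_unanimous_with_both_categories_is_one(self):
        matrix = ReadMatrix(
            ["s1", "s2"], ["r1", "r2", "r3"],
            np.array([[True] * 3, [False] * 3]),
        )
        assert fleiss_kappa(matrix).statistic == pytest.approx(1.0)

    def test_single_category_degenerate(self):
        matrix = ReadMatrix(["s1", "s2"], ["r1", "r2"], np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="single category"):
            fleiss_kappa(matrix)

    def test_two_reader_matrix_matches_hand_computation(self):
        calls = np.array([[1, 1], [1, 0], [0, 0], [0, 0], [1, 1]], dtype=bool)
        matrix = ReadMatrix([f"s{i}" for i in range(5)], ["a", "b"], calls)
        # brute force over all scan-pairs of ratings
        p_o = np.mean([1.0 if calls[i, 0] == calls[i, 1] else 0.0 for i in range(5)])
        p = calls.mean()
        p_e = p**2 + (1 - p) ** 2
        expected = (p_o - p_e) / (1 - p_e)
        assert fleiss_kappa(matrix).statistic == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(100))
    def test_summary_form_is_exactly_equivalent(self, seed):
        matrix = _random_matrix(seed)
        splits, totals, n = _summary_of(matrix)
        full = fleiss_kappa(matrix)
        summary = fleiss_kappa_from_summary(splits, totals, n)
        assert summary.statistic == full.statistic
        assert summary.se == full.se

    def test_matches_statsmodels_point_estimate(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        matrix = _random_matrix(7, n_scans=60)
        table, _ = aggregate_raters(matrix.calls.astype(int))
        assert fleiss_kappa(matrix).statistic == pytest.approx(sm_fleiss(table), abs=1e-12)

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError, match="sum to n_scans"):
            fleiss_kappa_from_summary({(5, 0): 3}, [1] * 5, 4)


class TestCohenKappa:
    def test_identical_vectors_give_one(self):
        a = [True, False, True, False]
        assert cohen_kappa(a, a).statistic == pytest.approx(1.0)

    def test_maximal_disagreement_gives_minus_one(self):
        a = [True, False, True, False]
        b = [not x for x in a]
        assert cohen_kappa(a, b).statistic == pytest.approx(-1.0)

    def test_matches_two_by_two_hand_formula(self):
        """20-scan test-retest, one discordant pair, 12/8 marginal split."""
        a = [True] * 12 + [False] * 8
        b = [True] * 11 + [False] * 9  # one T->F flip
        p_o = 19 / 20
        p_e = (12 / 20) * (11 / 20) + (8 / 20) * (9 / 20)
        expected = (p_o - p_e) / (1 - p_e)
        k = cohen_kappa(a, b)
        assert k.statistic == pytest.approx(expected)
        assert k.ci_high <= 1.0

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.random(50) < 0.6
        b = rng.random(50) < 0.6
        assert cohen_kappa(a, b).statistic == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=40))
    @settings(max_examples=60, derandomize=True)
    def test_symmetric_in_arguments(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        both = {*a} == {True, False} or {*b} == {True, False}
        if not both and a != b:
            return  # degenerate identical-marginal case raises by contract
        try:
            k_ab = cohen_kappa(a, b)
        except ValueError:
            with pytest.raises(ValueError):
                cohen_kappa(b, a)
            return
        k_ba = cohen_kappa(b, a)
        assert k_ab.statistic == pytest.approx(k_ba.statistic)
        assert k_ab.se == pytest.approx(k_ba.se)


class TestMajorityRead:
    def test_simple_majority(self):
        matrix = ReadMatrix(
            ["s1"], [f"r{j}" for j in range(5)],
            np.array([[True, True, True, False, False]]),
        )
        assert majority_read(matrix)[0]

    def test_invariant_to_reader_order(self, rng):
        matrix = _random_matrix(3, n_scans=20)
        base = majority_read(matrix)
        perm = rng.permutation(matrix.n_readers)
        shuffled = ReadMatrix(matrix.scan_ids, [matrix.reader_ids[j] for j in perm],
                              matrix.calls[:, perm])
        np.testing.assert_array_equal(majority_read(shuffled), base)

    def test_tie_rules_on_even_panels(self):
        matrix = ReadMatrix(["s1"], ["a", "b"], np.array([[True, False]]))
        with pytest.raises(ValueError, match="tied"):
            majority_read(matrix, "error")
        assert majority_read(matrix, "positive")[0]
        assert not majority_read(matrix, "negative")[0]


class TestSuccessCriteria:
    def _report_with(self, ppa_low, npa_low, fleiss_stat=0.9, fleiss_low=0.85):
        truth = [True] * 10 + [False] * 10
        matrix = simulate_reader_panel(truth, 1.0, 1.0, 5, seed=0)
        report = build_agreement_report(matrix)
        # rebuild proportion estimates with forced lower bounds
        from dataclasses import replace

        for r in report.per_reader:
            e = report.per_reader[r]
            report.per_reader[r] = type(e)(
                ppa=replace(e.ppa, ci_low_pct=ppa_low),
                npa=replace(e.npa, ci_low_pct=npa_low),
                overall=e.overall,
            )
        report.fleiss = replace(report.fleiss, statistic=fleiss_stat, ci_low=fleiss_low)
        return report

    def test_all_bounds_above_fifty_succeeds(self):
        ok_primary, ok_fleiss = evaluate_success_criteria(self._report_with(72.4, 80.8))
        assert ok_primary and ok_fleiss

    def test_bounds_just_below_fifty_fail(self):
        ok_primary, _ = evaluate_success_criteria(self._report_with(49.0, 80.0))
        assert not ok_primary

    def test_fleiss_boundary_is_inclusive(self):
        _, ok = evaluate_success_criteria(self._report_with(80, 80, 0.64, 0.55))
        assert ok
        _, not_ok = evaluate_success_criteria(self._report_with(80, 80, 0.639, 0.55))
        assert not not_ok


class TestSimulatedPanels:
    def test_perfect_readers_reproduce_truth_with_kappa_one(self):
        truth = [True] * 10 + [False] * 10
        matrix = simulate_reader_panel(truth, 1.0, 1.0, 5, seed=1)
        np.testing.assert_array_equal(matrix.calls, np.array(truth)[:, None].repeat(5, 1))
        assert fleiss_kappa(matrix).statistic == pytest.approx(1.0)

    def test_same_seed_is_deterministic(self):
        truth = [True] * 30 + [False] * 30
        a = simulate_reader_panel(truth, 0.8, 0.9, 5, seed=5)
        b = simulate_reader_panel(truth, 0.8, 0.9, 5, seed=5)
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_panel_recovers_sensitivity(self):
        """Mean PPA across replicates approaches the design sensitivity."""
        sens, n_pos, n_readers, reps = 0.85, 70, 5, 500
        truth = [True] * n_pos + [False] * n_pos
        ppa = []
        for rep in range(reps):
            m = simulate_reader_panel(truth, sens, 0.9, n_readers, seed=rep)
            for r in m.reader_ids:
                ppa.append(ppa_npa(contingency_from_reads(m, r)).ppa.point_pct)
        se = 100 * np.sqrt(sens * (1 - sens) / (n_pos * n_readers * reps))
        assert abs(np.mean(ppa) - 100 * sens) <= max(3 * se, 1.5)

    def test_fleiss_converges_to_analytic_value(self):
        """Estimated kappa matches the independent-reader closed form."""
        prevalence, sens, spec = 0.5, 0.85, 0.90
        n_scans = 4000
        truth = [True] * int(n_scans * prevalence) + [False] * int(n_scans * (1 - prevalence))
        matrix = simulate_reader_panel(truth, sens, spec, 5, seed=17)
        est = fleiss_kappa(matrix)
        expected = analytic_fleiss_kappa(prevalence, sens, spec)
        assert abs(est.statistic - expected) <= 3 * est.se


class TestAgreementReport:
    def test_pooled_counts_equal_sum_of_readers(self):
        truth = [True] * 40 + [False] * 40
        matrix = simulate_reader_panel(truth, 0.85, 0.9, 5, seed=2)
        report = build_agreement_report(matrix)
        assert report.pooled_counts.tp == sum(c.tp for c in report.reader_counts.values())
        assert report.pooled.ppa.numerator == report.pooled_counts.tp
        assert report.pooled.ppa.denominator == sum(
            e.ppa.denominator for e in report.per_reader.values()
        )

    def test_report_json_validates_against_schema(self):
        truth = [True] * 20 + [False] * 20
        matrix = simulate_reader_panel(truth, 0.9, 0.9, 3, seed=3)
        report = build_agreement_report(matrix)
        validate_report(report.to_dict(), "agreement_report")

    def test_schema_violation_detected(self):
        with pytest.raises(ValueError, match="missing required key"):
            validate_report({"per_reader": {}}, "agreement_report")
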