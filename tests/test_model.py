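"""Risk-model construction: contingency tests, Cox fits, weights, cutoff."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lnmrisk import (
    CollinearityError,
    ContingencyTable2x2,
    ScoreTable,
    ValidationError,
    association_test,
    contingency_from_cohort,
    derive_weights,
    fit_multivariate_ph,
    screen_factors,
    select_cutoff,
    total_score,
    total_scores,
    univariate_ph,
)
from lnmrisk.model import _pearson_chi2_2x2, cochran_armitage_trend

from conftest import REFERENCE_CHI2, REFERENCE_WEIGHTS, make_cohort


def cohort_from_counts(a, b, c, d):
    """Patient table realizing the 2x2 layout (absent/present x censored/event)."""
    times, events, factor = [], [], []
    for count, x, e in ((a, 0, 0), (b, 0, 1), (c, 1, 0), (d, 1, 1)):
        times += [30.0] * count
        events += [e] * count
        factor += [x] * count
    return make_cohort(times, events, factor=factor)


class TestContingency:
    def test_vascular_invasion_layout(self):
        cohort = cohort_from_counts(154, 11, 15, 12)
        t = contingency_from_cohort(cohort, "factor")
        assert (t.a, t.b, t.c, t.d) == (154, 11, 15, 12)
        # Pearson statistic by the closed form; the smallest expected cell
        # (27 * 23 / 192 ~ 3.2) is below 5, so the test itself routes to Fisher
        assert _pearson_chi2_2x2(*map(int, (154, 11, 15, 12))) == pytest.approx(31.40, abs=0.05)
        res = association_test(t)
        assert res.method == "fisher"
        assert res.p_value < 0.001

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            contingency_from_cohort(make_cohort([], [], factor=[]), "factor")

    def test_all_absent_no_events(self):
        cohort = make_cohort([10.0] * 5, [0] * 5, factor=[0] * 5)
        t = contingency_from_cohort(cohort, "factor")
        assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 0)

    def test_unknown_factor(self):
        with pytest.raises(ValidationError):
            contingency_from_cohort(cohort_from_counts(2, 2, 2, 2), "nope")


class TestAssociationTest:
    def test_balanced_table_independent(self):
        res = association_test(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_warns_not_raises(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            res = association_test(ContingencyTable2x2(5, 0, 7, 0))
        assert res.p_value == 1.0

    def test_chi2_matches_closed_form(self, rng):
        """Pearson statistic equals n(ad-bc)^2 / (r1 r2 c1 c2) on random tables."""
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(5, 60, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            res = association_test(t)
            if res.method != "chi-square":
                continue
            assert res.statistic == pytest.approx(
                _pearson_chi2_2x2(t.a, t.b, t.c, t.d), rel=1e-12
            )
            checked += 1

    def test_sparse_table_routes_to_fisher(self):
        res = association_test(ContingencyTable2x2(20, 1, 2, 4))
        assert res.method == "fisher"


class TestUnivariatePH:
    def test_recovers_rate_ratio(self, rng):
        """Two-group exponential cohorts with rate ratio 5, no censoring:
        the mean estimated hazard ratio over replicates stays within the
        Monte-Carlo band [4, 6.25]."""
        n, hrs = 500, []
        for _ in range(10):
            x = rng.integers(0, 2, size=n)
            rates = 0.02 * 5.0**x
            times = rng.exponential(1.0 / rates)
            cohort = make_cohort(times, [1] * n, factor=x)
            res = univariate_ph(cohort, "factor")
            hrs.append(res.hazard_ratio)
            assert res.ci95[0] <= res.hazard_ratio <= res.ci95[1]
        assert 4.0 <= np.mean(hrs) <= 6.25

    def test_exchangeable_groups_null(self, rng):
        n = 400
        times = rng.exponential(50.0, size=n)
        x = rng.permutation([0, 1] * (n // 2))
        cohort = make_cohort(times, [1] * n, factor=x)
        res = univariate_ph(cohort, "factor")
        assert abs(math.log(res.hazard_ratio)) < 0.5

    def test_constant_factor_rejected(self):
        cohort = make_cohort([5.0, 6.0, 7.0], [1, 0, 1], factor=[1, 1, 1])
        with pytest.raises(ValidationError, match="constant"):
            univariate_ph(cohort, "factor")

    def test_no_events_rejected(self):
        cohort = make_cohort([5.0, 6.0], [0, 0], factor=[0, 1])
        with pytest.raises(ValidationError, match="events"):
            univariate_ph(cohort, "factor")

    def test_separation_flagged_not_raised(self):
        # every carrier has an early event, every non-carrier is censored
        cohort = make_cohort(
            [1.0, 2.0, 3.0, 50.0, 60.0, 70.0],
            [1, 1, 1, 0, 0, 0],
            factor=[1, 1, 1, 0, 0, 0],
        )
        res = univariate_ph(cohort, "factor")
        assert res.flagged


class TestScreening:
    @pytest.fixture
    def cohort(self, rng):
        n = 300
        strong = rng.integers(0, 2, size=n)
        noise = rng.integers(0, 2, size=n)
        rates = 0.01 * np.exp(1.5 * strong)
        times = np.minimum(rng.exponential(1.0 / rates), 100.0)
        events = (times < 100.0).astype(int)
        return make_cohort(times, events, strong=strong, noise=noise)

    def test_alpha_extremes(self, cohort):
        assert screen_factors(cohort, ["strong", "noise"], alpha=1.0) == ["strong", "noise"]
        assert screen_factors(cohort, ["strong", "noise"], alpha=1e-300) == []

    def test_order_preserved_and_selective(self, cohort):
        kept = screen_factors(cohort, ["noise", "strong"], alpha=0.05)
        assert "strong" in kept
        assert kept == sorted(kept, key=["noise", "strong"].index)

    def test_constant_factor_skipped_with_warning(self, cohort):
        cohort = cohort.assign(flat=0)
        with pytest.warns(UserWarning, match="flat"):
            kept = screen_factors(cohort, ["flat", "strong"], alpha=0.05)
        assert kept == ["strong"]


class TestMultivariate:
    def test_single_covariate_matches_univariate(self, rng):
        n = 300
        x = rng.integers(0, 2, size=n)
        times = rng.exponential(1.0 / (0.02 * np.exp(0.8 * x)))
        cohort = make_cohort(times, [1] * n, factor=x)
        uni = univariate_ph(cohort, "factor")
        (multi,) = fit_multivariate_ph(cohort, ["factor"])
        assert multi.hazard_ratio == pytest.approx(uni.hazard_ratio, rel=1e-6)
        assert multi.wald_chi2 == pytest.approx((multi.beta / multi.se) ** 2, rel=1e-12)

    def test_duplicated_factor_collinear(self, rng):
        n = 100
        x = rng.integers(0, 2, size=n)
        cohort = make_cohort(rng.exponential(30, size=n), [1] * n, f1=x, f2=x)
        with pytest.raises(CollinearityError):
            fit_multivariate_ph(cohort, ["f1", "f2"])

    def test_more_factors_than_events_rejected(self, rng):
        cohort = make_cohort(
            [5.0, 6.0, 7.0, 8.0],
            [1, 0, 0, 0],
            f1=[0, 1, 0, 1],
            f2=[1, 0, 0, 1],
        )
        with pytest.raises(ValidationError, match="events"):
            fit_multivariate_ph(cohort, ["f1", "f2"])

    def test_breslow_not_available(self, rng):
        n = 50
        x = rng.integers(0, 2, size=n)
        cohort = make_cohort(rng.exponential(30, size=n), [1] * n, factor=x)
        with pytest.raises(ValidationError, match="tie method"):
            fit_multivariate_ph(cohort, ["factor"], tie_method="breslow")


class TestDeriveWeights:
    def test_reference_example(self):
        table = derive_weights(REFERENCE_CHI2)
        assert table.weights == REFERENCE_WEIGHTS
        assert table.reference_chi2 == pytest.approx(4.496)

    def test_single_factor_identity(self):
        assert derive_weights({"only": 7.3}).weights == {"only": 1.0}

    def test_exact_ratio(self):
        assert derive_weights({"a": 8.992, "b": 4.496}).weights == {"a": 2.0, "b": 1.0}

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0, 1000.0])
    def test_scale_invariance(self, k):
        base = derive_weights(REFERENCE_CHI2).weights
        scaled = derive_weights({f: k * v for f, v in REFERENCE_CHI2.items()}).weights
        assert scaled == base

    def test_minimum_weight_is_one(self, rng):
        for _ in range(20):
            chi2 = {f"f{i}": float(v) for i, v in enumerate(rng.uniform(0.5, 50, size=6))}
            weights = derive_weights(chi2).weights
            assert min(weights.values()) == 1.0
            assert all(w >= 1.0 for w in weights.values())

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            derive_weights({})
        with pytest.raises(ValidationError):
            derive_weights({"a": 0.0})


class TestTotalScore:
    table = ScoreTable(weights=REFERENCE_WEIGHTS, reference_chi2=4.496)

    def test_all_factors_present(self):
        patient = {f: 1 for f in REFERENCE_WEIGHTS}
        assert total_score(patient, self.table) == pytest.approx(7.9)

    def test_all_absent(self):
        patient = {f: 0 for f in REFERENCE_WEIGHTS}
        assert total_score(patient, self.table) == 0.0

    def test_single_factor(self):
        patient = {f: int(f == "mir31_positive") for f in REFERENCE_WEIGHTS}
        assert total_score(patient, self.table) == pytest.approx(1.7)

    def test_missing_factor_named(self):
        with pytest.raises(ValidationError, match="vascular_invasion"):
            total_score({"bclc_b_c": 1}, self.table)

    def test_monotone_in_factors(self):
        base = {f: 0 for f in REFERENCE_WEIGHTS}
        score = total_score(base, self.table)
        for f in REFERENCE_WEIGHTS:
            bumped = dict(base, **{f: 1})
            assert total_score(bumped, self.table) >= score

    def test_vectorized_agrees(self, rng):
        rows = [{f: int(rng.integers(0, 2)) for f in REFERENCE_WEIGHTS} for _ in range(25)]
        df = pd.DataFrame(rows)
        vec = total_scores(df, self.table)
        for i, row in enumerate(rows):
            assert vec.iloc[i] == pytest.approx(total_score(row, self.table))


class TestSelectCutoff:
    def test_perfect_separation(self):
        scores = [0, 0, 1.7, 5.6, 5.6, 7.9]
        outcomes = [0, 0, 0, 1, 1, 1]
        res = select_cutoff(scores, outcomes)
        assert 1.7 < res.cutoff < 5.6

    def test_matches_brute_force(self, rng):
        """Selected cutoff equals an exhaustive scan over every midpoint."""
        for _ in range(30):
            scores = rng.choice([0.0, 1.0, 1.3, 2.6, 3.9, 5.6, 7.9], size=40)
            outcomes = rng.binomial(1, np.clip(scores / 10 + 0.05, 0, 1))
            if outcomes.min() == outcomes.max() or len(np.unique(scores)) < 2:
                continue
            res = select_cutoff(scores, outcomes)
            distinct = np.unique(scores)
            best_cut, best_chi2 = None, -1.0
            for cut in (distinct[:-1] + distinct[1:]) / 2:
                high = scores > cut
                a = int((~high & (outcomes == 0)).sum())
                b = int((~high & (outcomes == 1)).sum())
                c = int((high & (outcomes == 0)).sum())
                d = int((high & (outcomes == 1)).sum())
                chi2 = _pearson_chi2_2x2(a, b, c, d)
                if chi2 > best_chi2 + 1e-12:
                    best_cut, best_chi2 = cut, chi2
            assert res.cutoff == pytest.approx(best_cut)
            assert res.chi2 == pytest.approx(best_chi2)

    def test_permutation_invariant(self, rng):
        scores = np.array([0, 1.3, 1.3, 2.6, 4.3, 5.6, 7.9, 0, 1.0, 3.9])
        outcomes = np.array([0, 0, 1, 0, 1, 1, 1, 0, 0, 1])
        ref = select_cutoff(scores, outcomes)
        for _ in range(5):
            p = rng.permutation(len(scores))
            res = select_cutoff(scores[p], outcomes[p])
            assert res.cutoff == ref.cutoff
            assert res.chi2 == pytest.approx(ref.chi2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            select_cutoff([1.0, 1.0], [0, 1])
        with pytest.raises(ValidationError):
            select_cutoff([0.0, 1.0], [1, 1])

    def test_modal_cutoff_under_reference_effects(self, recovery_study):
        """Across simulated rebuilds the modal cutoff falls in (2.6, 5.2],
        bracketing the published cutoff of 4."""
        assert 2.6 < recovery_study["modal_cutoff"] <= 5.2


class TestCochranArmitage:
    def test_equals_n_r_squared(self, rng):
        """The trend statistic equals N * r^2 (point-biserial correlation)."""
        for _ in range(20):
            levels = np.array([0.0, 1.0, 2.6, 3.9, 5.2])
            n_per = rng.integers(5, 30, size=5)
            d_per = np.array([rng.integers(0, n + 1) for n in n_per])
            if d_per.sum() in (0, n_per.sum()):
                continue
            stat = cochran_armitage_trend(levels, n_per, d_per)
            x = np.repeat(levels, n_per)
            y = np.concatenate([
                np.r_[np.ones(d), np.zeros(n - d)] for n, d in zip(n_per, d_per)
            ])
            r = np.corrcoef(x, y)[0, 1]
            assert stat == pytest.approx(len(x) * r**2, rel=1e-9)
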