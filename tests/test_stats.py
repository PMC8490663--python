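import itertools
import math

import numpy as np
import pytest

from voxeloq._errors import CapacityError, UndefinedStatisticError
from voxeloq.atlas import AnalysisConfig
from voxeloq.stats import (
    binarize_kps,
    cohens_kappa,
    compare_groups,
    fisher_exact_2x2,
    freeman_halton_exact,
    logistic_wald_from_cells,
    logistic_wald_univariable,
    significant,
)

# ---------------------------------------------------------------------------
# independent oracles, written from the definitions, no scipy


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_p(k):
        return (
            math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1)
            - math.lgamma(r2 - c1 + k + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = math.exp(log_p(a))
    total = 0.0
    for k in range(lo, hi + 1):
        p_k = math.exp(log_p(k))
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(total, 1.0)


def freeman_halton_oracle_2x3(table):
    """Brute-force enumerator over all 2×3 tables with the observed margins."""
    table = np.asarray(table)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()

    def log_prob(t):
        s = sum(math.lgamma(x + 1) for x in rows) + sum(
            math.lgamma(x + 1) for x in cols
        ) - math.lgamma(n + 1)
        return s - sum(math.lgamma(x + 1) for x in np.ravel(t))

    p_obs = math.exp(log_prob(table))
    total = 0.0
    for a in range(min(rows[0], cols[0]) + 1):
        for b in range(min(rows[0] - a, cols[1]) + 1):
            c = rows[0] - a - b
            if c > cols[2]:
                continue
            t = np.array([[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]])
            if (t < 0).any():
                continue
            p = math.exp(log_prob(t))
            if p <= p_obs * (1 + 1e-7):
                total += p
    return min(total, 1.0)


# ---------------------------------------------------------------------------


class TestFisherExact:
    def test_exchangeable_table_is_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table, printed",
        [
            ([[26, 29], [62, 160]], 0.009),   # precentral left
            ([[18, 37], [55, 167]], 0.236),   # precentral right
            ([[16, 39], [38, 184]], 0.057),   # postcentral right
            ([[5, 50], [9, 213]], 0.163),     # pericalcarine right
            ([[14, 41], [33, 189]], 0.072),   # hippocampus right
            ([[12, 43], [23, 199]], 0.038),   # parahippocampal right
            ([[24, 31], [63, 159]], 0.035),   # pars opercularis left
            ([[28, 27], [67, 155]], 0.007),   # CS right
            ([[15, 40], [44, 178]], 0.269),   # OR right
            ([[31, 24], [76, 146]], 0.003),   # IFOF left
        ],
    )
    def test_reproduces_published_three_decimal_values(self, table, printed):
        assert round(fisher_exact_2x2(table), 3) == printed

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    def test_matches_enumeration_oracle_spot_checks(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-9
            )


class TestFreemanHalton:
    def test_reduces_to_fisher_on_2x2(self, rng):
        for _ in range(30):
            t = rng.integers(0, 10, (2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert freeman_halton_exact(t) == pytest.approx(
                fisher_exact_2x2(t), abs=1e-9
            )

    def test_proportional_rows_give_one(self):
        assert freeman_halton_exact([[2, 4, 6], [2, 4, 6]]) == pytest.approx(1.0)

    def test_matches_independent_enumerator_on_random_2x3(self, rng):
        done = 0
        while done < 25:
            t = rng.integers(0, 8, (2, 3))
            if t.sum() == 0 or t.sum() > 40:
                continue
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert freeman_halton_exact(t) == pytest.approx(
                freeman_halton_oracle_2x3(t), abs=1e-9
            )
            done += 1

    def test_capacity_guard_and_monte_carlo_fallback(self):
        big = np.full((4, 4), 1000)
        with pytest.raises(CapacityError):
            freeman_halton_exact(big, max_tables=1000)
        # seeded MC on a moderate table approximates the exact answer
        t = [[8, 3, 5], [2, 9, 4]]
        exact = freeman_halton_exact(t)
        mc = freeman_halton_exact(
            t, max_tables=10, monte_carlo=True, n_samples=200_000, seed=1
        )
        assert mc == pytest.approx(exact, abs=0.01)

    def test_monte_carlo_is_seed_deterministic(self):
        t = [[8, 3, 5], [2, 9, 4]]
        kw = dict(max_tables=10, monte_carlo=True, n_samples=50_000, seed=7)
        assert freeman_halton_exact(t, **kw) == freeman_halton_exact(t, **kw)


class TestCohensKappa:
    def test_published_agreement_table(self):
        """Clinician-presumed vs voxel-based eloquence, N=277."""
        res = cohens_kappa([[173, 9], [59, 36]])
        assert round(res.kappa, 3) == 0.377
        assert res.kappa == pytest.approx(
            (res.observed_agreement - res.expected_agreement)
            / (1 - res.expected_agreement)
        )

    def test_perfect_agreement(self):
        assert cohens_kappa([[10, 0], [0, 7]]).kappa == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # counts proportional to the product of the margins
        assert cohens_kappa([[9, 3], [3, 1]]).kappa == pytest.approx(0.0)

    def test_transpose_and_relabel_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(0, 20, (2, 2))
            if t.sum() == 0:
                continue
            try:
                k = cohens_kappa(t).kappa
            except UndefinedStatisticError:
                continue
            assert cohens_kappa(t.T).kappa == pytest.approx(k)
            assert cohens_kappa(t[::-1, ::-1]).kappa == pytest.approx(k)

    def test_against_sklearn_cross_check(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(10):
            t = rng.integers(1, 15, (2, 2))
            ra = [0] * (t[0, 0] + t[0, 1]) + [1] * (t[1, 0] + t[1, 1])
            rb = [0] * t[0, 0] + [1] * t[0, 1] + [0] * t[1, 0] + [1] * t[1, 1]
            assert cohens_kappa(t).kappa == pytest.approx(
                cohen_kappa_score(ra, rb)
            )

    def test_degenerate_margins_rejected(self):
        # both raters always answer the first category: pe = 1
        with pytest.raises(UndefinedStatisticError):
            cohens_kappa([[8, 0], [0, 0]])


class TestLogisticWald:
    @pytest.mark.parametrize(
        "cells, printed_ci",
        [
            ((24, 31, 45, 177), (0.488, 1.739)),   # postcentral left
            ((28, 27, 41, 181), (0.893, 2.149)),   # hippocampus left
            ((10, 45, 7, 215), (0.903, 2.939)),    # pericalcarine left
            ((23, 32, 26, 196), (1.016, 2.364)),   # supramarginal left
            ((17, 38, 14, 208), (1.107, 2.681)),   # inferior parietal left
        ],
    )
    def test_reproduces_published_wald_intervals(self, cells, printed_ci):
        res = logistic_wald_from_cells(*cells)
        assert (round(res.ci_low, 3), round(res.ci_high, 3)) == printed_ci

    def test_balanced_independence_is_symmetric_about_zero(self):
        res = logistic_wald_from_cells(10, 10, 10, 10)
        assert res.coefficient == pytest.approx(0.0)
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_vector_api_equals_cell_api(self):
        a, b, c, d = 12, 18, 7, 33
        y = [1] * a + [1] * b + [0] * c + [0] * d
        x = [1] * a + [0] * b + [1] * c + [0] * d
        vec = logistic_wald_univariable(y, x)
        cell = logistic_wald_from_cells(a, b, c, d)
        assert vec.coefficient == pytest.approx(cell.coefficient)
        assert vec.ci_low == pytest.approx(cell.ci_low)

    def test_closed_form_agrees_with_iterative_fit(self, rng):
        import statsmodels.api as sm

        checked = 0
        while checked < 60:
            a, b, c, d = rng.integers(1, 30, 4)
            y = np.repeat([1, 1, 0, 0], [a, b, c, d])
            x = np.repeat([1, 0, 1, 0], [a, b, c, d])
            fit = sm.Logit(y, sm.add_constant(x.astype(float))).fit(disp=0)
            res = logistic_wald_from_cells(a, b, c, d)
            assert res.coefficient == pytest.approx(fit.params[1], abs=1e-6)
            assert res.se == pytest.approx(fit.bse[1], abs=1e-6)
            checked += 1

    def test_zero_cell_is_flagged_not_silent(self):
        res = logistic_wald_from_cells(5, 0, 3, 7)
        assert "haldane_anscombe" in res.flags
        assert math.isfinite(res.coefficient)

    def test_complete_separation_flagged(self):
        res = logistic_wald_from_cells(8, 0, 0, 9)
        assert "complete_separation" in res.flags

    def test_constant_predictor_flagged(self):
        res = logistic_wald_univariable([0, 1, 0, 1], [1, 1, 1, 1])
        assert "constant_predictor" in res.flags
        assert math.isnan(res.coefficient)

    def test_single_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_wald_univariable([1, 1, 1, 1], [0, 1, 0, 1])

    def test_continuous_predictor_recovers_effect(self, rng):
        n = 2000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = (rng.random(n) < p).astype(int)
        res = logistic_wald_univariable(y, x)
        assert res.ci_low < 0.8 < res.ci_high


class TestStatsProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    cell = st.integers(min_value=0, max_value=60)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(a=cell, b=cell, c=cell, d=cell)
    def test_kappa_bounded_and_consistent(self, a, b, c, d):
        """Kappa lies in [−1, 1] and satisfies its defining identity on any
        non-degenerate 2×2 agreement table."""
        t = np.array([[a, b], [c, d]])
        if t.sum() == 0:
            return
        try:
            res = cohens_kappa(t)
        except UndefinedStatisticError:
            return
        assert -1.0 - 1e-12 <= res.kappa <= 1.0 + 1e-12
        assert res.kappa == pytest.approx(
            (res.observed_agreement - res.expected_agreement)
            / (1 - res.expected_agreement)
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(a=cell, b=cell, c=cell, d=cell)
    def test_fisher_p_is_probability_and_symmetric(self, a, b, c, d):
        t = np.array([[a, b], [c, d]])
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            return
        p = fisher_exact_2x2(t)
        assert 0.0 <= p <= 1.0
        # the two-sided p is invariant under transposition and row swap
        assert fisher_exact_2x2(t.T) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2(t[::-1]) == pytest.approx(p, abs=1e-12)


class TestCompareGroups:
    def test_identical_samples_t_test(self):
        vals = list(range(10)) * 2
        groups = ["a"] * 10 + ["b"] * 10
        res = compare_groups(vals, groups, "continuous_normal")
        assert res.test == "t-test"
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kind, n_groups, expected",
        [
            ("continuous_normal", 3, "ANOVA"),
            ("continuous_nonnormal", 2, "Mann-Whitney U"),
            ("continuous_nonnormal", 3, "Kruskal-Wallis"),
            ("categorical", 2, "Fisher exact"),
            ("categorical", 3, "Freeman-Halton exact"),
        ],
    )
    def test_dispatch_table(self, rng, kind, n_groups, expected):
        if kind == "categorical":
            vals = rng.integers(0, 2, 30)
        else:
            vals = rng.normal(size=30)
        groups = rng.integers(0, n_groups, 30)
        res = compare_groups(vals, groups, kind, fh_seed=0)
        assert res.test == expected

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], ["a", "b"], "ordinal")

    def test_power_matches_monte_carlo_oracle(self, rng):
        """Unit-variance shift Δ=1, n=50/50: the rejection rate at α=0.002
        through the dispatcher matches an independent Monte-Carlo estimate
        computed from the t statistic directly."""
        from scipy import stats as sps

        reps = 2000
        alpha = 0.002
        rej_dispatch = 0
        for _ in range(reps):
            a = rng.normal(0.0, 1.0, 50)
            b = rng.normal(1.0, 1.0, 50)
            res = compare_groups(
                np.concatenate([a, b]), np.repeat([0, 1], 50), "continuous_normal"
            )
            rej_dispatch += res.p <= alpha
        # oracle: vectorized equal-variance t-test from first principles
        oracle_reps = 10_000
        xa = rng.normal(0.0, 1.0, (oracle_reps, 50))
        xb = rng.normal(1.0, 1.0, (oracle_reps, 50))
        va = xa.var(axis=1, ddof=1)
        vb = xb.var(axis=1, ddof=1)
        sp = np.sqrt((49 * va + 49 * vb) / 98)
        tstat = (xa.mean(axis=1) - xb.mean(axis=1)) / (sp * np.sqrt(2 / 50))
        p_oracle = 2 * sps.t.sf(np.abs(tstat), df=98)
        power_oracle = float(np.mean(p_oracle <= alpha))
        power_dispatch = rej_dispatch / reps
        # binomial sampling band around the oracle power
        se = math.sqrt(power_oracle * (1 - power_oracle) / reps)
        assert abs(power_dispatch - power_oracle) <= 4 * se + 1e-9


class TestSignificanceRule:
    @pytest.mark.parametrize(
        "p, expected", [(0.0019, True), (0.002, True), (0.0021, False)]
    )
    def test_inclusive_alpha(self, p, expected):
        assert significant(p) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significant(1.5)


class TestKpsBinarization:
    @pytest.mark.parametrize(
        "kps, impaired", [(90, False), (80, True), (100, False), (0, True)]
    )
    def test_cutoff_excludes_90(self, kps, impaired):
        assert binarize_kps(kps) is impaired

    def test_off_scale_rejected(self):
        with pytest.raises(ValueError):
            binarize_kps(85)

    def test_custom_cutoff(self):
        cfg = AnalysisConfig(kps_cutoff=70)
        assert binarize_kps(60, cfg) is True
        assert binarize_kps(70, cfg) is False
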