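"""Association statistics against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bgrisk.stats import (
    AssociationResult,
    ContingencyTable,
    GroupSummary,
    linear_by_linear,
    one_way_anova_raw,
    one_way_anova_summary,
    pearson_chi_square,
    pearson_correlation,
    pooled_total_summary,
    roc_auc,
)

# published cross-tabs used as worked examples (verified independently below)
GRADING_BY_SCORE = [[9, 3, 1, 0], [8, 12, 8, 8], [2, 5, 2, 0]]
GENDER_BY_SCORE = [[15, 15, 10, 8], [4, 5, 1, 0]]
PN_BY_SCORE = [[9, 9, 2, 1], [7, 6, 4, 2], [1, 4, 1, 2], [2, 1, 4, 3]]

tables_2x2 = st.lists(
    st.integers(min_value=1, max_value=50), min_size=4, max_size=4
).map(lambda v: np.array(v, float).reshape(2, 2))


def chi_square_oracle(counts):
    """Hand-summed (O-E)^2/E with E = row*col/N."""
    c = np.asarray(counts, float)
    n = c.sum()
    stat = 0.0
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            e = c[i].sum() * c[:, j].sum() / n
            stat += (c[i, j] - e) ** 2 / e
    return stat


def trend_oracle(counts):
    """Brute-force M2: expand the table to N (row, col) pairs, correlate."""
    c = np.asarray(counts, int)
    xs, ys = [], []
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            xs += [i] * c[i, j]
            ys += [j] * c[i, j]
    r = np.corrcoef(xs, ys)[0, 1]
    return (len(xs) - 1) * r**2


class TestPearsonChiSquare:
    def test_grading_by_score_matches_hand_oracle(self):
        tab = ContingencyTable(np.array(GRADING_BY_SCORE))
        res = pearson_chi_square(tab)
        assert res.statistic == pytest.approx(chi_square_oracle(GRADING_BY_SCORE))
        assert res.statistic == pytest.approx(14.48, abs=0.01)
        assert res.df == 6
        assert res.p_value == pytest.approx(0.025, abs=0.002)

    def test_gender_by_score_p(self):
        res = pearson_chi_square(ContingencyTable(np.array(GENDER_BY_SCORE)))
        assert res.p_value == pytest.approx(0.360, abs=0.002)

    def test_proportional_rows_give_zero_statistic(self):
        res = pearson_chi_square(ContingencyTable(np.array([[10, 20], [5, 10]])))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @settings(deadline=None)
    @given(tables_2x2)
    def test_2x2_closed_form(self, tab):
        a, b, c, d = tab.ravel()
        n = tab.sum()
        expected = (
            n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        res = pearson_chi_square(ContingencyTable(tab))
        assert res.statistic == pytest.approx(expected, rel=1e-10)

    def test_row_and_column_permutation_invariance(self, rng):
        tab = rng.integers(1, 30, size=(3, 4)).astype(float)
        base = pearson_chi_square(ContingencyTable(tab))
        perm = tab[rng.permutation(3)][:, rng.permutation(4)]
        assert pearson_chi_square(ContingencyTable(perm)).statistic == pytest.approx(
            base.statistic
        )

    def test_empty_level_dropped_with_warning(self):
        tab = ContingencyTable(
            np.array([[5, 5, 0], [3, 7, 0], [2, 8, 0]]),
            row_labels=("a", "b", "c"),
            col_labels=("x", "y", "z"),
        )
        with pytest.warns(UserWarning, match="dropping empty"):
            res = pearson_chi_square(tab)
        assert res.df == 2  # (3-1)(2-1) after dropping column z

    def test_low_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected count"):
            pearson_chi_square(ContingencyTable(np.array([[1, 9], [2, 8]])))


class TestLinearByLinear:
    def test_pn_by_score_matches_expanded_pair_oracle(self):
        res = linear_by_linear(ContingencyTable(np.array(PN_BY_SCORE)))
        assert res.statistic == pytest.approx(trend_oracle(PN_BY_SCORE), rel=1e-12)
        assert res.statistic == pytest.approx(7.93, abs=0.01)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.005, abs=0.002)

    def test_independent_margins_give_zero(self):
        row = np.array([2, 3, 5], float)
        col = np.array([4, 6], float)
        tab = np.outer(row, col)  # zero score correlation by construction
        res = linear_by_linear(ContingencyTable(tab))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @settings(deadline=None)
    @given(tables_2x2)
    def test_2x2_identity_with_pearson(self, tab):
        n = tab.sum()
        m2 = linear_by_linear(ContingencyTable(tab)).statistic
        chi2 = pearson_chi_square(ContingencyTable(tab)).statistic
        assert m2 == pytest.approx((n - 1) / n * chi2, rel=1e-10)

    def test_affine_score_rescaling_invariance(self):
        tab = np.array(PN_BY_SCORE, float)
        base = linear_by_linear(ContingencyTable(tab)).statistic
        scaled = linear_by_linear(
            ContingencyTable(
                tab,
                row_scores=tuple(5.0 + 2.0 * i for i in range(4)),
                col_scores=tuple(-1.0 - 0.5 * j for j in range(4)),
            )
        ).statistic
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            linear_by_linear(
                ContingencyTable(np.array([[1, 2], [3, 4]]), row_scores=(1.0, 1.0))
            )


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        res = one_way_anova_raw([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(i, 1.5, size=n) for i, n in enumerate((7, 12, 9))]
        res = one_way_anova_raw(groups)
        f, p = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_zero_within_variance_reports_p_zero_with_warning(self):
        with pytest.warns(UserWarning, match="within-group"):
            res = one_way_anova_raw([[1.0, 1.0], [2.0, 2.0]])
        assert res.p_value == 0.0

    def test_summary_age_groups_reproduce_published_p(self):
        summaries = [
            GroupSummary(3, 11.14, 2.74),
            GroupSummary(10, 16.39, 11.69),
            GroupSummary(14, 24.34, 14.11),
            GroupSummary(13, 16.77, 6.28),
            GroupSummary(18, 31.18, 11.82),
        ]
        res = one_way_anova_summary(summaries)
        assert res.statistic == pytest.approx(5.13, abs=0.01)
        assert (res.df, res.extra["df_within"]) == (4, 53)
        assert res.p_value == pytest.approx(0.001, abs=0.005)

    def test_summary_doi_by_nodal_status(self):
        summaries = [
            GroupSummary(20, 0.79, 0.30),
            GroupSummary(18, 1.17, 0.58),
            GroupSummary(8, 1.78, 1.13),
            GroupSummary(9, 1.23, 0.50),
        ]
        assert one_way_anova_summary(summaries).p_value == pytest.approx(
            0.003, abs=0.005
        )

    def test_two_identical_summaries(self):
        s = GroupSummary(5, 3.0, 1.0)
        res = one_way_anova_summary([s, s])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova_summary([GroupSummary(1, 1.0), GroupSummary(1, 2.0)])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_summary_equals_raw_on_any_data(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        groups = [rng.normal(rng.normal(), 2.0, size=int(rng.integers(2, 12)))
                  for _ in range(k)]
        summaries = [
            GroupSummary(len(g), float(np.mean(g)), float(np.std(g, ddof=1)))
            for g in groups
        ]
        raw = one_way_anova_raw(groups)
        summ = one_way_anova_summary(summaries)
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10, rel=1e-10)
        assert summ.p_value == pytest.approx(raw.p_value, abs=1e-10)

    def test_type_one_error_calibrated(self, rng):
        rej = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(0, 1, size=8) for _ in range(4)]
            rej += one_way_anova_raw(groups).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3 * se


class TestPooledTotal:
    def test_published_total_row_reconstructed(self):
        summaries = [
            GroupSummary(3, 11.14, 2.74),
            GroupSummary(10, 16.39, 11.69),
            GroupSummary(14, 24.34, 14.11),
            GroupSummary(13, 16.77, 6.28),
            GroupSummary(18, 31.18, 11.82),
        ]
        total = pooled_total_summary(summaries)
        assert total.n == 58
        assert round(total.mean, 2) == 22.71
        assert round(total.sd, 2) == 12.75

    def test_single_group_identity(self):
        s = GroupSummary(7, 4.2, 1.1)
        assert pooled_total_summary([s]) == s

    def test_matches_concatenated_raw_data(self, rng):
        groups = [rng.normal(rng.normal(), 1.0, size=int(n))
                  for n in rng.integers(2, 10, size=4)]
        summaries = [
            GroupSummary(len(g), float(np.mean(g)), float(np.std(g, ddof=1)))
            for g in groups
        ]
        total = pooled_total_summary(summaries)
        cat = np.concatenate(groups)
        assert total.mean == pytest.approx(cat.mean(), rel=1e-12)
        assert total.sd == pytest.approx(np.std(cat, ddof=1), rel=1e-10)


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, x).statistic == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        res = pearson_correlation(x, y)
        assert res.extra["n"] == 3
        assert res.statistic == pytest.approx(1.0)

    def test_known_correlation_recovered(self, rng):
        # average r over replicates at true rho = 0.3
        rho, reps = 0.3, 300
        rs = []
        for _ in range(reps):
            x = rng.normal(size=55)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=55)
            rs.append(pearson_correlation(x, y).statistic)
        assert np.mean(rs) == pytest.approx(rho, abs=0.03)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_null_predictor_near_half(self, rng):
        x = rng.normal(size=4000)
        y = rng.integers(0, 2, size=4000)
        assert roc_auc(x, y).auc == pytest.approx(0.5, abs=0.04)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=30).astype(float)  # ties on purpose
        y = np.r_[np.ones(12, int), np.zeros(18, int)]
        pos, neg = x[y == 1], x[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        oracle = wins / (len(pos) * len(neg))
        oracle = max(oracle, 1 - oracle)  # implementation orients >= 0.5
        assert roc_auc(x, y).auc == pytest.approx(oracle, rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        base = roc_auc(x, y).auc
        assert roc_auc(np.exp(x), y).auc == pytest.approx(base, rel=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])


def test_association_result_rejects_invalid_p():
    with pytest.raises(ValueError):
        AssociationResult("m", 1.0, 1, 1.5)
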