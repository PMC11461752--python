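"""Kendall tau-b against independent oracles, plus tables and summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import obsconf as oc
from obsconf import AccuracyLabel, Band, OrdinalCoding, QualityGrade, Strength

from conftest import make_record


def brute_force_tau_b(x, y):
    """All-pairs enumeration of the tie-corrected tau. Independent oracle."""
    n = len(x)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = (x[i] - x[j]) * (y[i] - y[j])
            if prod > 0:
                concordant += 1
            elif prod < 0:
                discordant += 1
    n0 = n * (n - 1) // 2
    n1 = sum(
        sum(1 for j in range(i + 1, n) if x[i] == x[j]) for i in range(n)
    )
    n2 = sum(
        sum(1 for j in range(i + 1, n) if y[i] == y[j]) for i in range(n)
    )
    return (concordant - discordant) / math.sqrt((n0 - n1) * (n0 - n2)), concordant, discordant


ordinal_pairs = st.lists(
    st.tuples(st.integers(0, 3), st.integers(0, 2)), min_size=2, max_size=30
).filter(
    lambda pairs: len({p[0] for p in pairs}) > 1 and len({p[1] for p in pairs}) > 1
)


class TestKendallTauB:
    def test_perfect_concordance(self):
        assert oc.kendall_tau_b([1, 2, 3], [1, 2, 3]).tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert oc.kendall_tau_b([1, 2, 3], [3, 2, 1]).tau == pytest.approx(-1.0)

    def test_tied_table_matches_pairwise_enumeration(self):
        # a 3x3 tied layout with 12 observations: 66 pairs enumerated by the oracle
        x = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]
        y = [0, 0, 1, 2, 0, 1, 1, 2, 1, 2, 2, 2]
        expected_tau, expected_c, expected_d = brute_force_tau_b(x, y)
        result = oc.kendall_tau_b(x, y)
        assert result.tau == pytest.approx(expected_tau)
        assert (result.concordant, result.discordant) == (expected_c, expected_d)
        assert result.concordant + result.discordant <= 66

    @given(ordinal_pairs)
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle_on_random_tied_instances(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        expected_tau, expected_c, expected_d = brute_force_tau_b(x, y)
        result = oc.kendall_tau_b(x, y)
        assert result.tau == pytest.approx(expected_tau)
        assert (result.concordant, result.discordant) == (expected_c, expected_d)

    @given(ordinal_pairs)
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_reference(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        expected = sps.kendalltau(x, y, variant="b").statistic
        assert oc.kendall_tau_b(x, y).tau == pytest.approx(expected)

    @given(ordinal_pairs)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_reversal_and_invariant_under_monotone_relabel(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        tau = oc.kendall_tau_b(x, y).tau
        assert oc.kendall_tau_b(x, [-v for v in y]).tau == pytest.approx(-tau)
        relabeled = [v * 10 + 7 for v in x]  # strictly monotone relabelling
        assert oc.kendall_tau_b(relabeled, y).tau == pytest.approx(tau)

    def test_tie_terms_reported(self):
        result = oc.kendall_tau_b([0, 0, 1, 1], [0, 1, 0, 1])
        assert result.ties_x == 2 and result.ties_y == 2

    def test_constant_sequence_is_an_error_not_nan(self):
        with pytest.raises(oc.ZeroVarianceError):
            oc.kendall_tau_b([1, 1, 1], [1, 2, 3])
        with pytest.raises(oc.ZeroVarianceError):
            oc.kendall_tau_b([1, 2, 3], [5, 5, 5])


class TestPValue:
    def test_balanced_pairs_give_p_one(self):
        result = oc.kendall_tau_b([0, 0, 1, 1], [0, 1, 0, 1])  # C == D == 1
        assert result.concordant == result.discordant
        assert result.p_value == pytest.approx(1.0)

    def test_smallest_valid_n_computes(self):
        result = oc.kendall_tau_b([1, 2], [1, 2])
        assert 0.0 <= result.p_value <= 1.0

    def test_normal_approximation_matches_closed_form(self):
        result = oc.kendall_tau_b([0, 1, 2, 3, 4], [0, 1, 2, 4, 3])
        s = result.concordant - result.discordant
        n = result.n
        z = 3 * s / math.sqrt(n * (n - 1) * (2 * n + 5) / 2)
        assert result.p_value == pytest.approx(2 * sps.norm.sf(abs(z)))
        assert oc.tau_p_value(result) == pytest.approx(result.p_value)

    def test_strong_concordance_at_n_1000_is_significant(self):
        dataset = oc.generate_dataset(
            oc.GeneratorParams(n=1000, association=0.9, stop_rate=0.0, seed=1))
        scored = oc.score_set(dataset.observations, dataset.registry)
        result = oc.correlate(scored, "confidence", "accuracy")
        assert result.p_value < 0.001

    def test_exact_permutation_oracle_at_tiny_n(self):
        # Exhaustive permutation distribution of S = C - D at n = 6:
        # the normal approximation should agree loosely even this small.
        import itertools

        x = [0, 0, 1, 1, 2, 2]
        y = [0, 1, 0, 2, 1, 2]
        observed = oc.kendall_tau_b(x, y)
        s_obs = observed.concordant - observed.discordant
        count = total = 0
        for perm in itertools.permutations(y):
            r = oc.kendall_tau_b(x, list(perm))
            if abs(r.concordant - r.discordant) >= abs(s_obs):
                count += 1
            total += 1
        exact_p = count / total
        assert observed.p_value == pytest.approx(exact_p, abs=0.15)


class TestStrength:
    @pytest.mark.parametrize("tau, label", [
        (0.82, Strength.STRONG),
        (0.16, Strength.WEAK),
        (-0.05, Strength.NEGLIGIBLE),
        (0.10, Strength.WEAK),       # lower-inclusive edge
        (0.40, Strength.MODERATE),
        (0.70, Strength.STRONG),
        (0.90, Strength.VERY_STRONG),
        (-1.0, Strength.VERY_STRONG),
    ])
    def test_banding(self, tau, label):
        assert oc.interpret_strength(tau) is label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            oc.interpret_strength(1.2)


def scored_from_triples(triples):
    """Build a ScoredSet from (band, accuracy, grade) triples via real scoring."""
    reg = oc.case_study_registry()
    templates = {
        "high": ("Carcinus maenas", oc.MediaClarity.CLEAR, oc.FeaturesShown.ALL, 250.0),
        "medium": ("Watersipora subtorquata", oc.MediaClarity.CLEAR, oc.FeaturesShown.MOST, 5000.0),
        "low": ("Bugulina flabellata", oc.MediaClarity.POOR, oc.FeaturesShown.SOME, 25000.0),
        "unscorable": ("Ulva lactuca", oc.MediaClarity.CLEAR, oc.FeaturesShown.ALL, 250.0),
    }
    records = []
    for i, (band, acc, grade) in enumerate(triples):
        sp, cl, sh, radius = templates[band]
        records.append(make_record(f"t{i}", species=sp, clarity=cl, shown=sh,
                                   accuracy=radius, grade=QualityGrade(grade),
                                   label=AccuracyLabel(acc)))
    return oc.score_set(oc.ObservationSet(records), reg)


class TestCrosstabAndSummary:
    def test_single_cell_table(self):
        scored = scored_from_triples([("high", "correct", "research_grade")] * 10)
        table = oc.crosstab(scored, "confidence", "accuracy")
        assert table.grand_total == 10
        assert table.counts[table.row_labels.index("high"),
                            table.col_labels.index("correct")] == 10

    def test_empty_set_rejected(self):
        empty = oc.ScoredSet(oc.ObservationSet([]), [])
        with pytest.raises(oc.DataError, match="empty_input"):
            oc.crosstab(empty, "confidence", "accuracy")
        with pytest.raises(oc.DataError, match="empty_input"):
            oc.summarize_proportions(empty)

    def test_unknown_variable_rejected(self):
        scored = scored_from_triples([("high", "correct", "research_grade")] * 2)
        with pytest.raises(ValueError, match="unknown variable"):
            oc.crosstab(scored, "confidence", "season")

    def test_marginals_agree_with_summary(self):
        triples = (
            [("high", "correct", "research_grade")] * 5
            + [("medium", "correct", "needs_id")] * 4
            + [("medium", "uncertain", "research_grade")] * 3
            + [("low", "incorrect", "casual")] * 2
            + [("unscorable", "uncertain", "needs_id")] * 6
        )
        scored = scored_from_triples(triples)
        table = oc.crosstab(scored, "confidence", "quality_grade")
        report = oc.summarize_proportions(scored)
        assert table.row_totals() == dict(report.band_counts)
        assert table.col_totals() == dict(report.grade_counts)

    def test_correlate_delegates_and_drops_unscorable_on_request(self):
        triples = (
            [("high", "correct", "research_grade")] * 4
            + [("medium", "uncertain", "needs_id")] * 4
            + [("low", "incorrect", "casual")] * 4
            + [("unscorable", "uncertain", "needs_id")] * 4
        )
        scored = scored_from_triples(triples)
        full = oc.correlate(scored, "confidence", "accuracy")
        assert full.n == 16 and full.n_dropped == 0
        dropped = oc.correlate(scored, "confidence", "accuracy",
                               OrdinalCoding(include_unscorable=False))
        assert dropped.n == 12 and dropped.n_dropped == 4
        assert dropped.tau == pytest.approx(1.0)

    def test_reversed_coding_negates_tau(self):
        triples = (
            [("high", "correct", "research_grade")] * 4
            + [("medium", "uncertain", "needs_id")] * 3
            + [("low", "incorrect", "casual")] * 4
        )
        scored = scored_from_triples(triples)
        forward = oc.correlate(scored, "confidence", "accuracy")
        reversed_coding = OrdinalCoding(accuracy_order=("correct", "uncertain", "incorrect"))
        backward = oc.correlate(scored, "confidence", "accuracy", reversed_coding)
        assert backward.tau == pytest.approx(-forward.tau)

    def test_percentages_round_half_up_at_one_decimal(self):
        assert oc.round_half_up(23.65, 1) == 23.7
        assert oc.round_half_up(23.64999, 1) == 23.6
        scored = scored_from_triples(
            [("high", "correct", "research_grade")] * 1
            + [("low", "incorrect", "casual")] * 15
        )
        report = oc.summarize_proportions(scored)
        assert report.band_percentages()["high"] == 6.3  # 6.25 rounds half-up

    def test_all_high_retention_is_total(self):
        scored = scored_from_triples([("high", "correct", "research_grade")] * 10)
        report = oc.summarize_proportions(scored)
        assert report.band_percentages()["high"] == 100.0
        assert report.retained_fraction == 100.0
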