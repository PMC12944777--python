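import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ruleout import (
    Cohort,
    ConfigurationError,
    ExamRecord,
    InputError,
    StratifiedCounts,
    adjusted_net_for,
    as_percent,
    bayes_predictive,
    caseload_reduction_rate,
    compute_metrics,
    fdr,
    gross_for,
    is_defined,
    net_for,
    net_missed_count,
    npv,
    ppv,
    round_half_away,
    sensitivity_specificity,
    stratify,
)
from ruleout import datasets

cells_strategy = st.tuples(*[st.integers(0, 2000) for _ in range(8)])


def make_counts(cells, threshold=0.5):
    b, c, d, e, g, h, i, j = cells
    return StratifiedCounts(threshold, b, c, d, e, g, h, i, j)


class TestStratify:
    def test_four_record_example(self, toy_cohort):
        ct = stratify(toy_cohort, 0.2)
        assert (ct.b, ct.c, ct.d, ct.e) == (1, 0, 0, 1)
        assert (ct.g, ct.h, ct.i, ct.j) == (0, 1, 1, 0)
        assert ct.f == ct.k == 2

    def test_threshold_zero_rules_out_nothing(self, toy_cohort):
        ct = stratify(toy_cohort, 0.0)
        assert ct.f == 0 and ct.k == 4

    def test_score_equal_to_threshold_is_ruled_out(self):
        coh = Cohort.from_records([ExamRecord("a", 0.2, False, False)])
        assert stratify(coh, 0.2).f == 1

    def test_reference_row_at_020(self, pseudo_cohort):
        ct = stratify(pseudo_cohort, 0.20)
        assert (ct.b, ct.c, ct.d, ct.e) == (79194, 82, 5803, 141)
        assert (ct.g, ct.h, ct.i, ct.j) == (24995, 66, 3373, 575)
        assert ct.f == 85220 and ct.k == 29009

    def test_threshold_outside_unit_interval_rejected(self, toy_cohort):
        with pytest.raises(ConfigurationError):
            stratify(toy_cohort, 1.5)

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_partition_invariants_on_random_cohorts(self, data):
        seed = data.draw(st.integers(0, 10_000))
        t = data.draw(st.floats(0, 1))
        from conftest import random_cohort

        coh = random_cohort(np.random.default_rng(seed), n=100)
        ct = stratify(coh, t)
        assert ct.n == len(coh)
        assert ct.cancers == coh.n_cancer


class TestRates:
    """Rate formulas against the bundled reference table's worked numbers."""

    @pytest.fixture
    def ct20(self):
        return datasets.counts_at(0.20)

    @pytest.fixture
    def ct05(self):
        return datasets.counts_at(0.05)

    def test_crr(self, ct20, ct05):
        assert as_percent(caseload_reduction_rate(ct20)) == 74.60
        assert as_percent(caseload_reduction_rate(ct05)) == 36.00

    def test_gross_for(self, ct20, ct05):
        assert as_percent(gross_for(ct20)) == 0.26
        assert as_percent(gross_for(ct05)) == 0.12

    def test_net_for(self, ct20, ct05):
        assert as_percent(net_for(ct20)) == 0.17
        assert as_percent(net_for(ct05)) == 0.07

    def test_adjusted_net_for(self, ct20):
        assert as_percent(adjusted_net_for(ct20, 0.30)) == 0.14
        assert adjusted_net_for(ct20, 0.0) == net_for(ct20)
        # strongly negative scenario at a low threshold
        ct02 = datasets.counts_at(0.02)
        assert as_percent(adjusted_net_for(ct02, 0.30)) == -0.37

    def test_net_missed_counts(self, ct20, ct05):
        assert net_missed_count(ct20, 0.30) == 121
        assert net_missed_count(ct20, 0.70) == 95
        assert net_missed_count(ct05, 0.30, clamp=True) == 0
        assert net_missed_count(ct05, 0.30) < 0

    def test_fdr_ppv(self, ct20, ct05):
        assert as_percent(fdr(ct20)) == 97.79
        assert as_percent(fdr(ct05)) == 98.89
        assert fdr(ct20) + ppv(ct20) == pytest.approx(1.0, abs=1e-15)

    def test_sensitivity_specificity(self, ct20):
        sens, spec = sensitivity_specificity(ct20)
        assert sens == pytest.approx(641 / 864)
        assert spec == pytest.approx(84997 / 113365)
        assert round(sens, 2) == 0.74 and round(spec, 2) == 0.75

    def test_undefined_sentinel_when_nothing_ruled_out(self):
        ct = StratifiedCounts(0.0, 0, 0, 0, 0, 10, 1, 2, 1)
        for fn in (gross_for, net_for, npv):
            assert not is_defined(fn(ct))
        assert not is_defined(adjusted_net_for(ct, 0.3))
        assert caseload_reduction_rate(ct) == 0.0

    def test_undefined_sentinel_when_nothing_retained(self):
        ct = StratifiedCounts(1.0, 10, 1, 2, 1, 0, 0, 0, 0)
        assert not is_defined(fdr(ct))
        assert not is_defined(ppv(ct))


class TestBayes:
    def test_uninformative_test_gives_prevalence(self):
        p, _ = bayes_predictive(0.5, 0.5, 0.3)
        assert p == pytest.approx(0.3)

    def test_perfect_test(self):
        assert bayes_predictive(1.0, 1.0, 0.1) == (1.0, 1.0)

    def test_degenerate_zero_over_zero_is_sentinel(self):
        p, n = bayes_predictive(0.0, 1.0, 0.0)
        assert not is_defined(p) and n == 1.0

    def test_identity_with_count_ratios_exact_rational(self, ref_table):
        """Bayes predictive values reproduce count ratios on every table row."""
        for _, r in ref_table.iterrows():
            B, C, D, E = (int(r[k]) for k in "BCDE")
            G, H, I, J = (int(r[k]) for k in "GHIJ")
            cancers, noncancers = C + E + H + J, B + D + G + I
            sens = Fraction(H + J, cancers)
            spec = Fraction(B + D, noncancers)
            prev = Fraction(cancers, cancers + noncancers)
            K, F = G + H + I + J, B + C + D + E
            ppv_b = (sens * prev) / (sens * prev + (1 - spec) * (1 - prev))
            assert ppv_b == Fraction(H + J, K)
            p_f, n_f = bayes_predictive(float(sens), float(spec), float(prev))
            assert p_f == pytest.approx(float(ppv_b), abs=1e-12)
            if F > 0:  # NPV is a 0/0 form when nothing is ruled out
                npv_b = (spec * (1 - prev)) / (spec * (1 - prev) + (1 - sens) * prev)
                assert npv_b == Fraction(B + D, F)
                assert n_f == pytest.approx(float(npv_b), abs=1e-12)


class TestMetricSetProperties:
    @given(cells_strategy)
    @settings(max_examples=200, deadline=None)
    def test_complementarity_and_ordering(self, cells):
        ct = make_counts(cells)
        if ct.n == 0:
            return
        m = compute_metrics(ct)
        if ct.f > 0:
            assert m.npv + m.g_for == pytest.approx(1.0, abs=1e-12)
            # AN-FOR(f) ≤ N-FOR ≤ G-FOR, AN-FOR monotone non-increasing in f
            assert m.n_for <= m.g_for + 1e-15
            prev_v = math.inf
            for f in sorted(m.an_for):
                v = m.an_for[f]
                assert v <= m.n_for + 1e-15
                assert v <= prev_v + 1e-15
                prev_v = v
            assert m.an_for[0.1] == pytest.approx(adjusted_net_for(ct, 0.1))
        if ct.k > 0:
            assert m.ppv + m.fdr == pytest.approx(1.0, abs=1e-12)
        if is_defined(m.youden_j):
            assert m.youden_j == pytest.approx(m.sensitivity + m.specificity - 1.0)

    def test_anfor_zero_fraction_equals_nfor(self):
        ct = make_counts((5, 1, 2, 3, 10, 4, 2, 6))
        assert adjusted_net_for(ct, 0.0) == net_for(ct)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.005, 0.01), (-0.005, -0.01), (-0.375, -0.38), (98.885, 98.89), (0.2649, 0.26)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x, 2) == expected

    def test_nan_passthrough(self):
        assert math.isnan(round_half_away(float("nan")))
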