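"""Decision rules: multipliers, funding tests, and their equivalences."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spillover_cea import (
    CostDelta,
    HealthEffect,
    MultiplierPair,
    ThresholdSpec,
    UndefinedMultiplierError,
    Verdict,
    ZeroDisplacedHealthError,
    conventional_decision,
    direct_spillover_decision,
    displaced_multiplier,
    generated_multiplier,
    net_health_benefit,
    spillover_decision,
)
from spillover_cea.errors import ConfigurationError

THRESHOLD = ThresholdSpec(k_p=20_000)


class TestHealthEffect:
    def test_aggregate_is_sum_of_components(self):
        effect = HealthEffect(1.0, (0.25, 0.5, -0.1))
        assert effect.network_delta == pytest.approx(0.65)
        assert effect.total_delta == pytest.approx(1.65)

    def test_empty_network_means_zero_spillover(self):
        assert HealthEffect(2.0).network_delta == 0.0

    def test_rejects_non_finite_components(self):
        with pytest.raises(ValueError):
            HealthEffect(float("nan"))
        with pytest.raises(ValueError):
            HealthEffect(1.0, (float("inf"),))


class TestGeneratedMultiplier:
    @pytest.mark.parametrize(
        ("patient", "network", "expected"),
        [
            # annual health losses averted: same-signed decrements
            (-0.109, (-0.030,), 1.28),
            (-0.041, (-0.023, -0.023), 2.12),
            (-0.226, (-0.005,), 1.02),
        ],
    )
    def test_published_decrement_pairs(self, patient, network, expected):
        m = generated_multiplier(HealthEffect(patient, network))
        assert round(m, 2) == pytest.approx(expected)

    def test_empty_network_gives_exactly_one(self):
        assert generated_multiplier(HealthEffect(0.7)) == 1.0

    def test_opposite_signed_spillover_shrinks_multiplier(self):
        assert generated_multiplier(HealthEffect(1.0, (-0.5,))) == pytest.approx(0.5)

    def test_zero_patient_delta_refers_to_direct_rule(self):
        with pytest.raises(UndefinedMultiplierError, match="direct_spillover_decision"):
            generated_multiplier(HealthEffect(0.0, (1.0,)))

    @pytest.mark.parametrize("n", [1, 2, 3, 8])
    def test_additivity_in_identical_members(self, n):
        p, c = 0.4, 0.1
        m = generated_multiplier(HealthEffect(p, (c,) * n))
        assert m == pytest.approx(1 + n * c / p)

    def test_monotone_in_network_size_for_same_signed_effects(self):
        ms = [
            generated_multiplier(HealthEffect(-0.2, (-0.05,) * n)) for n in range(5)
        ]
        assert ms == sorted(ms)
        assert ms[0] == 1.0


class TestDisplacedMultiplier:
    @pytest.mark.parametrize(
        ("patient", "network", "expected"),
        [
            (100.0, (16.0,), 1.16),
            (100.0, (16.0, 16.0), 1.32),
            (250.0, (), 1.0),
        ],
    )
    def test_displacement_examples(self, patient, network, expected):
        m = displaced_multiplier(HealthEffect(patient, network))
        assert m == pytest.approx(expected)


class TestThresholdSpec:
    def test_displacement_arithmetic_matches_budget(self):
        spec = ThresholdSpec(
            k_p=20_000,
            displaced_patient_per_budget=5e-5,
            displaced_network_per_member_per_budget=8e-6,
        )
        assert spec.displaced_patient_units(2e6) == pytest.approx(100.0)
        assert spec.displaced_network_units(2e6, 2) == pytest.approx(32.0)
        assert spec.displacement_multiplier(1) == pytest.approx(1.16)
        assert spec.displacement_multiplier(2) == pytest.approx(1.32)

    def test_inconsistent_threshold_and_displacement_rate_rejected(self):
        with pytest.raises(ConfigurationError, match="inconsistent"):
            ThresholdSpec(k_p=20_000, displaced_patient_per_budget=1e-3)

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            ThresholdSpec(k_p=0)


class TestConventionalDecision:
    def test_funds_below_threshold(self):
        d = conventional_decision(CostDelta(2_000_000), 120.0, THRESHOLD)
        assert d.verdict is Verdict.FUND
        assert d.icer == pytest.approx(2_000_000 / 120)

    def test_rejects_above_threshold(self):
        d = conventional_decision(CostDelta(2_000_000), 80.0, THRESHOLD)
        assert d.verdict is Verdict.REJECT

    def test_exact_tie_rejects(self):
        d = conventional_decision(2_000_000, 100.0, THRESHOLD)
        assert d.icer == pytest.approx(THRESHOLD.k_p)
        assert d.verdict is Verdict.REJECT

    def test_non_positive_benefit_is_verdict_not_exception(self):
        assert (
            conventional_decision(1000.0, -1.0, THRESHOLD).verdict is Verdict.DOMINATED
        )
        d = conventional_decision(1000.0, 0.0, THRESHOLD)
        assert d.verdict is Verdict.INDETERMINATE
        assert d.code == "zero-patient-benefit"


class TestSpilloverDecision:
    def test_large_generated_multiplier_flips_to_fund(self):
        d = spillover_decision(
            2_000_000, 120.0, MultiplierPair(1.56, 1.32), THRESHOLD
        )
        assert d.verdict is Verdict.FUND

    def test_small_generated_multiplier_flips_to_reject(self):
        d = spillover_decision(
            2_000_000, 120.0, MultiplierPair(1.04, 1.32), THRESHOLD
        )
        assert d.verdict is Verdict.REJECT

    def test_equal_multipliers_reduce_to_conventional(self):
        for benefit in (80.0, 100.0, 120.0):
            conv = conventional_decision(2_000_000, benefit, THRESHOLD)
            adj = spillover_decision(
                2_000_000, benefit, MultiplierPair(1.3, 1.3), THRESHOLD
            )
            assert adj.verdict is conv.verdict

    def test_non_positive_mi_refers_to_direct_rule(self):
        with pytest.raises(UndefinedMultiplierError, match="direct_spillover_decision"):
            spillover_decision(1000.0, 10.0, MultiplierPair(-0.2, 1.1), THRESHOLD)


class TestDirectSpilloverDecision:
    def test_generated_stream_beats_displaced(self):
        d = direct_spillover_decision(
            2e6, HealthEffect(120.0, (33.6,)), 2e6, HealthEffect(100.0, (16.0,))
        )
        assert d.verdict is Verdict.FUND  # 153.6 > 116 per £2M

    def test_identical_streams_reject_on_strict_inequality(self):
        eff = HealthEffect(100.0, (16.0,))
        d = direct_spillover_decision(2e6, eff, 2e6, eff)
        assert d.verdict is Verdict.REJECT

    def test_small_spillovers_lose_to_displaced_stream(self):
        d = direct_spillover_decision(
            2e6,
            HealthEffect(120.0, (2.4, 2.4)),
            2e6,
            HealthEffect(100.0, (16.0, 16.0)),
        )
        assert d.verdict is Verdict.REJECT  # 124.8 < 132

    def test_zero_displaced_health_is_an_error(self):
        with pytest.raises(ZeroDisplacedHealthError):
            direct_spillover_decision(
                1e6, HealthEffect(50.0), 1e6, HealthEffect(10.0, (-10.0,))
            )

    def test_non_positive_generated_total_rejects(self):
        d = direct_spillover_decision(
            1e6, HealthEffect(5.0, (-9.0,)), 1e6, HealthEffect(50.0)
        )
        assert d.verdict is Verdict.REJECT


class TestNetHealthBenefit:
    @pytest.mark.parametrize(
        ("generated", "displaced", "expected"),
        [(187.0, 132.0, 55.0), (132.0, 132.0, 0.0), (114.0, 132.0, -18.0)],
    )
    def test_accounting(self, generated, displaced, expected):
        assert net_health_benefit(generated, displaced) == expected


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)
multiplier_vals = st.floats(min_value=0.05, max_value=20.0)


@settings(max_examples=300, derandomize=True)
@given(cost=positive, benefit=positive, m=multiplier_vals, k_p=positive)
def test_equal_multipliers_never_change_the_verdict(cost, benefit, m, k_p):
    """With m_i == m_d the adjusted rule is the conventional rule."""
    threshold = ThresholdSpec(k_p=k_p)
    conv = conventional_decision(cost, benefit, threshold)
    adj = spillover_decision(cost, benefit, MultiplierPair(m, m), threshold)
    assert adj.verdict is conv.verdict


@settings(max_examples=300, derandomize=True)
@given(
    cost=positive,
    benefit=positive,
    m_i=multiplier_vals,
    m_d=multiplier_vals,
    k_p=positive,
)
def test_ratio_form_agrees_with_direct_form_on_consistent_streams(
    cost, benefit, m_i, m_d, k_p
):
    """Eq-7-style rule == two-stream comparison when streams encode (m_i, m_d, k_p).

    The displaced stream is constructed from the threshold: spending `cost`
    displaces cost/k_p patient units and (m_d − 1)·cost/k_p network units.
    """
    threshold = ThresholdSpec(k_p=k_p)
    ratio_form = spillover_decision(cost, benefit, MultiplierPair(m_i, m_d), threshold)
    generated = HealthEffect(benefit, (benefit * (m_i - 1.0),))
    displaced_patient = cost / k_p
    displaced = HealthEffect(displaced_patient, (displaced_patient * (m_d - 1.0),))
    direct = direct_spillover_decision(cost, generated, cost, displaced)
    assert direct.verdict is ratio_form.verdict


@settings(max_examples=300, derandomize=True)
@given(
    cost=positive,
    benefit=positive,
    m_i=multiplier_vals,
    m_d=multiplier_vals,
    k_p=positive,
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_verdicts_invariant_to_joint_currency_rescaling(
    cost, benefit, m_i, m_d, k_p, scale
):
    """Re-denominating the currency of Δc and k_p together changes nothing."""
    pair = MultiplierPair(m_i, m_d)
    base = spillover_decision(cost, benefit, pair, ThresholdSpec(k_p=k_p))
    rescaled = spillover_decision(
        cost * scale, benefit, pair, ThresholdSpec(k_p=k_p * scale)
    )
    assert base.verdict is rescaled.verdict


@settings(max_examples=200, derandomize=True)
@given(benefit=positive, m_i=multiplier_vals, m_d=multiplier_vals)
def test_adjusted_icer_at_threshold_boundary_never_funds(benefit, m_i, m_d):
    """Costs chosen so the adjusted ICER equals k_p exactly must reject."""
    k_p = 1000.0
    cost = k_p * benefit * m_i / m_d  # adjusted ICER == k_p up to rounding
    d = spillover_decision(cost, benefit, MultiplierPair(m_i, m_d), ThresholdSpec(k_p=k_p))
    if d.adjusted_icer == k_p:  # exact tie after rounding error, if any
        assert d.verdict is Verdict.REJECT
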