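"""Markov engine: probability algebra, matrix structure, cohort propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnpcea.engine import (
    DEAD,
    annual_prob_to_monthly,
    apply_relative_risk,
    background_mortality,
    build_transition_matrix,
    combine_death,
    microsim_oracle,
    run_cohort,
)
from bnpcea.params import Arm, HealthState, default_bundle


class TestProbabilityAlgebra:
    @pytest.mark.parametrize(
        "annual, monthly",
        [(0.0, 0.0), (1.0, 1.0), (0.218, 1 - (1 - 0.218) ** (1 / 12))],
    )
    def test_annual_to_monthly(self, annual, monthly):
        assert annual_prob_to_monthly(annual) == pytest.approx(monthly, abs=1e-12)

    def test_annual_to_monthly_oldest_band_value(self):
        # constant-hazard conversion of the oldest-band mortality
        assert annual_prob_to_monthly(0.218) == pytest.approx(0.0202841, abs=1e-6)

    def test_annual_to_monthly_monotone_and_bounded(self):
        grid = np.linspace(0, 1, 101)
        vals = [annual_prob_to_monthly(p) for p in grid]
        assert all(0 <= v <= 1 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_annual_to_monthly_domain(self):
        with pytest.raises(ValueError):
            annual_prob_to_monthly(1.5)

    @pytest.mark.parametrize(
        "age, prob", [(47, 0.002), (85, 0.218), (64.99, 0.0095), (60, 0.0095)]
    )
    def test_background_mortality_bands(self, age, prob, bundle):
        assert background_mortality(age, bundle.mortality) == prob

    @pytest.mark.parametrize(
        "p, rr, p_death, expected",
        [(0.168, 1.0, 0.5, 0.168), (0.168, 0.81, 0.067, 0.13608), (0.9, 2.0, 0.3, 0.7)],
    )
    def test_apply_relative_risk(self, p, rr, p_death, expected):
        assert apply_relative_risk(p, rr, p_death) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "hf, bg, expected",
        [(0.0, 0.0, 0.0), (0.067, 0.0, 0.067),
         (0.067, 0.020284, 1 - (1 - 0.067) * (1 - 0.020284))],
    )
    def test_combine_death(self, hf, bg, expected):
        assert combine_death(hf, bg) == pytest.approx(expected, abs=1e-12)
        assert combine_death(bg, hf) == combine_death(hf, bg)  # symmetric

    def test_combined_death_at_least_each_cause(self):
        assert combine_death(0.067, 0.020284) == pytest.approx(0.085925, abs=1e-5)
        assert combine_death(0.3, 0.4) >= 0.4


class TestTransitionMatrix:
    @pytest.mark.parametrize("arm", [Arm.BNP, Arm.STANDARD])
    @pytest.mark.parametrize("age", [45, 60, 87])
    def test_structure(self, arm, age, bundle):
        mat = build_transition_matrix(arm, age, bundle)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)
        assert ((mat >= 0) & (mat <= 1)).all()
        np.testing.assert_array_equal(mat[DEAD], [0, 0, 0, 0, 1])
        # no downward transitions, no skipping states upward
        assert mat[2, 1] == mat[3, 2] == mat[3, 1] == 0
        assert mat[0, 2] == mat[0, 3] == mat[1, 3] == 0

    def test_standard_nrh_row_hand_arithmetic(self, bundle):
        """NRH row at the youngest band composes the three primitives."""
        mat = build_transition_matrix(Arm.STANDARD, 47, bundle)
        p_bg = annual_prob_to_monthly(0.002)
        p_death = combine_death(0.067, p_bg)
        assert mat[0, DEAD] == pytest.approx(p_death)
        assert mat[0, 1] == pytest.approx(0.168)
        assert mat[0, 0] == pytest.approx(1 - 0.168 - p_death)
        # spot values from evaluating the closed forms at high precision
        assert mat[0, DEAD] == pytest.approx(0.0671556, abs=1e-6)
        assert mat[0, 0] == pytest.approx(0.7648444, abs=1e-6)

    def test_rr_scales_hospitalization_only(self, bundle):
        bnp = build_transition_matrix(Arm.BNP, 60, bundle)
        std = build_transition_matrix(Arm.STANDARD, 60, bundle)
        for i in range(3):
            assert bnp[i, i + 1] == pytest.approx(0.81 * std[i, i + 1])
        np.testing.assert_allclose(bnp[:, DEAD], std[:, DEAD])

    def test_invalid_bundle_rejected(self, bundle):
        bundle.transitions.p_hosp_rh2 = 0.95
        with pytest.raises(ValueError, match="invalid bundle"):
            build_transition_matrix(Arm.BNP, 60, bundle)


def _deathless_bundle():
    b = default_bundle()
    t = b.transitions
    for f in ("p_death_nrh", "p_death_rh1", "p_death_rh2", "p_death_rh3"):
        setattr(t, f, 0.0)
    b.mortality.annual_probs = (0.0,) * 9
    return b


def _certain_death_bundle():
    b = default_bundle()
    t = b.transitions
    for f in ("p_hosp_nrh", "p_hosp_rh1", "p_hosp_rh2"):
        setattr(t, f, 0.0)
    for f in ("p_death_nrh", "p_death_rh1", "p_death_rh2", "p_death_rh3"):
        setattr(t, f, 1.0)
    return b


class TestCohortRun:
    def test_one_healthy_year_is_one_qaly(self):
        b = _deathless_bundle()
        b.utilities.values = {k: 1.0 for k in b.utilities.values}
        b.discount.rate_cost = b.discount.rate_effect = 0.0
        b.config.horizon_years = 1.0
        trace = run_cohort(Arm.STANDARD, b)
        assert trace.n_cycles == 12
        assert trace.totals().qaly == pytest.approx(1.0, abs=1e-12)

    def test_certain_death_single_cycle(self):
        b = _certain_death_bundle()
        trace = run_cohort(Arm.BNP, b)
        assert trace.n_cycles == 1
        assert trace.totals().qaly == pytest.approx(b.utilities.values["NRH"] / 12)
        assert trace.totals().cost == pytest.approx(b.costs.bnp["NRH"])

    def test_initial_distribution_and_conservation(self, bundle):
        trace = run_cohort(Arm.BNP, bundle)
        np.testing.assert_array_equal(trace.occupancy[0], [1, 0, 0, 0, 0])
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_death_absorbing_and_sums_monotone(self, bundle):
        trace = run_cohort(Arm.STANDARD, bundle)
        dead = trace.occupancy[:, DEAD]
        assert (np.diff(dead) >= -1e-15).all()
        assert (np.diff(np.cumsum(trace.cost_disc)) >= 0).all()
        assert (np.diff(np.cumsum(trace.qaly_disc)) >= 0).all()

    def test_discount_zero_equivalence(self, bundle):
        bundle.discount.rate_cost = bundle.discount.rate_effect = 0.0
        trace = run_cohort(Arm.BNP, bundle)
        np.testing.assert_array_equal(trace.cost, trace.cost_disc)
        np.testing.assert_array_equal(trace.qaly, trace.qaly_disc)

    def test_rr_neutrality_bit_identical_arms(self, bundle):
        bundle.effects.rr_hosp = 1.0
        bundle.costs.standard = dict(bundle.costs.bnp)
        a = run_cohort(Arm.BNP, bundle)
        b = run_cohort(Arm.STANDARD, bundle)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        np.testing.assert_array_equal(a.cost_disc, b.cost_disc)
        np.testing.assert_array_equal(a.qaly_disc, b.qaly_disc)

    def test_cost_monotone_in_state_cost(self, short_bundle):
        base = run_cohort(Arm.BNP, short_bundle).totals().cost
        short_bundle.costs.bnp["RH1"] += 100.0
        assert run_cohort(Arm.BNP, short_bundle).totals().cost >= base

    def test_qaly_decreases_with_rr(self, short_bundle):
        """Hospitalized states carry lower utility and higher mortality, so a
        larger hospitalization RR weakly lowers BNP-arm QALYs."""
        lo = run_cohort(Arm.BNP, short_bundle).totals().qaly
        short_bundle.effects.rr_hosp = 1.2
        assert run_cohort(Arm.BNP, short_bundle).totals().qaly <= lo

    def test_two_state_geometric_closed_form(self):
        """Reduced to NRH/DEAD with constant monthly death p and no
        discounting, life-years follow the truncated geometric series."""
        b = _deathless_bundle()
        p = 0.05
        b.transitions.p_death_nrh = p
        for f in ("p_hosp_nrh", "p_hosp_rh1", "p_hosp_rh2"):
            setattr(b.transitions, f, 0.0)
        b.discount.rate_cost = b.discount.rate_effect = 0.0
        b.utilities.values = {k: 1.0 for k in b.utilities.values}
        trace = run_cohort(Arm.STANDARD, b)
        n = trace.n_cycles
        expected = (1 - (1 - p) ** n) / p / 12
        assert trace.totals().qaly == pytest.approx(expected, abs=1e-9)
        assert trace.totals().life_years == pytest.approx(expected, abs=1e-9)

    def test_event_cost_semantics_cheaper_than_per_cycle(self, bundle):
        """Charging admissions once (NRH per cycle) accrues no more cost than
        charging every occupied cycle."""
        per_cycle = run_cohort(Arm.STANDARD, bundle).totals().cost
        bundle.config.cost_semantics = "event"
        assert run_cohort(Arm.STANDARD, bundle).totals().cost <= per_cycle

    def test_literal_stay_mode_runs_and_conserves(self, bundle):
        bundle.config.transition_label_mode = "literal-stay"
        trace = run_cohort(Arm.BNP, bundle)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)


@st.composite
def valid_bundles(draw):
    """Random feasible bundles: each row's hosp + HF-death stays below 1."""
    b = default_bundle()
    t = b.transitions
    for hosp_f, death_f in (
        ("p_hosp_nrh", "p_death_nrh"),
        ("p_hosp_rh1", "p_death_rh1"),
        ("p_hosp_rh2", "p_death_rh2"),
        (None, "p_death_rh3"),
    ):
        death = draw(st.floats(0.0, 0.6))
        setattr(t, death_f, death)
        if hosp_f:
            setattr(t, hosp_f, draw(st.floats(0.0, 1.0)) * (1.0 - death))
    b.effects.rr_hosp = draw(st.floats(0.1, 1.5))
    for state in b.utilities.values:
        b.utilities.values[state] = draw(st.floats(0.0, 1.0))
    b.config.horizon_years = 3.0
    return b


class TestRandomBundleProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(b=valid_bundles(), arm=st.sampled_from([Arm.BNP, Arm.STANDARD]))
    def test_conservation_and_absorption(self, b, arm):
        trace = run_cohort(arm, b)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert (np.diff(trace.occupancy[:, DEAD]) >= -1e-12).all()
        totals = trace.totals()
        assert totals.cost >= 0 and totals.qaly >= 0
        assert totals.qaly <= totals.life_years * max(b.utilities.values.values()) + 1e-12


class TestMicrosimOracle:
    def test_degenerate_chain_matches_cohort_exactly(self):
        b = _certain_death_bundle()
        ms = microsim_oracle(Arm.BNP, b, 50, seed=3)
        tr = run_cohort(Arm.BNP, b).totals()
        assert ms.cost == pytest.approx(tr.cost, abs=1e-12)
        assert ms.qaly == pytest.approx(tr.qaly, abs=1e-12)

    def test_seeded_reproducibility(self, short_bundle):
        a = microsim_oracle(Arm.STANDARD, short_bundle, 500, seed=11)
        b = microsim_oracle(Arm.STANDARD, short_bundle, 500, seed=11)
        assert (a.cost, a.qaly) == (b.cost, b.qaly)
        c = microsim_oracle(Arm.STANDARD, short_bundle, 500, seed=12)
        assert (a.cost, a.qaly) != (c.cost, c.qaly)

    @pytest.mark.parametrize("arm", [Arm.BNP, Arm.STANDARD])
    def test_cohort_totals_within_3se(self, arm, bundle):
        ms = microsim_oracle(arm, bundle, 20_000, seed=42)
        tr = run_cohort(arm, bundle).totals()
        assert abs(tr.cost - ms.cost) <= 3 * ms.cost_se
        assert abs(tr.qaly - ms.qaly) <= 3 * ms.qaly_se
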