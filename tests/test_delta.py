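"""The delta effect size: closed forms, limits, scheme reductions, count data."""

import numpy as np
import pytest

import yonezawa as yz
from yonezawa.kinetics import f_antiderivative, xi

from conftest import random_params


class TestDeltaFromCounts:
    @pytest.mark.parametrize(
        "n2, n12, expected",
        [((83, 200), (60, 200), 0.277), ((83, 200), (126, 200), -0.518)],
    )
    def test_published_count_pairs(self, n2, n12, expected):
        got = yz.delta_from_counts(*n2, *n12)
        assert round(got, 3) == expected

    def test_equal_frequencies_give_zero(self):
        assert yz.delta_from_counts(50, 100, 100, 200) == pytest.approx(0.0)

    def test_no_reference_events_is_undefined(self):
        with pytest.raises(ValueError):
            yz.delta_from_counts(0, 200, 10, 200)
        with pytest.raises(ValueError):
            yz.delta_from_counts(10, 0, 10, 200)


class TestDeltaMutations:
    def test_worked_example(self, abstract_params):
        res = yz.delta_mutations(abstract_params, 1.0, 5.0, 3.0)
        assert round(res.delta, 3) == 0.728
        assert res.yonezawa_effect
        assert res.scheme == "mutations"

    def test_no_priming_gives_zero(self, abstract_params):
        assert yz.delta_mutations(abstract_params, 0.0, 5.0, 3.0).delta == pytest.approx(0.0)

    def test_large_interval_asymptote(self, abstract_params):
        far = yz.delta_mutations(abstract_params, 1.0, 5.0, 1e4).delta
        dmin = yz.delta_min(abstract_params, 1.0, 5.0)
        assert far == pytest.approx(dmin, abs=1e-9)
        assert dmin == pytest.approx(-(1 / 5) * np.exp(-xi(abstract_params, 1.0)), rel=1e-12)
        assert dmin == pytest.approx(-0.02341, abs=5e-5)

    def test_zero_challenge_rejected(self, abstract_params):
        with pytest.raises(ValueError):
            yz.delta_mutations(abstract_params, 1.0, 0.0, 3.0)
        with pytest.raises(ValueError):
            yz.delta_min(abstract_params, 1.0, 0.0)

    def test_delta_min_bounds(self, rng):
        for _ in range(50):
            p = random_params(rng)
            d1, d2 = rng.uniform(0.01, 2), rng.uniform(2, 6)
            dmin = yz.delta_min(p, d1, d2)
            assert dmin < 0
            assert abs(dmin) < d1 / d2
            assert yz.delta_min(p, 0.0, d2) == 0.0


class TestDeltaLesions:
    def test_no_priming_gives_zero(self, abstract_params):
        assert yz.delta_lesions(abstract_params, 0.0, 5.0, 3.0, 10.0).delta == pytest.approx(0.0)

    def test_background_free_form_matches_zero_background(self, rng):
        for _ in range(100):
            p = random_params(rng)
            d1, d2 = rng.uniform(0.01, 1), rng.uniform(1, 5)
            dt = rng.uniform(0.5, 10)
            T = dt + rng.uniform(0.5, 10)
            mu = yz.LesionInductionParams(0.0, rng.uniform(0.1, 2))
            free = yz.delta_lesions(p, d1, d2, dt, T).delta
            with_mu = yz.delta_lesions(p, d1, d2, dt, T, mu=mu).delta
            assert with_mu == pytest.approx(free, rel=1e-12, abs=1e-12)

    def test_late_observation_converges_to_mutation_form(self, rng):
        for _ in range(100):
            p = random_params(rng)
            d1, d2 = rng.uniform(0.01, 1), rng.uniform(1, 5)
            dt = rng.uniform(0.5, 10)
            les = yz.delta_lesions(p, d1, d2, dt, 1e6).delta
            mut = yz.delta_mutations(p, d1, d2, dt).delta
            assert abs(les - mut) < 1e-6

    def test_ratio_and_expanded_forms_agree(self, rng):
        # the challenge-dose repair factors cancel between N_{1+2} and N_2
        for _ in range(50):
            p = random_params(rng)
            d1, d2 = rng.uniform(0.01, 1), rng.uniform(1, 5)
            dt = rng.uniform(0.5, 10)
            T = dt + rng.uniform(0.5, 10)
            mu = yz.LesionInductionParams(rng.uniform(0, 0.01), rng.uniform(0.1, 2))
            n12 = yz.lesions_remaining_two_dose(p, mu, d1, d2, dt, T)
            n2 = mu.mu1 * d2 * np.exp(yz.repair_integral(p, d2, 0.0, T - dt))
            ratio_form = 1 - n12 / n2
            expanded = yz.delta_lesions(p, d1, d2, dt, T, mu=mu).delta
            assert ratio_form == pytest.approx(expanded, abs=1e-12)

    def test_delta_bounded_above_by_one(self, rng):
        # delta = 1 only in the unreachable perfect-repair limit; strong
        # repair can round to exactly 1.0 in floating point
        for _ in range(200):
            p = random_params(rng)
            d1, d2 = rng.uniform(0, 2), rng.uniform(0.5, 6)
            dt = rng.uniform(0, 20)
            T = dt + rng.uniform(0.1, 30)
            assert yz.delta_lesions(p, d1, d2, dt, T).delta <= 1
            assert yz.delta_mutations(p, d1, d2, dt).delta <= 1

    def test_invalid_times_rejected(self, abstract_params):
        with pytest.raises(ValueError):
            yz.delta_lesions(abstract_params, 1.0, 5.0, 3.0, 3.0)
        with pytest.raises(ValueError):
            yz.delta_lesions(abstract_params, 1.0, 0.0, 3.0, 10.0)

    def test_high_challenge_warns(self):
        p = yz.AdaptiveResponseParams(22.9, 79.5, 0.0832)
        with pytest.warns(UserWarning, match="challenging dose"):
            yz.delta_lesions(p, 0.01, 1.5, 16.0, 22.0)


class TestIntervalThreshold:
    def test_boundary_interval_gives_zero_delta(self, abstract_params):
        th = yz.dt_threshold_ok(abstract_params, 1.0, 5.0, 3.0)
        assert th.satisfied and th.satisfiable
        at_boundary = yz.delta_mutations(abstract_params, 1.0, 5.0, th.boundary_dt).delta
        assert abs(at_boundary) < 1e-9

    def test_consistency_with_delta_sign(self, rng):
        for _ in range(100):
            p = random_params(rng)
            d1, d2 = rng.uniform(0.05, 1.5), rng.uniform(2, 6)
            dt = rng.uniform(0, 30)
            th = yz.dt_threshold_ok(p, d1, d2, dt)
            delta = yz.delta_mutations(p, d1, d2, dt).delta
            assert th.satisfied == (delta >= -1e-12)

    def test_finite_observation_variant(self, abstract_params):
        th = yz.dt_threshold_ok(abstract_params, 1.0, 5.0, 2.0, T=8.0)
        delta = yz.delta_lesions(abstract_params, 1.0, 5.0, 2.0, 8.0).delta
        assert th.satisfied == (delta >= 0)
        if th.boundary_dt is not None and th.boundary_dt < 8.0:
            at_b = yz.delta_lesions(abstract_params, 1.0, 5.0, th.boundary_dt, 8.0).delta
            assert abs(at_b) < 1e-9

    def test_large_interval_fails(self, abstract_params):
        assert not yz.dt_threshold_ok(abstract_params, 1.0, 5.0, 1e4).satisfied

    def test_unsatisfiable_condition_reported(self):
        # negligible repair and a priming dose larger than the challenge:
        # no interval can push delta back to zero
        weak = yz.AdaptiveResponseParams(1e-6, 1.0, 0.7)
        th = yz.dt_threshold_ok(weak, 6.0, 5.0, 1.0)
        assert not th.satisfiable
        assert not th.satisfied


class TestMultiPrimingSchemes:
    def test_two_priming_closed_form_oracle(self, abstract_params):
        # independent evaluation of the nested-survival closed form
        p = abstract_params
        d1 = d2 = 1.0
        d3, dt1, dt2 = 5.0, 3.0, 2.0
        expect = (
            1.0
            - np.exp(-f_antiderivative(p, d1, dt1 + dt2) - f_antiderivative(p, d2, dt2))
            - (d2 / d3) * np.exp(-f_antiderivative(p, d1, dt1) - xi(p, d2))
            - (d1 / d3) * np.exp(-xi(p, d1) - xi(p, d2))
        )
        got = yz.delta_two_priming(p, d1, d2, d3, dt1, dt2).delta
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(0.90738, abs=5e-5)

    def test_two_priming_reduces_without_second_dose(self, rng):
        for _ in range(50):
            p = random_params(rng)
            d1, d3 = rng.uniform(0.05, 1.5), rng.uniform(2, 6)
            dt1, dt2 = rng.uniform(0.1, 5, size=2)
            got = yz.delta_two_priming(p, d1, 0.0, d3, dt1, dt2).delta
            ref = yz.delta_mutations(p, d1, d3, dt1 + dt2).delta
            assert got == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_two_priming_all_zero_priming(self, abstract_params):
        assert yz.delta_two_priming(abstract_params, 0.0, 0.0, 5.0, 3.0, 2.0).delta == pytest.approx(0.0)

    def test_multi_priming_single_dose_identity(self, rng):
        for _ in range(100):
            p = random_params(rng)
            d, dstar = rng.uniform(0.05, 1.5), rng.uniform(2, 6)
            dt = rng.uniform(0.1, 8)
            got = yz.delta_multi_priming(p, d, dstar, dt, 1).delta
            ref = yz.delta_mutations(p, d, dstar, dt).delta
            assert got == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_multi_priming_double_dose_identity(self, rng):
        for _ in range(100):
            p = random_params(rng)
            d, dstar = rng.uniform(0.05, 1.5), rng.uniform(2, 6)
            dt = rng.uniform(0.1, 8)
            got = yz.delta_multi_priming(p, d, dstar, dt, 2).delta
            ref = yz.delta_two_priming(p, d, d, dstar, dt, dt).delta
            assert got == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_multi_priming_bounded_above(self, rng):
        for _ in range(20):
            p = random_params(rng)
            d, dstar = rng.uniform(0.05, 1.0), rng.uniform(2, 6)
            dt = rng.uniform(0.2, 5)
            for n in (1, 3, 10, 50):
                # heavy training can saturate to 1.0 in floating point
                assert yz.delta_multi_priming(p, d, dstar, dt, n).delta <= 1

    def test_training_protection_grows_with_dose_number(self, abstract_params):
        deltas = [
            yz.delta_multi_priming(abstract_params, 0.5, 5.0, 2.0, n).delta for n in (1, 2, 3, 4)
        ]
        assert np.all(np.diff(deltas) > 0)

    def test_zero_priming_doses_rejected(self, abstract_params):
        with pytest.raises(ValueError):
            yz.delta_multi_priming(abstract_params, 1.0, 5.0, 3.0, 0)


class TestPublishedTables:
    def test_all_printed_deltas_regenerate(self):
        for name, size in [("all_table2", 33), ("day_inversions", 8)]:
            bundle = yz.load_bundled(name)
            assert len(bundle) == size
            for r in bundle.records.itertuples():
                got = yz.delta_from_counts(r.n2_events, r.n2_denom, r.n12_events, r.n12_denom)
                assert round(got + 1e-12, 3) == pytest.approx(r.delta, abs=1e-9), r
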