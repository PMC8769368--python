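"""Energy, power, muscle power density scenarios and cost of transport."""

import numpy as np
import pytest

import larvajump as lj
from larvajump.datasets import (COHORT_BODY_MASS, COHORT_MUSCLE_FRACTION,
                                reference_cohort, reference_cohort_means)


class TestKineticEnergy:
    def test_reference_single_jump_row(self):
        # published row: m = 1.3 mg, v = 0.54 m/s -> 1.90e-7 J
        assert lj.kinetic_energy(1.3e-6, 0.54) == pytest.approx(1.90e-7, rel=0.01)

    def test_zero_velocity(self):
        assert lj.kinetic_energy(1.3e-6, 0.0) == 0.0

    def test_quadratic_in_velocity(self):
        assert lj.kinetic_energy(1e-6, 0.8) == pytest.approx(
            4 * lj.kinetic_energy(1e-6, 0.4))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            lj.kinetic_energy(-1e-6, 0.5)
        with pytest.raises(ValueError):
            lj.kinetic_energy(1e-6, -0.5)


class TestJumpPower:
    def test_reference_single_jump_row(self):
        # L = 1.4 mm over t = (8.8 + 0.63) ms at m = 1.3 mg
        P = lj.jump_power(1.3e-6, 1.4e-3, 9.43e-3)
        assert P == pytest.approx(3.0378e-6, rel=1e-3)

    def test_zero_displacement(self):
        assert lj.jump_power(1e-6, 0.0, 1e-3) == 0.0

    def test_inverse_cube_in_duration(self):
        assert lj.jump_power(1e-6, 1e-3, 5e-4) == pytest.approx(
            8 * lj.jump_power(1e-6, 1e-3, 1e-3))

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            lj.jump_power(1e-6, 1e-3, 0.0)


class TestPowerDensity:
    def test_reference_row_reproduces_printed_value(self):
        P = lj.jump_power(1.3e-6, 1.4e-3, 9.43e-3)
        O = lj.power_density(P, 1.3e-6, COHORT_MUSCLE_FRACTION)
        assert O == pytest.approx(24.0, rel=0.05)

    def test_inverse_in_fraction(self):
        assert lj.power_density(1e-6, 1e-6, 0.5) == pytest.approx(
            2 * lj.power_density(1e-6, 1e-6, 1.0))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            lj.power_density(1e-6, 1e-6, 0.0)
        with pytest.raises(ValueError):
            lj.power_density(1e-6, 1e-6, 1.5)


class TestMuscleFraction:
    def test_microct_estimate(self):
        # 0.12 mm^3 of muscle at 1060 kg/m^3 in a 1.3 mg larva -> 9.78%
        frac = lj.muscle_fraction(1.2e-10, 1060.0, 1.3e-6)
        assert round(frac, 4) == 0.0978

    def test_scales_with_volume(self):
        assert lj.muscle_fraction(2e-10, 1060.0, 1.3e-6) == pytest.approx(
            2 * lj.muscle_fraction(1e-10, 1060.0, 1.3e-6))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lj.muscle_fraction(1e-10, 0.0, 1.3e-6)
        with pytest.raises(ValueError, match="non-physical"):
            lj.muscle_fraction(1.2e-10, 1060.0, 1e-8)


@pytest.fixture(scope="module")
def table():
    return reference_cohort()


class TestScenarioSweep:
    def _powers_from_density(self, dens):
        return np.asarray(dens) * COHORT_MUSCLE_FRACTION * COHORT_BODY_MASS

    def test_larvae_with_a_jump_over_threshold(self, table):
        sweep = lj.scenario_sweep(
            self._powers_from_density(table["power_density_max"]),
            COHORT_BODY_MASS, larva_ids=table.index.to_numpy())
        assert sweep.n_larvae_any_exceeds(0.0978) == 5
        assert sweep.n_larvae_any_exceeds(0.0489) == 8

    def test_larvae_with_mean_over_threshold(self, table):
        sweep = lj.scenario_sweep(
            self._powers_from_density(table["power_density_mean"]),
            COHORT_BODY_MASS, larva_ids=table.index.to_numpy())
        assert sweep.n_larvae_mean_exceeds(0.0978) == 3

    def test_conservation_o_times_c_constant(self, table):
        sweep = lj.scenario_sweep(
            self._powers_from_density(table["power_density_max"]), COHORT_BODY_MASS)
        prod = sweep.power_density.mul(sweep.power_density.columns, axis=1)
        assert np.allclose(prod.to_numpy(), prod.iloc[:, [0]].to_numpy())

    def test_flag_monotone_in_fraction(self, table):
        sweep = lj.scenario_sweep(
            self._powers_from_density(table["power_density_max"]), COHORT_BODY_MASS)
        flags = sweep.exceeds[sorted(sweep.exceeds.columns)].to_numpy()
        # sorted ascending by fraction: once False, never True again
        assert np.all(flags[:, 1:] <= flags[:, :-1])

    def test_simple_algebraic_flag(self):
        sweep = lj.scenario_sweep([100e-6], 1e-6, fractions=(0.3, 0.249, 0.2))
        # O = 100 W/kg body => exceeds 400 W/kg muscle iff c < 0.25
        assert not bool(sweep.exceeds[0.3].iloc[0])
        assert bool(sweep.exceeds[0.249].iloc[0])

    def test_empty_jump_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lj.scenario_sweep([], 1e-6)


class TestCriticalFraction:
    def test_cohort_maximum_gives_printed_crossover(self):
        # cohort max 1319 W/kg muscle at c = 9.78% -> c* ~ 32.3%
        cstar = lj.critical_fraction(1319.0 * COHORT_MUSCLE_FRACTION)
        assert cstar == pytest.approx(0.3231, abs=0.002)

    def test_exact_boundary(self):
        p_spec = 1319.0 * COHORT_MUSCLE_FRACTION
        cstar = lj.critical_fraction(p_spec)
        eps = 1e-6
        above = lj.scenario_sweep([p_spec * COHORT_BODY_MASS], COHORT_BODY_MASS,
                                  fractions=(cstar * (1 + eps),))
        below = lj.scenario_sweep([p_spec * COHORT_BODY_MASS], COHORT_BODY_MASS,
                                  fractions=(cstar * (1 - eps),))
        assert not above.exceeds.to_numpy().any()
        assert below.exceeds.to_numpy().any()

    def test_limits(self):
        assert lj.critical_fraction(100.0, threshold=1e12) < 1e-9
        assert lj.critical_fraction(400.0) == pytest.approx(1.0)


class TestCostOfTransport:
    def test_jump_cot_at_cohort_means(self):
        means = reference_cohort_means()
        cot = lj.cot_jump(means["energy_e7_J"] * 1e-7, COHORT_BODY_MASS,
                          means["distance_mm"] * 1e-3)
        assert cot == pytest.approx(110.0, rel=0.02)

    def test_crawl_cot_at_cohort_mass(self):
        assert lj.cot_crawl(COHORT_BODY_MASS) == pytest.approx(825.0, rel=0.005)

    def test_crawl_cot_unit_mass(self):
        assert lj.cot_crawl(1.0) == pytest.approx(10.8)

    def test_crawl_cot_monotone_decreasing(self):
        assert lj.cot_crawl(1e-6) > lj.cot_crawl(1e-5)

    def test_jump_cot_scalings(self):
        base = lj.cot_jump(1e-7, 1.3e-6, 1e-2)
        assert lj.cot_jump(1e-7, 1.3e-6, 2e-2) == pytest.approx(base / 2)
        assert lj.cot_jump(1e-7, 1.3e-6, 1e-2, efficiency=1.0) == pytest.approx(base / 10)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            lj.cot_jump(1e-7, 1.3e-6, 0.0)


def test_mass_unit_heuristic_warns():
    with pytest.warns(UserWarning, match="check units"):
        lj.kinetic_energy(1.3, 0.5)  # grams passed where kg expected
    with pytest.warns(UserWarning, match="check units"):
        lj.cot_crawl(1e-10)


def test_morphometrics_defaults_consistent():
    m = lj.Morphometrics()
    assert m.muscle_fraction == pytest.approx(0.0978, abs=2e-4)
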