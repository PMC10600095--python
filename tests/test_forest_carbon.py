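"""Stand growth, regulated estates, avoided-harvest credit, afforestation."""

import numpy as np
import pandas as pd
import pytest

from circwood.forest_carbon import (
    DEFAULT_BIOMASS_C_PER_M3,
    AfforestationProgramme,
    EstateConfig,
    StandCohort,
    YieldCurve,
    afforestation_series,
    avoided_harvest_credit,
    estate_carbon_series,
    regulated_mean_stock,
    stand_trajectory,
    weighted_mean_yield_class,
)


def linear_curve(slope=2.0, max_age=120):
    ages = tuple(float(a) for a in range(max_age + 1))
    return YieldCurve("linear", 10.0, ages, tuple(slope * a for a in ages))


@pytest.fixture(scope="module")
def curve():
    return YieldCurve.from_chapman_richards("s", 16.0, 1100.0, 0.045, 2.8)


class TestYieldCurve:
    def test_volume_zero_at_age_zero(self):
        assert linear_curve().volume(0) == 0.0

    def test_flat_extrapolation_beyond_last_point(self):
        c = linear_curve(max_age=50)
        assert c.volume(80) == c.volume(50)

    def test_decreasing_volumes_rejected(self):
        with pytest.raises(ValueError):
            YieldCurve("bad", 10.0, (0.0, 1.0, 2.0), (0.0, 5.0, 4.0))

    def test_chapman_richards_monotone(self):
        c = YieldCurve.from_chapman_richards("s", 16.0, 1100.0, 0.045, 2.8)
        vols = np.asarray(c.volumes)
        assert vols[0] == 0.0
        assert (np.diff(vols) >= 0).all()


class TestStandTrajectory:
    def test_age_zero_has_zero_biomass(self):
        cohort = StandCohort(1.0, plant_year=2030, rotation=50, curve=linear_curve())
        traj = stand_trajectory(cohort, [2030])
        assert traj["biomass_c"].iloc[0] == 0.0

    def test_hand_arithmetic_linear_curve(self):
        # v(a) = 2a, carbon product 0.25 t C/m3, 1 ha, age 10 -> 5 t C
        cohort = StandCohort(1.0, plant_year=2020, rotation=50, curve=linear_curve())
        traj = stand_trajectory(cohort, range(2020, 2031), biomass_c_per_m3=0.25)
        assert traj.loc[2030, "biomass_c"] == pytest.approx(5.0)

    def test_sawtooth_resets_at_rotation_multiples(self):
        # brute-force year loop: zeros exactly at multiples of the rotation
        R = 7
        cohort = StandCohort(1.0, plant_year=0, rotation=R, curve=linear_curve())
        traj = stand_trajectory(cohort, range(0, 4 * R + 1))
        for age in range(0, 4 * R + 1):
            if age % R == 0:
                assert traj.loc[age, "biomass_c"] == 0.0
            else:
                assert traj.loc[age, "biomass_c"] > 0.0

    def test_harvest_transfers_residue_to_soil(self):
        R = 10
        cohort = StandCohort(1.0, plant_year=0, rotation=R, curve=linear_curve())
        traj = stand_trajectory(cohort, range(0, R + 1), soil_decay=0.0)
        assert traj.loc[R, "harvested_volume_m3"] > 0.0
        assert traj.loc[R, "soil_c"] > traj.loc[R - 1, "soil_c"]

    def test_invalid_area_rejected(self):
        with pytest.raises(ValueError):
            StandCohort(0.0, 2020, 50, linear_curve())


class TestRegulatedEstate:
    def test_closed_form_matches_cohort_simulation(self):
        # regulated-forest oracle: age-class closed form vs brute-force
        # cohort simulation, within 0.1%
        curve = YieldCurve.from_chapman_richards("s", 16.0, 1100.0, 0.045, 2.8)
        est = EstateConfig(area_ha=1000.0)
        sim = estate_carbon_series(curve, est, rotation=50, n_years=25)
        closed = 1000.0 * regulated_mean_stock(curve, 50) * DEFAULT_BIOMASS_C_PER_M3
        assert np.allclose(sim["biomass_c"], closed, rtol=1e-3)

    def test_extended_rotation_raises_standing_carbon(self):
        curve = YieldCurve.from_chapman_richards("s", 16.0, 1100.0, 0.045, 2.8)
        est = EstateConfig(area_ha=1000.0)
        base = estate_carbon_series(curve, est, rotation=50, n_years=28)
        ext = estate_carbon_series(curve, est, rotation=54, n_years=28)
        assert (ext["total_c"] >= base["total_c"] - 1e-9).all()
        assert ext["total_c"].iloc[-1] > base["total_c"].iloc[-1]


class TestAvoidedHarvestCredit:
    def test_zero_recycling_gives_zero_credit(self, curve):
        credit, reduction = avoided_harvest_credit(0.0, curve)
        assert credit == 0.0 and reduction == 0.0

    def test_credit_negative_and_reduction_positive(self, curve):
        credit, reduction = avoided_harvest_credit(5.7e5, curve)
        assert credit < 0.0
        assert reduction > 0.0

    def test_credit_magnitude_monotone_in_recycled_volume(self, curve):
        credits = [
            abs(avoided_harvest_credit(v, curve)[0])
            for v in (0.0, 1e5, 5e5, 1e6)
        ]
        assert credits == sorted(credits)

    def test_shorter_extension_rejected(self, curve):
        with pytest.raises(ValueError):
            EstateConfig(rotation_baseline=50, rotation_extended=48)


class TestWeightedMeanYieldClass:
    def test_identity(self):
        assert weighted_mean_yield_class([(1.0, 24.0)]) == 24.0

    def test_even_mixture(self):
        assert weighted_mean_yield_class([(0.5, 24.0), (0.5, 6.0)]) == 15.0

    @pytest.mark.parametrize("seed", range(3))
    def test_random_mixture_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        fracs = rng.dirichlet(np.ones(4))
        ycs = rng.uniform(4, 24, 4)
        got = weighted_mean_yield_class(list(zip(fracs, ycs)))
        assert got == pytest.approx(sum(f * y for f, y in zip(fracs, ycs)))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            weighted_mean_yield_class([(0.5, 10.0), (0.4, 20.0)])


class TestAfforestation:
    def test_zero_planting_rate_all_zero(self, curve):
        prog = AfforestationProgramme(0.0, 2023, 2050, ((1.0, "s", curve),))
        series = afforestation_series(prog, range(2022, 2051))
        assert (series == 0.0).all().all()

    def test_two_year_programme_is_superposition(self, curve):
        years = list(range(2022, 2051))
        two = AfforestationProgramme(1000.0, 2023, 2024, ((1.0, "s", curve),))
        one_a = AfforestationProgramme(1000.0, 2023, 2023, ((1.0, "s", curve),))
        one_b = AfforestationProgramme(1000.0, 2024, 2024, ((1.0, "s", curve),))
        combined = (
            afforestation_series(one_a, years)["annual_tco2e"]
            + afforestation_series(one_b, years)["annual_tco2e"]
        )
        assert np.allclose(
            afforestation_series(two, years)["annual_tco2e"], combined
        )

    def test_cumulative_magnitude_accelerates(self, curve):
        # the programme's cumulative sequestration builds gradually and
        # gains pace approaching the final year
        prog = AfforestationProgramme(20000.0, 2023, 2050, ((1.0, "s", curve),))
        series = afforestation_series(prog, range(2022, 2051))
        annual = -series["annual_tco2e"]
        assert (annual >= -1e-9).all()
        early = annual.loc[2025:2030].mean()
        late = annual.loc[2045:2050].mean()
        assert late > 2 * early

    def test_cumulative_monotone_in_planting_rate(self, curve):
        years = range(2022, 2051)
        small = afforestation_series(
            AfforestationProgramme(5000.0, 2023, 2050, ((1.0, "s", curve),)), years
        )
        large = afforestation_series(
            AfforestationProgramme(20000.0, 2023, 2050, ((1.0, "s", curve),)), years
        )
        assert (
            large["cumulative_tco2e"] <= small["cumulative_tco2e"] + 1e-9
        ).all()

    def test_empty_mix_rejected(self):
        with pytest.raises(ValueError):
            AfforestationProgramme(1000.0, 2023, 2050, ())

    def test_bad_fractions_rejected(self, curve):
        with pytest.raises(ValueError):
            AfforestationProgramme(
                1000.0, 2023, 2050, ((0.6, "s", curve), (0.6, "s", curve))
            )
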