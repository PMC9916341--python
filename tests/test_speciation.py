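"""Ionic strength, Davies activity model, and saturation indices."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from aquarisk.core import WaterSample
from aquarisk.speciation import (
    MINERALS,
    MineralPhase,
    SolutionState,
    SpeciationError,
    activity_coeff,
    classify_si,
    ionic_strength,
    saturation_index,
    saturation_table,
)


class TestIonicStrength:
    def test_1_1_salt_identity(self):
        assert ionic_strength({"Na+1": 0.01, "Cl-1": 0.01}) == pytest.approx(0.01)

    def test_2_1_salt(self):
        # 0.01 m CaCl2: 0.5*(0.01*4 + 0.02*1)
        assert ionic_strength({"Ca+2": 0.01, "Cl-1": 0.02}) == pytest.approx(0.03)

    def test_pure_water(self):
        assert ionic_strength({}) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ionic_strength({"Na+1": -0.1})


class TestDavies:
    def test_neutral_species(self):
        assert activity_coeff(0, 0.5) == 1.0

    def test_infinite_dilution(self):
        assert activity_coeff(1, 0.0) == 1.0

    def test_monovalent_at_tenth_molal(self):
        # 10**(-0.5092*(sqrt(.1)/(1+sqrt(.1)) - 0.03)) evaluated by hand
        assert activity_coeff(1, 0.1) == pytest.approx(0.7815, abs=1e-4)

    def test_charge_square_scaling(self):
        g1, g2 = activity_coeff(1, 0.1), activity_coeff(2, 0.1)
        assert math.log10(g2) == pytest.approx(4 * math.log10(g1), rel=1e-9)

    @given(I=st.floats(0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_bounded_below_one(self, I):
        assert 0.0 < activity_coeff(2, I) <= 1.0


class TestSaturationIndex:
    def test_equilibrium_is_zero(self):
        # halite activities tuned so IAP = K = 10**1.570
        a = 10 ** (1.570 / 2)
        assert saturation_index({"Na+1": a, "Cl-1": a}, "halite") == pytest.approx(0.0)

    def test_doubling_two_species_adds_2log2(self):
        base = {"Ca+2": 1e-3, "SO4-2": 1e-3}
        doubled = {k: 2 * v for k, v in base.items()}
        d = saturation_index(doubled, "gypsum") - saturation_index(base, "gypsum")
        assert d == pytest.approx(2 * math.log10(2), abs=1e-12)

    def test_calcite_hand_value(self):
        si = saturation_index({"Ca+2": 1e-3, "CO3-2": 1e-5}, "calcite")
        assert si == pytest.approx(0.48, abs=1e-9)

    def test_missing_species_raises(self):
        with pytest.raises(SpeciationError):
            saturation_index({"Ca+2": 1e-3}, "calcite")

    def test_unknown_mineral(self):
        with pytest.raises(SpeciationError):
            saturation_index({}, "kryptonite")

    def test_classification_thresholds(self):
        assert classify_si(0.5) == "supersaturated"
        assert classify_si(-0.5) == "undersaturated"
        assert classify_si(0.0) == "equilibrium"
        # literal threshold-1 variant
        assert classify_si(0.5, threshold=1.0) == "undersaturated"

    def test_inert_ions_only_act_through_ionic_strength(self):
        low = SolutionState({"Ca+2": 1e-3, "HCO3-1": 2e-3}, ph=7.5)
        high = SolutionState({"Ca+2": 1e-3, "HCO3-1": 2e-3, "Na+1": 0.05,
                              "Cl-1": 0.05}, ph=7.5)
        si_low = saturation_index(low, "calcite")
        si_high = saturation_index(high, "calcite")
        assert si_low != si_high  # gamma shifts
        assert abs(si_low - si_high) < 0.6  # but only via activity coefficients


class TestSolutionState:
    def test_from_sample_and_table(self, survey):
        df, _ = survey
        from aquarisk.core import frame_to_samples

        samples = frame_to_samples(df.head(5))
        table = saturation_table(samples, minerals=["calcite", "gypsum", "halite"])
        assert len(table) == 5
        assert table["ionic_strength"].between(0.0, 0.7).all()
        # groundwater here is hard and bicarbonate-rich: calcite above halite
        assert (table["calcite"] > table["halite"]).all()

    def test_brucite_uses_proton_convention(self):
        state = SolutionState({"Mg+2": 1e-3}, ph=8.0)
        si = saturation_index(state, "brucite")
        expected = (
            math.log10(state.activities["Mg+2"]) + 2 * 8.0 - MINERALS["brucite"].logk
        )
        assert si == pytest.approx(expected, abs=1e-12)

    def test_ph_required(self):
        s = WaterSample("x", "mining", conc={"Ca": 40.0})
        with pytest.raises(SpeciationError):
            SolutionState.from_sample(s)

    def test_custom_phase(self):
        phase = MineralPhase("fake", {"Ca+2": 1}, logk=-3.0)
        assert saturation_index({"Ca+2": 1e-3}, phase) == pytest.approx(0.0)
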