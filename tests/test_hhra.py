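"""Deterministic health-risk chain: intake, hazard quotients, cancer risk."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquarisk import datatables as dt
from aquarisk.hhra import (
    ExposureProfile,
    ProfileError,
    ToxicityError,
    cancer_risk,
    cdi,
    default_profiles,
    hi,
    hq,
    metal_chain,
    risk_table,
    thi,
)

PROFILES = default_profiles()


class TestCdi:
    @pytest.mark.parametrize(
        "conc, cohort, expected",
        [
            (4.5, "child", 0.500),  # Cr ceiling, 2 L/day over 18 kg
            (4.5, "male", 0.173),
            (4.5, "female", 0.218),
            (0.0, "child", 0.0),
        ],
    )
    def test_printed_intakes(self, conc, cohort, expected):
        assert cdi(conc, PROFILES[cohort]) == pytest.approx(expected, abs=5e-4)

    def test_lifetime_bracket_is_unity(self):
        assert PROFILES["child"].exposure_factor == pytest.approx(1.0)

    def test_printed_convention_scales_down(self):
        # ED = 350 days over a 70-year averaging time scales every intake
        printed = default_profiles("printed_2023")
        ratio = cdi(1.0, printed["child"]) / cdi(1.0, PROFILES["child"])
        assert ratio == pytest.approx(350.0 / (70 * 365), rel=1e-9)

    def test_bad_profile(self):
        with pytest.raises(ProfileError):
            ExposureProfile("child", ir_L_day=2.0, bw_kg=0.0)


class TestHazard:
    def test_hq_values(self):
        assert hq(0.500, 1.5) == pytest.approx(0.333, abs=5e-4)
        assert hq(0.250, 0.02) == pytest.approx(12.5)
        assert hq(0.0, 1.5) == 0.0

    def test_hq_flags_missing_rfd(self):
        with pytest.raises(ToxicityError):
            hq(1.0, 0.0)

    def test_hi_sum(self):
        assert hi({"Cr": 0.333, "Ni": 12.5, "Mn": 0.8}) == pytest.approx(13.633)
        assert hi({}) == 0.0
        assert hi({"Cr": 0.4}) == pytest.approx(0.4)

    def test_cancer_risk_values(self):
        assert cancer_risk(0.500, dt.CSF["Cr"]) == pytest.approx(0.250)
        assert cancer_risk(0.244, dt.CSF["Ni"]) == pytest.approx(0.222, abs=5e-4)

    def test_mn_is_not_carcinogenic(self):
        chain = metal_chain(1.0, "Mn", PROFILES["child"])
        assert "cr" not in chain

    def test_thi_mine_water_child_endpoints(self):
        # group-level carcinogenic totals from the printed per-metal intakes
        maxima = {"Cr": cancer_risk(0.667, 0.5), "Ni": cancer_risk(0.250, 0.91)}
        minima = {"Cr": cancer_risk(0.639, 0.5), "Ni": cancer_risk(0.246, 0.91)}
        assert thi(maxima) == pytest.approx(0.561, abs=1e-3)
        assert thi(minima) == pytest.approx(0.542, abs=1.5e-3)

    def test_thi_empty(self):
        with pytest.raises(ValueError):
            thi({})


class TestOrderings:
    def test_cohort_order_at_fixed_concentration(self):
        # IR/BW: child 0.111 > female 0.0484 > male 0.0385
        intakes = {c: cdi(1.0, p) for c, p in PROFILES.items()}
        assert intakes["child"] > intakes["female"] > intakes["male"]

    def test_nickel_dominates_hazard_everywhere(self):
        # with the bundled RfDs and the group-mean concentrations, Ni is the
        # dominant noncarcinogenic hazard, and the carcinogenic risk ranks
        # Ni > Cr (Mn carries no slope factor, so its cancer risk is nil)
        for group, stats in dt.GROUP_STATS.items():
            for cohort, prof in PROFILES.items():
                hqs = {
                    m: hq(cdi(stats[m][2], prof), dt.RFD[m]) for m in dt.METALS
                }
                assert hqs["Ni"] > max(hqs["Cr"], hqs["Mn"]), (group, cohort)
                crs = {
                    m: cancer_risk(cdi(stats[m][2], prof), dt.CSF[m])
                    for m in dt.CSF
                }
                assert crs["Ni"] > crs["Cr"] > 0.0, (group, cohort)

    @given(c=st.floats(0, 10), k=st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_degree_one(self, c, k):
        chain = metal_chain(c, "Cr", PROFILES["child"])
        scaled = metal_chain(k * c, "Cr", PROFILES["child"])
        for key in chain:
            assert scaled[key] == pytest.approx(k * chain[key], rel=1e-9, abs=1e-12)


class TestRiskTable:
    def test_long_table_shapes_and_hi(self, survey):
        df, _ = survey
        risk = risk_table(df)
        assert set(risk.cohort) == {"child", "male", "female"}
        # HI >= every component HQ
        grp = risk.groupby(["sample_id", "cohort"])
        assert (grp.apply(lambda g: (g.hi >= g.hq - 1e-12).all(), include_groups=False)).all()
        # CR defined only for Cr and Ni
        assert risk.loc[risk.metal == "Mn", "cr"].isna().all()
        assert (risk[risk.metal != "Mn"]["cr"] >= 0).all()
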