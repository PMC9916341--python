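"""Versioned reference tables used across the package.

Everything here is plain data: guideline limits, ion properties, toxicity
constants, mineral solubility products, and the per-group summary statistics
of the study cohort that the synthetic generator reproduces.  All tables are
ordinary dicts so callers can copy and override them; the library never
mutates them.
"""

from __future__ import annotations

TABLES_VERSION = "2024.1"

#: Metals measured in the survey; the only parameters in the risk chain.
METALS = ("Cr", "Ni", "Mn")

#: Major-ion vocabulary used for charge balance and facies work.
CATIONS = ("Na", "K", "Ca", "Mg")
ANIONS = ("HCO3", "Cl", "SO4", "NO3", "PO4")

#: All concentration parameters carried on a water sample (mg/L).
CONC_PARAMS = CATIONS + ANIONS + METALS

#: Bulk physicochemical parameters (name -> unit), stored outside ``conc``.
PHYSICO_PARAMS = {
    "ph": "unitless",
    "ec_uScm": "uS/cm",
    "tds_mgL": "mg/L",
    "turbidity_NTU": "NTU",
    "orp_mV": "mV",
    "temp_C": "degC",
}

#: Ion properties: molar mass (g/mol) and signed charge.
ION_SPECS: dict[str, tuple[float, int]] = {
    "Na": (22.990, +1),
    "K": (39.098, +1),
    "Ca": (40.078, +2),
    "Mg": (24.305, +2),
    "HCO3": (61.016, -1),
    "Cl": (35.453, -1),
    "SO4": (96.060, -2),
    "NO3": (62.004, -1),
    "PO4": (94.971, -3),
    "Cr": (51.996, +3),
    "Ni": (58.693, +2),
    "Mn": (54.938, +2),
}

#: WHO drinking-water guideline limits, same units as the measurements.
#: Keys match sample parameter names; bulk parameters use their column names.
WHO_LIMITS: dict[str, float] = {
    "ec_uScm": 400.0,
    "turbidity_NTU": 5.0,
    "tds_mgL": 1000.0,
    "Na": 200.0,
    "K": 12.0,
    "Mg": 50.0,
    "Ca": 100.0,
    "PO4": 0.1,
    "NO3": 50.0,
    "HCO3": 500.0,
    "Cl": 250.0,
    "SO4": 500.0,
    "Cr": 0.05,
    "Ni": 3.0,
    "Mn": 0.5,
}

#: Optional two-sided pH guideline; midpoint of the 6.5-9.2 band is not used.
#: When a pH ratio is requested explicitly, it is computed against this value.
PH_REFERENCE = 7.8

# ---------------------------------------------------------------------------
# Exposure / toxicity constants for the deterministic risk chain.
# ---------------------------------------------------------------------------

#: Ingestion rate (L/day) and body weight (kg) per cohort.
COHORTS: dict[str, dict[str, float]] = {
    "child": {"ir_L_day": 2.0, "bw_kg": 18.0},
    "male": {"ir_L_day": 2.5, "bw_kg": 65.0},
    "female": {"ir_L_day": 3.0, "bw_kg": 62.0},
}

#: Oral reference doses (mg/kg/day). Derived by inverting printed CDI/HQ
#: pairs of the study's risk table; see docs/methods.md.
RFD: dict[str, float] = {"Cr": 1.5, "Ni": 0.02, "Mn": 0.14}

#: Cancer slope factors ((mg/kg/day)^-1); only Cr and Ni are carcinogens here.
CSF: dict[str, float] = {"Cr": 0.5, "Ni": 0.91}

#: Acceptable incremental lifetime cancer risk band.
CR_ACCEPTABLE = (1.0e-6, 1.0e-4)

# ---------------------------------------------------------------------------
# Receptor-model uncertainty defaults.
# ---------------------------------------------------------------------------

#: Method detection limits (mg/L) for the metals; analytical error fraction.
MDL: dict[str, float] = {"Cr": 0.1, "Ni": 0.5, "Mn": 0.05}
ERROR_FRACTION = 0.035

# ---------------------------------------------------------------------------
# Mineral solubility products at 25 degC (log10 K, dissolution convention).
# Stoichiometry maps species -> signed coefficient on the product side, so
# SI = sum(nu * log10 a) - log10 K.  Brucite is written against H+ (its K
# here is for Mg(OH)2 + 2H+ = Mg+2 + 2H2O).
# ---------------------------------------------------------------------------

MINERALS: dict[str, dict] = {
    "calcite": {"stoich": {"Ca+2": 1, "CO3-2": 1}, "logk": -8.48},
    "aragonite": {"stoich": {"Ca+2": 1, "CO3-2": 1}, "logk": -8.34},
    "dolomite": {"stoich": {"Ca+2": 1, "Mg+2": 1, "CO3-2": 2}, "logk": -17.09},
    "gypsum": {"stoich": {"Ca+2": 1, "SO4-2": 1}, "logk": -4.58},
    "anhydrite": {"stoich": {"Ca+2": 1, "SO4-2": 1}, "logk": -4.36},
    "halite": {"stoich": {"Na+1": 1, "Cl-1": 1}, "logk": 1.570},
    "rhodochrosite": {"stoich": {"Mn+2": 1, "CO3-2": 1}, "logk": -11.13},
    "brucite": {"stoich": {"Mg+2": 1, "H+1": -2}, "logk": 16.84},
}

#: Second dissociation constant of carbonic acid (HCO3- = H+ + CO3-2).
LOG_K2_CARBONATE = -10.33
#: Water ion product at 25 degC.
LOG_KW = -14.0
#: Debye-Huckel A parameter at 25 degC (Davies equation).
DAVIES_A = 0.5092

# ---------------------------------------------------------------------------
# Study-cohort summary statistics: per group, per parameter,
# (min, max, mean, sd).  These are the conditions the synthetic generator
# reproduces; groups are mining (n=35), non_mining (n=20), mine_water (n=5).
# ---------------------------------------------------------------------------

GROUP_SIZES = {"mining": 35, "non_mining": 20, "mine_water": 5}

GROUP_STATS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "mining": {
        "ph": (7.2, 8.0, 7.4, 0.2),
        "depth_m": (30.0, 135.0, 74.0, 25.5),
        "elevation_m": (290.0, 495.0, 376.0, 57.8),
        "ec_uScm": (480.0, 1500.0, 782.0, 249.1),
        "temp_C": (27.5, 31.2, 30.0, 1.0),
        "turbidity_NTU": (2.4, 14.0, 6.0, 2.7),
        "orp_mV": (140.0, 280.0, 196.0, 36.5),
        "tds_mgL": (310.0, 980.0, 503.0, 164.3),
        "Na": (25.0, 210.0, 86.0, 53.1),
        "K": (6.0, 12.0, 10.0, 1.8),
        "Mg": (25.0, 60.0, 40.0, 8.5),
        "Ca": (25.0, 125.0, 66.0, 25.5),
        "PO4": (1.33, 8.5, 3.0, 1.9),
        "NO3": (10.0, 28.0, 18.0, 4.7),
        "HCO3": (200.0, 650.0, 293.0, 70.1),
        "Cl": (75.0, 145.0, 110.0, 14.1),
        "SO4": (100.0, 210.0, 153.0, 27.2),
        "Cr": (0.02, 4.5, 1.3, 1.2),
        "Ni": (0.4, 3.8, 1.4, 0.28),
        "Mn": (0.05, 0.8, 0.4, 0.12),
    },
    "non_mining": {
        "ph": (7.3, 8.2, 7.71, 0.26),
        "depth_m": (27.0, 95.0, 64.6, 18.84),
        "elevation_m": (310.0, 500.0, 347.0, 23.92),
        "ec_uScm": (480.0, 1400.0, 760.0, 233.31),
        "temp_C": (27.4, 30.2, 28.6, 0.76),
        "turbidity_NTU": (3.2, 12.0, 6.7, 2.83),
        "orp_mV": (160.0, 225.0, 191.0, 19.0),
        "tds_mgL": (310.0, 1000.0, 512.5, 174.8),
        "Na": (30.0, 245.0, 152.3, 71.05),
        "K": (6.0, 12.0, 9.6, 2.01),
        "Mg": (12.0, 45.0, 27.7, 9.90),
        "Ca": (15.0, 110.0, 49.8, 27.65),
        "PO4": (1.5, 10.0, 3.5, 1.93),
        "NO3": (10.0, 27.0, 17.0, 4.0),
        "HCO3": (215.0, 580.0, 350.0, 74.0),
        "Cl": (95.0, 145.0, 115.0, 13.0),
        "SO4": (140.0, 190.0, 161.0, 15.0),
        "Cr": (0.02, 2.3, 0.7, 0.81),
        "Ni": (0.05, 3.6, 1.2, 0.23),
        "Mn": (0.04, 0.6, 0.3, 0.10),
    },
    "mine_water": {
        "ph": (6.5, 7.2, 6.8, 0.25),
        "depth_m": (15.0, 25.0, 20.0, 3.81),
        "elevation_m": (430.0, 470.0, 452.0, 16.43),
        "ec_uScm": (1200.0, 1500.0, 1370.0, 139.6),
        "temp_C": (27.5, 31.2, 29.2, 1.50),
        "turbidity_NTU": (33.0, 70.0, 47.6, 16.47),
        "orp_mV": (170.0, 260.0, 212.0, 38.34),
        "tds_mgL": (750.0, 980.0, 848.0, 84.38),
        "Na": (180.0, 255.0, 213.0, 27.75),
        "K": (8.0, 12.0, 10.6, 1.95),
        "Mg": (21.0, 30.0, 25.2, 3.19),
        "Ca": (25.0, 50.0, 39.0, 9.62),
        "PO4": (1.5, 6.5, 3.7, 1.92),
        "NO3": (10.0, 15.0, 12.8, 2.17),
        "HCO3": (400.0, 630.0, 451.0, 30.90),
        "Cl": (100.0, 125.0, 115.0, 9.35),
        "SO4": (140.0, 180.0, 159.0, 14.75),
        "Cr": (5.8, 6.0, 5.9, 0.11),
        "Ni": (3.2, 5.8, 4.2, 0.52),
        "Mn": (0.6, 1.2, 0.8, 0.21),
    },
}

#: Water-type frequencies of the surveyed cohort (Chadha quadrants):
#: Ca-HCO3, Na-HCO3, Na-Cl, Ca-Mg-Cl.
FACIES_WEIGHTS = {
    "Ca-HCO3": 0.466,
    "Na-HCO3": 0.266,
    "Na-Cl": 0.233,
    "Ca-Mg-Cl": 0.035,
}
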