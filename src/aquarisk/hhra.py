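"""Deterministic drinking-water health-risk chain.

For each metal, cohort, and sample:

    CDI = C * IR * (EF * ED / AT) / BW      chronic daily intake, mg/kg/day
    HQ  = CDI / RfD                         hazard quotient (noncarcinogenic)
    HI  = sum_metals HQ                     hazard index per sample
    CR  = CDI * CSF                         incremental lifetime cancer risk
    THI = sum_metals (HQ or CR)             total hazard index at group level

The default exposure convention is lifetime exposure: EF = 365 d/y,
ED = 70 y, AT = 70*365 d, so EF*ED/AT = 1 and CDI = C*IR/BW.  A
``printed_2023`` profile with ED = 350 days is provided for comparison with
risk tables that state that constant; it scales every quantity by the same
factor (the chain is homogeneous of degree 1 in the exposure bracket).
HQ > 1 flags noncarcinogenic concern; CR above 1e-4 is conventionally
intolerable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datatables as dt
from .core import CONC_COLUMNS


class ProfileError(ValueError):
    """Invalid exposure profile parameter."""


class ToxicityError(KeyError):
    """Missing RfD, or CSF requested for a non-carcinogen."""


@dataclass(frozen=True)
class ExposureProfile:
    """Cohort exposure parameters plus toxicity constants."""

    cohort: str
    ir_L_day: float
    bw_kg: float
    ef_days_yr: float = 365.0
    ed_years: float = 70.0
    at_days: float = 70.0 * 365.0
    rfd: Mapping[str, float] = field(default_factory=lambda: dict(dt.RFD))
    csf: Mapping[str, float] = field(default_factory=lambda: dict(dt.CSF))

    def __post_init__(self) -> None:
        if self.ir_L_day <= 0 or self.bw_kg <= 0 or self.at_days <= 0:
            raise ProfileError("IR, BW and AT must be positive")

    @property
    def exposure_factor(self) -> float:
        """EF * ED / AT; equals 1 under the lifetime convention."""
        return self.ef_days_yr * self.ed_years / self.at_days


def default_profiles(convention: str = "lifetime") -> dict[str, ExposureProfile]:
    """Bundled cohort profiles: child / male / female.

    ``convention='lifetime'`` gives EF*ED/AT = 1; ``'printed_2023'`` uses
    ED = 350 days with EF = 365 d/y and AT = 70*365 d.
    """
    profiles = {
        name: ExposureProfile(cohort=name, ir_L_day=p["ir_L_day"], bw_kg=p["bw_kg"])
        for name, p in dt.COHORTS.items()
    }
    if convention == "lifetime":
        return profiles
    if convention == "printed_2023":
        return {
            name: replace(prof, ef_days_yr=365.0, ed_years=350.0 / 365.0,
                          at_days=70.0 * 365.0)
            for name, prof in profiles.items()
        }
    raise ProfileError(f"unknown exposure convention {convention!r}")


def cdi(conc_mgL: float, profile: ExposureProfile) -> float:
    """Chronic daily intake (mg/kg/day) via drinking-water ingestion."""
    if conc_mgL < 0:
        raise ValueError(f"negative concentration: {conc_mgL}")
    return conc_mgL * profile.ir_L_day * profile.exposure_factor / profile.bw_kg


def hq(cdi_value: float, rfd: float) -> float:
    """Hazard quotient CDI/RfD; > 1 flags noncarcinogenic concern."""
    if rfd <= 0:
        raise ToxicityError(f"nonpositive RfD: {rfd}")
    return cdi_value / rfd


def hi(hq_values: Mapping[str, float] | Sequence[float]) -> float:
    """Hazard index: sum of hazard quotients over metals for one sample."""
    vals = list(hq_values.values()) if isinstance(hq_values, Mapping) else list(hq_values)
    return float(np.sum(vals)) if vals else 0.0


def cancer_risk(cdi_value: float, csf: float) -> float:
    """Incremental lifetime cancer risk CDI * CSF."""
    return cdi_value * csf


def thi(values: Mapping[str, float] | Sequence[float]) -> float:
    """Total hazard index: sum of HQs (or CRs) across metals."""
    vals = list(values.values()) if isinstance(values, Mapping) else list(values)
    if not vals:
        raise ValueError("empty input")
    return float(np.sum(vals))


def metal_chain(
    conc_mgL: float, metal: str, profile: ExposureProfile
) -> dict[str, float]:
    """CDI, HQ and (for carcinogens) CR of one metal concentration."""
    c = cdi(conc_mgL, profile)
    if metal not in profile.rfd:
        raise ToxicityError(f"no RfD for {metal!r}")
    out = {"cdi": c, "hq": hq(c, profile.rfd[metal])}
    if metal in profile.csf:
        out["cr"] = cancer_risk(c, profile.csf[metal])
    return out


def risk_table(
    df: pd.DataFrame,
    profiles: Mapping[str, ExposureProfile] | None = None,
    metals: Sequence[str] = dt.METALS,
) -> pd.DataFrame:
    """Per-sample, per-metal, per-cohort CDI/HQ/CR plus per-sample HI.

    Returns a long table with one row per (sample, cohort, metal) and the
    sample-level hazard index repeated on each row of its (sample, cohort).
    """
    profiles = profiles if profiles is not None else default_profiles()
    records = []
    for _, row in df.iterrows():
        for cohort, prof in profiles.items():
            hqs = {}
            rows_here = []
            for metal in metals:
                col = CONC_COLUMNS[metal]
                if col not in row or pd.isna(row[col]):
                    continue
                chain = metal_chain(float(row[col]), metal, prof)
                hqs[metal] = chain["hq"]
                rows_here.append(
                    {
                        "sample_id": row["sample_id"],
                        "group": row["group"],
                        "cohort": cohort,
                        "metal": metal,
                        "cdi": chain["cdi"],
                        "hq": chain["hq"],
                        "cr": chain.get("cr", np.nan),
                    }
                )
            sample_hi = hi(hqs)
            for r in rows_here:
                r["hi"] = sample_hi
            records.extend(rows_here)
    return pd.DataFrame.from_records(records)


def group_risk_summary(risk: pd.DataFrame) -> pd.DataFrame:
    """Group-level range/mean/sd of CDI, HQ, CR per metal and cohort, plus THI.

    THI rows sum the carcinogenic risks across metals at the group range
    endpoints (min and max), mirroring how study-style risk tables report a
    group-level total.
    """
    records = []
    for (group, cohort), sub in risk.groupby(["group", "cohort"], sort=False):
        for metal, msub in sub.groupby("metal", sort=False):
            for qty in ("cdi", "hq", "cr"):
                vals = msub[qty].dropna()
                if vals.empty:
                    continue
                records.append(
                    {
                        "group": group,
                        "cohort": cohort,
                        "metal": metal,
                        "quantity": qty,
                        "min": float(vals.min()),
                        "max": float(vals.max()),
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
        cr_by_metal = sub.dropna(subset=["cr"]).groupby("metal")["cr"]
        if len(cr_by_metal) > 0:
            records.append(
                {
                    "group": group,
                    "cohort": cohort,
                    "metal": "all",
                    "quantity": "thi_carcinogenic",
                    "min": float(cr_by_metal.min().sum()),
                    "max": float(cr_by_metal.max().sum()),
                    "mean": float(cr_by_metal.mean().sum()),
                    "sd": np.nan,
                }
            )
    return pd.DataFrame.from_records(records)
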