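"""Hydrochemical facies: Gibbs mechanism coordinates and Chadha water types.

Gibbs coordinates place a sample on the rock-weathering / evaporation /
precipitation continuum by plotting log10 TDS against the cation ratio
Na/(Na+Ca) and the anion ratio Cl/(Cl+HCO3) (mass concentrations by
default).  The Chadha diagram classifies a sample into one of four water
types from the signs of two milliequivalent-percent coordinates:

    x = ((Ca+Mg) - (Na+K))   as % of total cation meq
    y = (HCO3 - (Cl+SO4))    as % of total anion meq of the panel

Quadrants: (+,+) Ca-HCO3, (-,+) Na-HCO3, (-,-) Na-Cl, (+,-) Ca-Mg-Cl.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CONC_COLUMNS, IONS, WaterSample, to_meq

log = logging.getLogger("aquarisk")

WATER_TYPES = ("Ca-HCO3", "Na-HCO3", "Na-Cl", "Ca-Mg-Cl")


class CoordinateError(ValueError):
    """A facies coordinate is undefined (zero denominator)."""


@dataclass(frozen=True)
class FaciesResult:
    gibbs_x1: float  # Na/(Na+Ca)
    gibbs_x2: float  # Cl/(Cl+HCO3)
    gibbs_y: float  # log10 TDS
    chadha_x: float  # meq%
    chadha_y: float  # meq%
    water_type: str
    boundary: bool  # a Chadha coordinate was exactly 0


def gibbs_coords(
    sample: WaterSample | Mapping[str, float],
    tds: float | None = None,
    use_meq: bool = False,
) -> tuple[float, float, float]:
    """(Na/(Na+Ca), Cl/(Cl+HCO3), log10 TDS) for one sample."""
    conc = sample.conc if isinstance(sample, WaterSample) else sample
    if tds is None:
        if not isinstance(sample, WaterSample) or np.isnan(sample.tds_mgL):
            raise CoordinateError("TDS not available")
        tds = sample.tds_mgL
    vals = dict(conc)
    if use_meq:
        vals = {k: to_meq(v, IONS[k]) for k, v in vals.items() if k in IONS}
    na, ca = vals["Na"], vals["Ca"]
    cl, hco3 = vals["Cl"], vals["HCO3"]
    if na + ca <= 0 or cl + hco3 <= 0 or tds <= 0:
        raise CoordinateError("zero denominator in Gibbs coordinates")
    return na / (na + ca), cl / (cl + hco3), float(np.log10(tds))


def chadha_coords(sample: WaterSample | Mapping[str, float]) -> tuple[float, float]:
    """Chadha diagram coordinates in milliequivalent percent."""
    conc = sample.conc if isinstance(sample, WaterSample) else sample
    try:
        meq = {k: to_meq(conc[k], IONS[k]) for k in ("Na", "K", "Ca", "Mg", "HCO3", "Cl", "SO4")}
    except KeyError as exc:
        raise CoordinateError(f"ion missing for Chadha coordinates: {exc}") from None
    cat_total = meq["Na"] + meq["K"] + meq["Ca"] + meq["Mg"]
    an_total = meq["HCO3"] + meq["Cl"] + meq["SO4"]
    if cat_total <= 0 or an_total <= 0:
        raise CoordinateError("zero ion panel total")
    x = ((meq["Ca"] + meq["Mg"]) - (meq["Na"] + meq["K"])) / cat_total * 100.0
    y = (meq["HCO3"] - (meq["Cl"] + meq["SO4"])) / an_total * 100.0
    return x, y


def classify_quadrant(x: float, y: float) -> tuple[str, bool]:
    """Water type from coordinate signs; exact zeros go to the positive side."""
    boundary = x == 0.0 or y == 0.0
    if boundary:
        log.warning("Chadha coordinate exactly on a boundary (x=%g, y=%g)", x, y)
    if x >= 0 and y >= 0:
        return "Ca-HCO3", boundary
    if x < 0 and y >= 0:
        return "Na-HCO3", boundary
    if x < 0 and y < 0:
        return "Na-Cl", boundary
    return "Ca-Mg-Cl", boundary


def chadha_classify(sample: WaterSample | Mapping[str, float]) -> str:
    x, y = chadha_coords(sample)
    water_type, _ = classify_quadrant(x, y)
    return water_type


def facies_result(sample: WaterSample) -> FaciesResult:
    x1, x2, y = gibbs_coords(sample)
    cx, cy = chadha_coords(sample)
    water_type, boundary = classify_quadrant(cx, cy)
    return FaciesResult(x1, x2, y, cx, cy, water_type, boundary)


def facies_table(df: pd.DataFrame) -> pd.DataFrame:
    """Coordinates and water type for every sample in a survey table."""
    records = []
    for _, row in df.iterrows():
        conc = {p: float(row[c]) for p, c in CONC_COLUMNS.items() if c in row and pd.notna(row[c])}
        tds = float(row["tds_mgL"]) if pd.notna(row.get("tds_mgL", np.nan)) else None
        rec = {"sample_id": row["sample_id"], "group": row["group"]}
        try:
            x1, x2, gy = gibbs_coords(conc, tds=tds)
            rec.update(gibbs_x1=x1, gibbs_x2=x2, gibbs_y=gy)
        except CoordinateError:
            rec.update(gibbs_x1=np.nan, gibbs_x2=np.nan, gibbs_y=np.nan)
        cx, cy = chadha_coords(conc)
        water_type, boundary = classify_quadrant(cx, cy)
        rec.update(chadha_x=cx, chadha_y=cy, water_type=water_type, boundary=boundary)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def facies_tally(water_types: pd.Series | list[str]) -> pd.Series:
    """Percent of samples per water type (all four types always reported)."""
    s = pd.Series(water_types)
    counts = s.value_counts().reindex(WATER_TYPES, fill_value=0)
    return counts / max(len(s), 1) * 100.0
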