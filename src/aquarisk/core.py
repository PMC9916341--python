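"""Sample data model, unit conversions, standards registry, and charge-balance QC.

A survey is carried as a pandas DataFrame with one row per sample (the CSV
schema below), but the scalar chemistry operations are also exposed on a thin
``WaterSample`` record so they can be used one sample at a time.

CSV schema (header names are fixed)::

    sample_id, group, x, y, depth_m, elevation_m, ph, ec_uScm, tds_mgL,
    turbidity_NTU, orp_mV, temp_C, na_mgL, k_mgL, ca_mgL, mg_mgL, hco3_mgL,
    cl_mgL, so4_mgL, no3_mgL, po4_mgL, cr_mgL, ni_mgL, mn_mgL

Concentrations are mg/L throughout; charge-balance arithmetic is meq/L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import datatables as dt

log = logging.getLogger("aquarisk")

GROUPS = ("mining", "non_mining", "mine_water")

#: column name in the CSV for each concentration parameter
CONC_COLUMNS = {p: f"{p.lower()}_mgL" for p in dt.CONC_PARAMS}

META_COLUMNS = [
    "sample_id", "group", "x", "y", "depth_m", "elevation_m",
    "ph", "ec_uScm", "tds_mgL", "turbidity_NTU", "orp_mV", "temp_C",
]

CSV_COLUMNS = META_COLUMNS + [CONC_COLUMNS[p] for p in dt.CONC_PARAMS]


class VocabularyError(KeyError):
    """An ion or parameter name outside the registered vocabulary."""


class StandardsError(ValueError):
    """A guideline limit is missing or nonpositive."""


class BalanceError(ValueError):
    """Charge balance undefined (no measured cations or anions)."""


@dataclass(frozen=True)
class IonSpec:
    """Molar mass (g/mol) and signed charge of an ion."""

    name: str
    molar_mass: float
    charge: int

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar mass must be positive: {self.name}")


#: registry of the measured ions
IONS: dict[str, IonSpec] = {
    name: IonSpec(name, m, z) for name, (m, z) in dt.ION_SPECS.items()
}


@dataclass
class WaterSample:
    """One well or mine-water record."""

    sample_id: str
    group: str
    x: float = 0.0
    y: float = 0.0
    depth_m: float = float("nan")
    elevation_m: float = float("nan")
    ph: float = float("nan")
    ec_uScm: float = float("nan")
    tds_mgL: float = float("nan")
    turbidity_NTU: float = float("nan")
    orp_mV: float = float("nan")
    temp_C: float = float("nan")
    conc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not math.isnan(self.ph) and not (0.0 <= self.ph <= 14.0):
            raise ValueError(f"pH out of range: {self.ph}")
        for name, value in self.conc.items():
            if name not in dt.CONC_PARAMS:
                raise VocabularyError(name)
            if value < 0:
                raise ValueError(f"negative concentration for {name}: {value}")


def to_meq(conc_mgL: float, ion: IonSpec | str) -> float:
    """Convert a concentration in mg/L to milliequivalents per litre.

    meq/L = mg/L * |charge| / molar mass.
    """
    if isinstance(ion, str):
        try:
            ion = IONS[ion]
        except KeyError as exc:
            raise VocabularyError(str(exc)) from None
    if conc_mgL < 0:
        raise ValueError(f"negative concentration: {conc_mgL}")
    return conc_mgL * abs(ion.charge) / ion.molar_mass


def _meq_sum(conc: Mapping[str, float], names: Sequence[str]) -> tuple[float, int]:
    total, n_used = 0.0, 0
    for name in names:
        if name not in conc:
            log.warning("charge balance: %s not measured, excluded from sum", name)
            continue
        total += to_meq(conc[name], IONS[name])
        n_used += 1
    return total, n_used


def icbe(
    sample: WaterSample | Mapping[str, float],
    cations: Sequence[str] = dt.CATIONS,
    anions: Sequence[str] = dt.ANIONS,
) -> float:
    """Ion charge balance error in percent.

    ICBE = (sum cations - sum anions) / (sum cations + sum anions) * 100,
    with both sums in meq/L.  |ICBE| <= 5 % is the conventional QC pass.
    Missing ions are excluded from the sums (never imputed as zero).
    """
    conc = sample.conc if isinstance(sample, WaterSample) else sample
    cat, n_cat = _meq_sum(conc, cations)
    an, n_an = _meq_sum(conc, anions)
    if n_cat == 0 or n_an == 0 or (cat + an) == 0.0:
        raise BalanceError("need at least one measured cation and anion")
    return (cat - an) / (cat + an) * 100.0


def icbe_acceptable(value: float, tolerance: float = 5.0) -> bool:
    return abs(value) <= tolerance


class StandardsTable(dict):
    """Guideline limits keyed by parameter name; all limits must be positive."""

    def __init__(self, limits: Mapping[str, float] | None = None):
        super().__init__(limits if limits is not None else dt.WHO_LIMITS)
        for name, limit in self.items():
            if limit <= 0:
                raise StandardsError(f"nonpositive limit for {name}: {limit}")

    def limit(self, param: str) -> float:
        try:
            return self[param]
        except KeyError:
            raise StandardsError(f"no guideline limit registered for {param!r}") from None


def samples_to_frame(samples: Iterable[WaterSample]) -> pd.DataFrame:
    """Flatten WaterSample records into the canonical one-row-per-sample table."""
    rows = []
    for s in samples:
        row = {c: getattr(s, c) for c in META_COLUMNS}
        for p, col in CONC_COLUMNS.items():
            row[col] = s.conc.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_samples(df: pd.DataFrame) -> list[WaterSample]:
    out = []
    for _, row in df.iterrows():
        conc = {
            p: float(row[col])
            for p, col in CONC_COLUMNS.items()
            if col in row and pd.notna(row[col])
        }
        out.append(
            WaterSample(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                x=float(row.get("x", 0.0)),
                y=float(row.get("y", 0.0)),
                depth_m=float(row.get("depth_m", np.nan)),
                elevation_m=float(row.get("elevation_m", np.nan)),
                ph=float(row.get("ph", np.nan)),
                ec_uScm=float(row.get("ec_uScm", np.nan)),
                tds_mgL=float(row.get("tds_mgL", np.nan)),
                turbidity_NTU=float(row.get("turbidity_NTU", np.nan)),
                orp_mV=float(row.get("orp_mV", np.nan)),
                temp_C=float(row.get("temp_C", np.nan)),
                conc=conc,
            )
        )
    return out


def read_samples(path) -> pd.DataFrame:
    """Read and validate a survey CSV; logs per-row QC (charge balance)."""
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"survey CSV missing required columns: {missing}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        raise ValueError(
            f"unknown group labels: {sorted(df.loc[bad_group, 'group'].unique())}"
        )
    for p, col in CONC_COLUMNS.items():
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValueError(f"negative concentrations in column {col}")
    for sample in frame_to_samples(df):
        try:
            err = icbe(sample)
        except BalanceError:
            log.warning("sample %s: charge balance undefined", sample.sample_id)
            continue
        if not icbe_acceptable(err):
            log.warning("sample %s: ICBE %.2f%% outside +/-5%%", sample.sample_id, err)
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def group_summary(
    df: pd.DataFrame,
    params: Sequence[str] | None = None,
    by: str = "group",
) -> pd.DataFrame:
    """Per-group min/max/mean/sd table (sample sd, n-1 denominator).

    Degenerate groups of one sample get sd 0 and ``degenerate=True``.
    """
    if df.empty:
        raise ValueError("no samples")
    if params is None:
        params = [c for c in df.columns if c not in ("sample_id", "group")]
    records = []
    for group, sub in df.groupby(by, sort=False):
        if sub.empty:
            raise ValueError(f"empty group {group!r}")
        for p in params:
            vals = sub[p].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            degenerate = vals.size < 2
            records.append(
                {
                    "group": group,
                    "parameter": p,
                    "n": vals.size,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "mean": float(vals.mean()),
                    "sd": 0.0 if degenerate else float(vals.std(ddof=1)),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame.from_records(records)


def conc_matrix(df: pd.DataFrame, params: Sequence[str]) -> np.ndarray:
    """Extract an (n_samples, n_params) concentration matrix in mg/L."""
    cols = []
    for p in params:
        col = CONC_COLUMNS.get(p, p)
        if col not in df.columns:
            raise VocabularyError(p)
        cols.append(df[col].to_numpy(dtype=float))
    return np.column_stack(cols)
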