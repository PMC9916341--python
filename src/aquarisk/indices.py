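"""Single-factor pollution ratios, the Nemerow composite index, and
guideline-exceedance percentages.

The single-factor ratio of parameter *i* is C_i / S_i against its guideline
limit.  The Nemerow composite of a sample over a parameter set is

    NPI = sqrt(((mean_i C_i/S_i)^2 + (max_i C_i/S_i)^2) / 2),

which weights the worst single offender alongside the average burden.  pH is
two-sided and excluded from the composite by default; an explicit pH ratio
against a reference value can be requested separately.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datatables as dt
from .core import CONC_COLUMNS, StandardsTable, StandardsError, WaterSample

#: parameters entering the default composite (single-sided, limit registered)
DEFAULT_NPI_PARAMS = tuple(p for p in dt.WHO_LIMITS)


def single_factor(conc: float, limit: float) -> float:
    """C/S ratio of one parameter against its guideline limit."""
    if limit <= 0:
        raise StandardsError(f"nonpositive limit: {limit}")
    if conc < 0:
        raise ValueError(f"negative concentration: {conc}")
    return conc / limit


def sample_ratios(
    sample: WaterSample | Mapping[str, float],
    standards: StandardsTable,
    params: Sequence[str] | None = None,
    include_ph: bool = False,
) -> dict[str, float]:
    """Single-factor ratios for every requested parameter of one sample.

    ``sample`` may be a WaterSample or a flat name->value mapping that also
    carries bulk parameters (ec_uScm, tds_mgL, turbidity_NTU).  With
    ``include_ph`` the pH ratio against the reference value is added.
    """
    if isinstance(sample, WaterSample):
        values: dict[str, float] = dict(sample.conc)
        for bulk in ("ec_uScm", "tds_mgL", "turbidity_NTU"):
            v = getattr(sample, bulk)
            if not np.isnan(v):
                values[bulk] = v
        if include_ph and not np.isnan(sample.ph):
            values["ph"] = sample.ph
    else:
        values = dict(sample)
    if params is None:
        params = [p for p in values if p in standards or p == "ph"]
    out = {}
    for p in params:
        if p not in values:
            continue
        if p == "ph":
            if include_ph:
                out["ph"] = values["ph"] / dt.PH_REFERENCE
            continue
        out[p] = single_factor(values[p], standards.limit(p))
    return out


def nemerow(ratios: Mapping[str, float] | Sequence[float]) -> float:
    """Nemerow composite of a set of single-factor ratios."""
    vals = np.asarray(
        list(ratios.values()) if isinstance(ratios, Mapping) else ratios, dtype=float
    )
    if vals.size == 0:
        raise ValueError("empty parameter set")
    if (vals < 0).any():
        raise ValueError("ratios must be nonnegative")
    return float(np.sqrt((vals.mean() ** 2 + vals.max() ** 2) / 2.0))


def index_table(
    df: pd.DataFrame,
    standards: StandardsTable | None = None,
    params: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample single-factor ratios and Nemerow composite for a survey table."""
    standards = standards if standards is not None else StandardsTable()
    if params is None:
        params = [
            p
            for p in standards
            if CONC_COLUMNS.get(p, p) in df.columns and p != "ph"
        ]
    out = pd.DataFrame({"sample_id": df["sample_id"], "group": df["group"]})
    ratio_cols = []
    for p in params:
        col = CONC_COLUMNS.get(p, p)
        r = df[col].astype(float) / standards.limit(p)
        out[f"ratio_{p}"] = r
        ratio_cols.append(f"ratio_{p}")
    ratios = out[ratio_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["npi"] = np.sqrt(
            (np.nanmean(ratios, axis=1) ** 2 + np.nanmax(ratios, axis=1) ** 2) / 2.0
        )
    return out


def exceedance_table(
    df: pd.DataFrame,
    standards: StandardsTable | None = None,
    params: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percent of samples with C > S per parameter, per group and overall."""
    if df.empty:
        raise ValueError("no samples")
    standards = standards if standards is not None else StandardsTable()
    if params is None:
        params = [p for p in standards if CONC_COLUMNS.get(p, p) in df.columns]
    records = []
    scopes = [("overall", df)] + [(g, sub) for g, sub in df.groupby("group", sort=False)]
    for scope, sub in scopes:
        for p in params:
            col = CONC_COLUMNS.get(p, p)
            vals = sub[col].dropna()
            if vals.empty:
                continue
            frac = float((vals > standards.limit(p)).mean())
            records.append(
                {
                    "scope": scope,
                    "parameter": p,
                    "n": int(vals.size),
                    "percent_exceeding": 100.0 * frac,
                }
            )
    return pd.DataFrame.from_records(records)
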