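"""End-to-end pipeline: QC -> indices -> facies -> risk -> clustering ->
sources -> speciation -> spatial, writing per-stage CSV/JSON and a summary
bundle plus a machine-readable run manifest.

Outputs are a pure function of (input table, configuration, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, clustering, datatables as dt, facies, hhra, indices
from . import sources, spatial, speciation
from .core import (
    StandardsTable,
    conc_matrix,
    frame_to_samples,
    group_summary,
    icbe,
    read_samples,
)

log = logging.getLogger("aquarisk")

ALL_STAGES = (
    "qc", "indices", "facies", "hhra", "cluster", "sources", "speciate", "spatial",
)

#: parameters entering the multivariate stages (clustering, PMF, APCS)
MULTIVARIATE_PARAMS = [
    "ph", "ec_uScm", "tds_mgL", "turbidity_NTU",
    "Na", "K", "Mg", "Ca", "PO4", "NO3", "HCO3", "Cl", "SO4", "Cr", "Ni", "Mn",
]


@dataclass
class RunConfig:
    input_path: str | Path | None = None
    out_dir: str | Path = "aquarisk_out"
    stages: Sequence[str] = ALL_STAGES
    seed: int = 0
    n_factors: int = 5
    n_starts: int = 20
    cluster_k: int = 3
    krige_param: str = "Cr"
    krige_resolution: int = 40
    standards: StandardsTable = field(default_factory=StandardsTable)

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def _matrix(df: pd.DataFrame):
    cols = [c for c in MULTIVARIATE_PARAMS]
    X = np.column_stack(
        [
            df[c].to_numpy(dtype=float)
            if c in df.columns
            else conc_matrix(df, [c])[:, 0]
            for c in cols
        ]
    )
    keep = ~np.isnan(X).any(axis=1)
    return X[keep], cols, keep


def run_pipeline(config: RunConfig, df: pd.DataFrame | None = None) -> dict:
    """Run the enabled stages and write the report bundle.

    ``df`` may be passed directly (e.g. fresh from the synthetic generator);
    otherwise ``config.input_path`` is read.  Returns a dict of stage name ->
    output artefact paths.  A stage failure aborts the run but retains the
    outputs already written, alongside an ``error.json`` record.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if df is None:
        if config.input_path is None:
            raise ValueError("either df or config.input_path is required")
        df = read_samples(config.input_path)
    written: dict[str, list[str]] = {}
    manifest = {
        "aquarisk_version": __version__,
        "tables_version": dt.TABLES_VERSION,
        "seed": config.seed,
        "stages": list(config.stages),
        "n_samples": int(len(df)),
        "input_sha256": hashlib.sha256(
            df.to_csv(index=False).encode()
        ).hexdigest(),
    }

    def emit(stage: str, name: str, obj) -> None:
        path = out_dir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        else:
            path.write_text(json.dumps(obj, indent=2, default=_jsonable))
        written.setdefault(stage, []).append(str(path))
        log.info("stage %s: wrote %s (%d input rows)", stage, path, len(df))

    try:
        samples = frame_to_samples(df)
        if "qc" in config.stages:
            qc = pd.DataFrame(
                {
                    "sample_id": df["sample_id"],
                    "group": df["group"],
                    "icbe_pct": [icbe(s) for s in samples],
                }
            )
            qc["acceptable"] = qc["icbe_pct"].abs() <= 5.0
            emit("qc", "qc.csv", qc)
            emit("qc", "group_summary.csv", group_summary(df))
        if "indices" in config.stages:
            emit("indices", "indices.csv", indices.index_table(df, config.standards))
            emit("indices", "exceedance.csv",
                 indices.exceedance_table(df, config.standards))
        if "facies" in config.stages:
            ftab = facies.facies_table(df)
            emit("facies", "facies.csv", ftab)
            emit("facies", "facies_tally.json",
                 facies.facies_tally(ftab["water_type"]).to_dict())
        if "hhra" in config.stages:
            risk = hhra.risk_table(df)
            emit("hhra", "risk.csv", risk)
            emit("hhra", "risk_summary.csv", hhra.group_risk_summary(risk))
        X, cols, keep = _matrix(df)
        if "cluster" in config.stages:
            result = clustering.haca(X, k=config.cluster_k, params=cols)
            lab = pd.DataFrame(
                {"sample_id": df.loc[keep, "sample_id"], "cluster": result.labels}
            )
            emit("cluster", "clusters.csv", lab)
            emit("cluster", "cluster_centroids.csv",
                 result.centroids.reset_index(names="cluster"))
            severity = (
                clustering.severity_ranking(result, standards=config.standards)
                if config.cluster_k == 3
                else None
            )
            emit(
                "cluster",
                "cluster_summary.json",
                {
                    "within_pct": result.within_pct,
                    "between_pct": result.between_pct,
                    "counts": result.counts.tolist(),
                    "severity": severity.reset_index().to_dict("records")
                    if severity is not None
                    else None,
                },
            )
        if "sources" in config.stages:
            U = sources.build_uncertainty(
                np.abs(X), cols, sources.UncertaintyModel(), default_mdl=0.01
            )
            model = sources.fit_pmf(
                np.clip(X, 0.0, None), U, p=config.n_factors,
                n_starts=config.n_starts, seed=config.seed,
            )
            emit("sources", "pmf_profiles.csv",
                 pd.DataFrame(model.F, columns=cols))
            emit("sources", "pmf_contributions.csv",
                 pd.DataFrame(model.G, columns=[f"F{k+1}" for k in range(model.p)]))
            apcs = sources.apcs_mlr(X, n_factors=config.n_factors)
            emit(
                "sources",
                "sources_diagnostics.json",
                {
                    "q_true": model.q_true,
                    "q_robust": model.q_robust,
                    "converged": model.converged,
                    "signal_to_noise": dict(
                        zip(cols, sources.signal_to_noise(np.clip(X, 0, None), U))
                    ),
                    "apcs_contributions_pct": apcs.contributions_pct.tolist(),
                    "apcs_r_squared": apcs.r_squared,
                },
            )
        if "speciate" in config.stages:
            emit("speciate", "saturation_indices.csv",
                 speciation.saturation_table(samples))
        if "spatial" in config.stages:
            pts = df[["x", "y"]].to_numpy(dtype=float)
            vals = conc_matrix(df, [config.krige_param])[:, 0]
            ok = ~np.isnan(vals)
            gx, gy, grid = spatial.krige_grid(
                pts[ok], vals[ok], resolution=config.krige_resolution
            )
            classed = spatial.classify5(grid)
            raster = pd.DataFrame(
                {
                    "x": gx.ravel(),
                    "y": gy.ravel(),
                    "value": grid.ravel(),
                    "class": [
                        spatial.VULNERABILITY_CLASSES[c] if c >= 0 else ""
                        for c in classed.classes.ravel()
                    ],
                }
            )
            emit("spatial", "raster.csv", raster)
            emit("spatial", "raster_breaks.json",
                 {"breaks": classed.breaks.tolist(), "constant": classed.constant})
    except Exception as exc:  # retain partial outputs + machine-readable error
        (out_dir / "error.json").write_text(
            json.dumps({"stage_outputs": written, "error": repr(exc)}, indent=2)
        )
        raise
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    written["manifest"] = [str(out_dir / "manifest.json")]
    return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
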