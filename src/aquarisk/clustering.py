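"""Hierarchical agglomerative cluster analysis (Ward) with severity labels.

Samples are clustered on z-scored variables with Euclidean distance and Ward
linkage; the tree is cut at a fixed cluster count (three in the study
design).  Clusters are then ordered by the total metal burden of their
centroids (sum of single-factor C/S ratios) and labelled least / moderately
/ severely polluted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import datatables as dt
from .core import StandardsTable

log = logging.getLogger("aquarisk")

SEVERITY_LABELS = ("least", "moderately", "severely")


class DegenerateScaleError(ValueError):
    """A variable is constant; z-scoring is undefined."""


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray  # scipy linkage encoding of the tree
    labels: np.ndarray  # 1..k per sample
    k: int
    centroids: pd.DataFrame  # per-cluster means in original units
    counts: np.ndarray  # per-cluster sample counts
    within_pct: float
    between_pct: float
    params: list[str]


def haca(
    X: np.ndarray | pd.DataFrame,
    k: int,
    params: list[str] | None = None,
    standardize: bool = True,
) -> ClusterResult:
    """Ward-linkage clustering cut at k clusters with variance decomposition.

    The within/between percentages decompose the total sum of squares of the
    (standardized) data: within% + between% = 100 exactly.
    """
    if isinstance(X, pd.DataFrame):
        params = list(X.columns) if params is None else params
        X = X[params].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        params = params if params is not None else [f"v{j}" for j in range(X.shape[1])]
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if standardize:
        sd = X.std(axis=0, ddof=1) if n > 1 else np.ones(X.shape[1])
        if np.any(sd <= 0):
            bad = [params[j] for j in np.where(sd <= 0)[0]]
            raise DegenerateScaleError(f"constant columns: {bad}")
        Z = (X - X.mean(axis=0)) / sd
    else:
        Z = X
    Zlink = linkage(Z, method="ward")
    labels = fcluster(Zlink, t=k, criterion="maxclust")
    grand = Z.mean(axis=0)
    tss = float(np.sum((Z - grand) ** 2))
    wss = 0.0
    centroid_rows, counts = [], []
    for c in range(1, k + 1):
        members = labels == c
        counts.append(int(members.sum()))
        zc = Z[members].mean(axis=0)
        wss += float(np.sum((Z[members] - zc) ** 2))
        centroid_rows.append(X[members].mean(axis=0))
    within_pct = 100.0 * wss / tss if tss > 0 else 0.0
    centroids = pd.DataFrame(
        centroid_rows, columns=params, index=[f"C{c}" for c in range(1, k + 1)]
    )
    return ClusterResult(
        linkage_matrix=Zlink,
        labels=labels,
        k=k,
        centroids=centroids,
        counts=np.asarray(counts),
        within_pct=within_pct,
        between_pct=100.0 - within_pct,
        params=params,
    )


def severity_ranking(
    result: ClusterResult,
    metals: tuple[str, ...] = dt.METALS,
    standards: StandardsTable | None = None,
) -> pd.DataFrame:
    """Order k=3 clusters by centroid metal burden and label them.

    Burden of a cluster = sum over metals of centroid C/S.  Returns a frame
    indexed by cluster with burden, severity label, count, and share (%).
    Ties are broken lexicographically by cluster name and flagged.
    """
    if result.k != len(SEVERITY_LABELS):
        raise ValueError(f"severity ranking requires k={len(SEVERITY_LABELS)}")
    standards = standards if standards is not None else StandardsTable()
    usable = [m for m in metals if m in result.centroids.columns]
    if not usable:
        raise ValueError("no metal columns in centroids")
    burden = sum(
        result.centroids[m] / standards.limit(m) for m in usable
    )
    order = burden.sort_values(kind="stable").index  # lexicographic on ties
    tie = bool(burden.duplicated().any())
    if tie:
        log.warning("severity ranking: tied centroid burdens, lexicographic break")
    n_total = int(result.counts.sum())
    rows = []
    for label, cluster in zip(SEVERITY_LABELS, order):
        idx = int(cluster[1:]) - 1
        rows.append(
            {
                "cluster": cluster,
                "severity": label,
                "metal_burden": float(burden[cluster]),
                "n": int(result.counts[idx]),
                "share_pct": 100.0 * result.counts[idx] / n_total,
                "tie": tie,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def dendrogram_text(result: ClusterResult, labels: list[str] | None = None) -> str:
    """Nested-parenthesis (newick-like) rendering of the merge tree with heights."""
    n = result.linkage_matrix.shape[0] + 1
    names = labels if labels is not None else [f"s{i}" for i in range(n)]
    nodes: dict[int, str] = {i: names[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(result.linkage_matrix):
        nodes[n + i] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.4g}"
    return nodes[2 * n - 2] + ";"
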