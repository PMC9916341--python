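"""Receptor-model source apportionment.

Two complementary routes are implemented:

* **PMF** — uncertainty-weighted nonnegative matrix factorization.  The data
  matrix X (samples x parameters) is approximated by G F with G >= 0 (source
  contributions) and F >= 0 (source profiles), minimizing

      Q = sum_ij ((x_ij - (GF)_ij) / u_ij)^2

  where u_ij is the measurement uncertainty.  Uncertainties follow the EPA
  convention: below the detection limit u = (5/6) MDL, above it
  u = sqrt(MDL^2 + (error_fraction * C)^2).  The solver uses multiplicative
  updates on the weighted Frobenius objective, restarted from several random
  nonnegative initializations; the best run is kept.  A robust Q caps
  scaled residuals |e/u| at 4.

* **APCS-MLR** — principal components of the correlation matrix, varimax
  rotation, absolute principal component scores (rescored against an
  artificial zero-concentration sample), and a least-squares regression of
  the total measured burden on the APCS to convert factors into percent
  contributions.

Factor order in any NMF is arbitrary; recovery metrics match factors to a
reference by Hungarian assignment on cosine similarity of profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import datatables as dt

_EPS = 1e-12


class UncertaintyError(ValueError):
    """Invalid or degenerate uncertainty matrix."""


@dataclass(frozen=True)
class UncertaintyModel:
    """Per-parameter detection limits and a common analytical error fraction."""

    mdl: Mapping[str, float] = field(default_factory=lambda: dict(dt.MDL))
    error_fraction: float = dt.ERROR_FRACTION

    def __post_init__(self) -> None:
        if not (0.0 < self.error_fraction < 1.0):
            raise ValueError("error fraction must be in (0, 1)")
        for name, v in self.mdl.items():
            if v < 0:
                raise ValueError(f"negative MDL for {name}")


def build_uncertainty(
    X: np.ndarray,
    params: Sequence[str],
    model: UncertaintyModel | None = None,
    default_mdl: float = 0.0,
) -> np.ndarray:
    """Elementwise uncertainty matrix for X (samples x parameters).

    u = (5/6) MDL where C <= MDL, else sqrt(MDL^2 + (ef * C)^2).
    Parameters without a registered MDL use ``default_mdl``.
    """
    model = model if model is not None else UncertaintyModel()
    X = np.asarray(X, dtype=float)
    if (X < 0).any() or not np.isfinite(X).all():
        raise ValueError("concentrations must be finite and nonnegative")
    mdl = np.array([model.mdl.get(p, default_mdl) for p in params], dtype=float)
    below = X <= mdl[None, :]
    above = np.sqrt(mdl[None, :] ** 2 + (model.error_fraction * X) ** 2)
    U = np.where(below, (5.0 / 6.0) * mdl[None, :], above)
    # a zero MDL with C = 0 would give u = 0; keep weights finite
    return np.maximum(U, _EPS)


def signal_to_noise(X: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Per-parameter S/N: mean over samples of (x-u)/u where x > u, else 0."""
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if X.shape != U.shape:
        raise ValueError("X and U shapes differ")
    if (U <= 0).any():
        raise UncertaintyError("uncertainties must be strictly positive")
    d = np.where(X > U, (X - U) / U, 0.0)
    return d.mean(axis=0)


@dataclass
class PMFModel:
    """A fitted weighted nonnegative factorization X ~ G F."""

    X: np.ndarray
    U: np.ndarray
    G: np.ndarray  # (n, p) contributions
    F: np.ndarray  # (p, m) profiles
    q_true: float
    q_robust: float
    n_starts: int
    converged: bool
    q_history: np.ndarray  # per-iteration Q of the winning run

    @property
    def p(self) -> int:
        return self.G.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.G @ self.F


def q_value(X: np.ndarray, U: np.ndarray, G: np.ndarray, F: np.ndarray) -> float:
    r = (X - G @ F) / U
    return float(np.sum(r * r))


def q_robust_value(
    X: np.ndarray, U: np.ndarray, G: np.ndarray, F: np.ndarray, cap: float = 4.0
) -> float:
    """Q with scaled residuals capped at ``cap`` (outlier-limited objective)."""
    r = (X - G @ F) / U
    return float(np.sum(np.minimum(r * r, cap * cap)))


def _fit_once(
    X: np.ndarray,
    W: np.ndarray,
    U: np.ndarray,
    p: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    tol_window: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    n, m = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / p)
    G = rng.uniform(0.1, 1.0, size=(n, p)) * scale
    F = rng.uniform(0.1, 1.0, size=(p, m)) * scale
    WX = W * X
    q_hist = np.empty(max_iter)
    converged = False
    q_prev = q_value(X, U, G, F)
    for it in range(max_iter):
        R = W * (G @ F)
        G *= (WX @ F.T) / np.maximum(R @ F.T, _EPS)
        R = W * (G @ F)
        F *= (G.T @ WX) / np.maximum(G.T @ R, _EPS)
        q = q_value(X, U, G, F)
        q_hist[it] = q
        if it >= tol_window:
            q_old = q_hist[it - tol_window]
            if q_old - q <= tol * max(q_old, _EPS):
                converged = True
                q_hist = q_hist[: it + 1]
                break
        q_prev = q
    else:
        q_hist = q_hist[:max_iter]
    return G, F, q_hist, converged


def fit_pmf(
    X: np.ndarray,
    U: np.ndarray,
    p: int,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 5000,
    tol: float = 1e-8,
    tol_window: int = 20,
) -> PMFModel:
    """Weighted NMF minimizing Q, best of ``n_starts`` random starts.

    Non-convergence within ``max_iter`` iterations is flagged on the result,
    not raised.  For a fixed seed the fit is bit-reproducible.
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if X.shape != U.shape:
        raise ValueError("X and U shapes differ")
    n, m = X.shape
    if not (1 <= p < min(n, m)):
        raise ValueError(f"factor count p={p} must satisfy 1 <= p < min(n, m)")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if (U <= 0).any():
        raise UncertaintyError("uncertainties must be strictly positive")
    rng = np.random.default_rng(seed)
    W = 1.0 / (U * U)
    best = None
    for _ in range(n_starts):
        G, F, q_hist, conv = _fit_once(X, W, U, p, rng, max_iter, tol, tol_window)
        q = q_hist[-1]
        if best is None or q < best[2][-1]:
            best = (G, F, q_hist, conv)
    G, F, q_hist, conv = best
    return PMFModel(
        X=X,
        U=U,
        G=G,
        F=F,
        q_true=float(q_hist[-1]),
        q_robust=q_robust_value(X, U, G, F),
        n_starts=n_starts,
        converged=conv,
        q_history=q_hist,
    )


def factor_contributions(model: PMFModel) -> np.ndarray:
    """Percent contribution of each factor to each parameter, (p, m).

    For parameter j, factor k contributes
    sum_i g_ik f_kj / sum_i sum_k g_ik f_kj * 100; columns sum to 100.
    """
    g_sums = model.G.sum(axis=0)  # (p,)
    mass = g_sums[:, None] * model.F  # (p, m)
    total = mass.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("all-zero reconstruction for some parameter")
    return mass / total[None, :] * 100.0


def factor_scan(
    X: np.ndarray,
    U: np.ndarray,
    p_values: Sequence[int] = (3, 4, 5),
    n_starts: int = 20,
    seed: int | None = None,
    **kwargs,
) -> dict[int, dict[str, float]]:
    """Q_true / Q_robust across candidate factor counts (no automatic choice)."""
    out = {}
    for p in p_values:
        model = fit_pmf(X, U, p, n_starts=n_starts, seed=seed, **kwargs)
        out[p] = {
            "q_true": model.q_true,
            "q_robust": model.q_robust,
            "ratio": model.q_true / model.q_robust if model.q_robust > 0 else np.nan,
        }
    return out


def match_factors(
    F_est: np.ndarray, F_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated to true factors (rows) by Hungarian assignment on
    cosine similarity of profiles.  Returns (permutation, similarities),
    where permutation[k] is the estimated row matched to true row k.
    """
    def _unit(A):
        norms = np.linalg.norm(A, axis=1, keepdims=True)
        return A / np.maximum(norms, _EPS)

    S = _unit(F_true) @ _unit(F_est).T  # (p_true, p_est)
    rows, cols = linear_sum_assignment(-S)
    perm = np.empty(len(rows), dtype=int)
    sims = np.empty(len(rows))
    for r, c in zip(rows, cols):
        perm[r] = c
        sims[r] = S[r, c]
    return perm, sims


# ---------------------------------------------------------------------------
# APCS-MLR
# ---------------------------------------------------------------------------


@dataclass
class ApcsResult:
    loadings: np.ndarray  # (m, k) varimax-rotated loadings
    apcs: np.ndarray  # (n, k) absolute principal component scores
    coefficients: np.ndarray  # (k,) regression slopes
    intercept: float
    contributions_pct: np.ndarray  # (k,) percent of explained burden
    unexplained_pct: float
    r_squared: float
    eigenvalues: np.ndarray


def varimax(loadings: np.ndarray) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal, communality-preserving).

    Each rotated factor is sign-flipped so its largest-magnitude loading is
    positive, removing the reflection ambiguity.
    """
    from statsmodels.multivariate.factor_rotation import rotate_factors

    A = np.asarray(loadings, dtype=float)
    if A.shape[1] < 2:
        L = A.copy()
    else:
        L, _ = rotate_factors(A, "varimax")
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    return L * signs[None, :]


def apcs_mlr(
    X: np.ndarray,
    n_factors: int,
    rotate: bool = True,
    target: np.ndarray | None = None,
) -> ApcsResult:
    """PCA -> varimax -> absolute scores -> regression contributions.

    ``target`` is the response the scores are regressed on; by default the
    total measured burden (row sums of X).  Percent contributions of the
    retained sources are shares of the mean fitted response; the remainder
    (intercept share) is reported as unexplained.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not (1 <= n_factors <= m):
        raise ValueError("n_factors must be between 1 and n parameters")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise np.linalg.LinAlgError("constant column: correlation matrix singular")
    Z = (X - mean) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1][:n_factors]
    eigvals_k = np.maximum(eigvals[order], _EPS)
    loadings = eigvecs[:, order] * np.sqrt(eigvals_k)[None, :]
    if rotate and n_factors > 1:
        loadings = varimax(loadings)
    # regression-method factor scores: scores = Z corr^{-1} L
    B = np.linalg.solve(corr, loadings)  # (m, k)
    scores = Z @ B
    z0 = (np.zeros(m) - mean) / sd  # artificial zero-concentration sample
    apcs = scores - z0 @ B  # absolute principal component scores
    y = X.sum(axis=1) if target is None else np.asarray(target, dtype=float)
    design = np.column_stack([np.ones(n), apcs])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    mean_fitted = float(fitted.mean())
    source_means = coef[1:] * apcs.mean(axis=0)
    contributions = source_means / mean_fitted * 100.0
    unexplained = 100.0 - float(contributions.sum())
    return ApcsResult(
        loadings=loadings,
        apcs=apcs,
        coefficients=coef[1:],
        intercept=float(coef[0]),
        contributions_pct=contributions,
        unexplained_pct=unexplained,
        r_squared=r2,
        eigenvalues=eigvals[order],
    )
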