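"""Partial correlations between brain-average coupling and the phenotype.

Covariate control follows the standard residualization definition: the partial
correlation of x and y given Z is the Pearson correlation of the residuals of
x and y after ordinary least-squares regression on Z (with intercept), with a
two-sided p from the t distribution on n - 2 - k degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import CouplingTable
from .datatypes import AnalysisConfig, ParticipantTable, ValidationError

__all__ = ["partial_correlation", "partial_correlation_matrix",
           "brain_average_association"]


def _design(Z: np.ndarray | None, n: int) -> np.ndarray:
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        return np.ones((n, 1))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValidationError("covariate matrix length does not match data")
    X = np.column_stack([np.ones(n), Z])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                bad.append(j - 1)
        raise ValidationError(f"covariate columns {bad} are collinear")
    return X


def partial_correlation(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for Z.

    Returns (r, p).  With no covariates this reduces to the plain Pearson
    correlation.  Requires n > k + 3 for a defined test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    X = _design(Z, n)
    k = X.shape[1] - 1
    if n <= k + 3:
        raise ValidationError(f"need n > k + 3 observations (n={n}, k={k})")
    q, _ = np.linalg.qr(X)
    rx = x - q @ (q.T @ x)
    ry = y - q @ (q.T @ y)
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    # residuals at floating-point noise level mean x or y lies in span(Z)
    if nx <= 1e-10 * max(np.linalg.norm(x), 1.0) or             ny <= 1e-10 * max(np.linalg.norm(y), 1.0):
        return 0.0, 1.0
    denom = nx * ny
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def partial_correlation_matrix(
    X: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None
) -> np.ndarray:
    """Column-wise partial correlations of an (n, m) matrix with y given Z.

    Degenerate (constant after residualization) columns yield 0.  This is the
    vectorized workhorse behind node-measure-assignment mask building.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    D = _design(Z, n)
    q, _ = np.linalg.qr(D)
    Xr = X - q @ (q.T @ X)
    yr = y - q @ (q.T @ y)
    ny = np.linalg.norm(yr)
    nx = np.linalg.norm(Xr, axis=0)
    if ny <= 1e-10 * max(np.linalg.norm(y), 1.0):
        return np.zeros(X.shape[1])
    degenerate = nx <= 1e-10 * np.maximum(np.linalg.norm(X, axis=0), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xr.T @ yr) / (np.where(degenerate, 1.0, nx) * ny)
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0)


def brain_average_association(
    table: CouplingTable,
    participants: ParticipantTable,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Phenotype association of brain-average coupling, per condition x measure.

    For each condition and measure, the mean coupling over regions is
    partially correlated with the phenotype controlling for age, gender,
    handedness and the condition-specific motion covariate.  Significance is
    flagged at the Bonferroni-corrected threshold (default 0.05 / 4 measures).
    """
    cfg = cfg or AnalysisConfig()
    sub = participants.subset(table.participants)
    g = sub.g
    region_mean = table.values.mean(axis=3)
    rows = []
    for ci, cond in enumerate(table.conditions):
        Z = sub.covariates(cond)
        for mi, meas in enumerate(table.measures):
            r, p = partial_correlation(region_mean[:, ci, mi], g, Z)
            rows.append({
                "condition": cond, "measure": meas, "r": r, "p": p,
                "n": len(sub), "significant": p < cfg.bonferroni_alpha,
            })
    return pd.DataFrame(rows)
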