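"""Vulnerability as expected poverty via three-stage feasible GLS.

Stage 1: OLS of log welfare on X gives residuals.
Stage 2: OLS of squared residuals on X, then one FGLS refinement weighted by
         the first-pass fitted variances, gives the variance-equation
         coefficients ``beta``.
Stage 3: WLS of log welfare on X with weights 1/sqrt(X @ beta) gives the
         mean-equation coefficients ``alpha``.

Per-row vulnerability is then
``Phi((ln_poverty_line - X @ alpha) / sqrt(max(X @ beta, floor)))``,
binarised at a cutoff (boundary inclusive).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

log = logging.getLogger(__name__)

#: lower bound applied to fitted variances before taking square roots
VARIANCE_FLOOR = 1e-4


@dataclass
class WelfareModel:
    alpha: np.ndarray
    beta: np.ndarray
    design_columns: tuple[str, ...]
    n_obs: int
    r2_mean: float
    r2_variance: float
    n_floored: int


@dataclass
class VulnerabilityResult:
    vulnerability: np.ndarray
    vep_binary: np.ndarray
    ln_poverty_line: float
    cutoff: float


def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    # rank-revealing QR; name the pivoted-out columns on failure
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if (diag <= tol).any():
        from scipy.linalg import qr as scipy_qr
        _, _, piv = scipy_qr(X, mode="economic", pivoting=True)
        rank = int(np.linalg.matrix_rank(X))
        bad = [columns[i] for i in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {bad}")


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else 0.0
    return coef, resid, r2


def fit_welfare_fgls(ln_welfare: np.ndarray, X: np.ndarray,
                     design_columns: Sequence[str] | None = None) -> WelfareModel:
    """Three-stage FGLS fit of the heteroskedastic welfare equation."""
    y = np.asarray(ln_welfare, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if design_columns is None:
        design_columns = tuple(f"x{i}" for i in range(p))
    if len(design_columns) != p:
        raise ValueError("design_columns length must match X columns")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than columns ({p})")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in welfare fit inputs")
    _check_rank(X, design_columns)

    # stage 1: OLS mean equation
    _, resid, _ = _ols(y, X)
    e2 = resid ** 2

    # stage 2: variance equation, OLS pass then one FGLS refinement
    lam, _, r2_var = _ols(e2, X)
    v0 = np.maximum(X @ lam, VARIANCE_FLOOR)
    beta, _, _ = _ols(e2 / v0, X / v0[:, None])

    var = X @ beta
    if (var < 0).all():
        raise ValueError("all fitted variances are negative before flooring")
    n_floored = int((var < VARIANCE_FLOOR).sum())
    if n_floored:
        log.warning("variance floor applied to %d of %d rows", n_floored, n)
    var = np.maximum(var, VARIANCE_FLOOR)

    # stage 3: WLS mean equation with weights 1/sqrt(var)
    w = 1.0 / np.sqrt(var)
    alpha, _, _ = _ols(y * w, X * w[:, None])
    fitted = X @ alpha
    tss = float(((y - y.mean()) ** 2).sum())
    r2_mean = 1.0 - float(((y - fitted) ** 2).sum()) / tss if tss > 0 else 0.0

    return WelfareModel(alpha=alpha, beta=beta,
                        design_columns=tuple(design_columns), n_obs=n,
                        r2_mean=r2_mean, r2_variance=r2_var,
                        n_floored=n_floored)


def predict_vulnerability(model: WelfareModel, X: np.ndarray,
                          ln_poverty_line: float,
                          design_columns: Sequence[str] | None = None) -> np.ndarray:
    """Per-row probability that welfare falls below the poverty line."""
    X = np.asarray(X, float)
    if X.shape[1] != len(model.design_columns):
        raise ValueError(f"X has {X.shape[1]} columns, model expects "
                         f"{len(model.design_columns)}")
    if design_columns is not None and tuple(design_columns) != model.design_columns:
        raise ValueError(f"design columns {tuple(design_columns)} do not match "
                         f"model columns {model.design_columns}")
    mean = X @ model.alpha
    sd = np.sqrt(np.maximum(X @ model.beta, VARIANCE_FLOOR))
    return norm.cdf((ln_poverty_line - mean) / sd)


def binarize(vulnerability: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """1 where vulnerability >= cutoff (cutoff strictly inside (0, 1))."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    v = np.asarray(vulnerability, float)
    if ((v < 0) | (v > 1)).any():
        raise ValueError("vulnerability values must lie in [0, 1]")
    return (v >= cutoff).astype(int)


def af_welfare(combined_score: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Map a joint deprivation score to log welfare: ln(1 - score + eps)."""
    return np.log(1.0 - np.asarray(combined_score, float) + eps)


def af_poverty_line(gamma: float, eps: float = 1e-3) -> float:
    """Poverty line on the af_welfare scale: ln(1 - gamma + eps)."""
    return float(np.log(1.0 - gamma + eps))
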