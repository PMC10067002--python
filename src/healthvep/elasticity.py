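"""Income elasticity of demand for health care.

The elasticity is the slope of an ordinary least-squares regression of
ln(health expenditure) on ln(income).  A single cross-section yields one
slope, so per-person variation is constructed by stratifying (default:
urban/rural x within-group income quintile), fitting the log-log slope in
each cell, and assigning each record its cell's slope truncated below at
zero.  Cells below a minimum size fall back to the pooled estimate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Stratum = tuple


@dataclass
class ElasticityModel:
    strategy: str  # "global" | "stratified"
    strata_definition: tuple[str, ...]
    beta_by_stratum: dict[Stratum, float]
    intercepts: dict[Stratum, float]
    se_by_stratum: dict[Stratum, float]
    n_by_stratum: dict[Stratum, int]
    pooled_alpha: float = 0.0
    pooled_beta: float = 0.0
    min_stratum_n: int = 30
    n_quantile_groups: int = 5
    n_excluded: int = 0
    fallback_strata: list = field(default_factory=list)


def fit_loglog(ln_q: np.ndarray, ln_i: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln_q on ln_i; returns (alpha, beta_h, se_beta)."""
    y = np.asarray(ln_q, float)
    x = np.asarray(ln_i, float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("ln_q and ln_i must be 1-d vectors of equal length")
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise ValueError("non-finite values in log-log inputs")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx <= 1e-12 * n:
        raise ValueError("zero variance in ln income; slope not identified")
    beta = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    alpha = float(y.mean() - beta * x.mean())
    resid = y - alpha - beta * x
    sigma2 = float((resid ** 2).sum() / (n - 2))
    return alpha, beta, float(np.sqrt(sigma2 / sxx))


def _usable(records: pd.DataFrame) -> pd.Series:
    return (records["health_expenditure"] > 0) & (records["income"] > 0)


def _strata_keys(records: pd.DataFrame, strata: tuple[str, ...],
                 n_groups: int) -> pd.Series:
    """Stratum key per row; 'income_quintile' bins income within the other keys."""
    parts = []
    quantize = False
    for col in strata:
        if col in ("income_quintile", "income_decile"):
            quantize = True
            n_groups = 10 if col == "income_decile" else n_groups
            continue
        if col not in records.columns:
            raise KeyError(f"stratum column {col!r} not in table")
        parts.append(records[col])
    if parts:
        base = pd.Series(list(zip(*parts)), index=records.index)
    else:
        base = pd.Series([()] * len(records), index=records.index)
    if not quantize:
        return base
    qlab = pd.Series(0, index=records.index)
    for _, idx in records.groupby(base, sort=True).groups.items():
        ranks = records.loc[idx, "income"].rank(method="first")
        qlab.loc[idx] = ((ranks - 1) * n_groups // len(idx)).astype(int)
    return pd.Series([b + (int(q),) for b, q in zip(base, qlab)], index=records.index)


def fit_elasticity(records: pd.DataFrame, strategy: str = "stratified",
                   strata: tuple[str, ...] = ("urban", "income_quintile"),
                   min_stratum_n: int = 30) -> ElasticityModel:
    """Fit the elasticity model; rows with Q <= 0 or I <= 0 are excluded."""
    if strategy not in ("global", "stratified"):
        raise ValueError(f"unknown strategy {strategy!r}")
    usable = _usable(records)
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.info("excluded %d rows with nonpositive expenditure or income",
                 n_excluded)
    sub = records[usable]
    ln_q = np.log(sub["health_expenditure"].to_numpy())
    ln_i = np.log(sub["income"].to_numpy())
    pooled_alpha, pooled_beta, pooled_se = fit_loglog(ln_q, ln_i)

    model = ElasticityModel(strategy=strategy, strata_definition=tuple(strata),
                            beta_by_stratum={}, intercepts={}, se_by_stratum={},
                            n_by_stratum={}, pooled_alpha=pooled_alpha,
                            pooled_beta=pooled_beta, min_stratum_n=min_stratum_n,
                            n_excluded=n_excluded)
    if strategy == "global":
        model.beta_by_stratum[()] = pooled_beta
        model.intercepts[()] = pooled_alpha
        model.se_by_stratum[()] = pooled_se
        model.n_by_stratum[()] = len(sub)
        return model

    keys = _strata_keys(sub, tuple(strata), model.n_quantile_groups)
    for key, idx in sub.groupby(keys, sort=True).groups.items():
        cell = sub.loc[idx]
        model.n_by_stratum[key] = len(cell)
        if len(cell) < max(min_stratum_n, 3):
            log.warning("stratum %s has n=%d < %d; using pooled estimate",
                        key, len(cell), min_stratum_n)
            model.fallback_strata.append(key)
            model.beta_by_stratum[key] = pooled_beta
            model.intercepts[key] = pooled_alpha
            model.se_by_stratum[key] = pooled_se
            continue
        a, b, se = fit_loglog(np.log(cell["health_expenditure"].to_numpy()),
                              np.log(cell["income"].to_numpy()))
        model.beta_by_stratum[key] = b
        model.intercepts[key] = a
        model.se_by_stratum[key] = se
    return model


def assign_eh(records: pd.DataFrame, model: ElasticityModel) -> np.ndarray:
    """Per-row elasticity assignment E_H >= 0 (slopes truncated at zero)."""
    if model.strategy == "global":
        eh = np.full(len(records), model.beta_by_stratum[()])
    else:
        keys = _strata_keys(records, model.strata_definition,
                            model.n_quantile_groups)
        eh = np.empty(len(records))
        missing_logged = set()
        for pos, key in enumerate(keys):
            if key in model.beta_by_stratum:
                eh[pos] = model.beta_by_stratum[key]
            else:
                if key not in missing_logged:
                    log.warning("stratum %s unseen at fit time; using pooled "
                                "estimate", key)
                    missing_logged.add(key)
                eh[pos] = model.pooled_beta
    eh = np.maximum(eh, 0.0)
    log.info("assigned E_H: mean=%.4f sd=%.4f", eh.mean(), eh.std())
    return eh
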