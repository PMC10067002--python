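"""Two-layer logistic regression with interactions, marginal effects and
joint Wald tests.

The first layer regresses the binary vulnerability outcome on the subsidy and
public-mechanism variables plus covariates and province dummy fixed effects.
The second layer adds the elasticity variable and its interactions with the
two policy variables.  Average marginal effects use derivative AMEs for
continuous regressors (with the full chain through interaction columns) and
discrete-change AMEs for binary regressors; standard errors come from the
delta method.  Subgroup harnesses re-run the second-layer design on
urban/rural and east/central/west splits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("gender", "age", "family_size", "marriage", "education",
                      "job_satisfaction", "social_status", "smoke", "drink",
                      "exercise", "patient_trust")


class SeparationError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class RegressionSpec:
    outcome: str
    main_terms: tuple[str, ...]
    second_layer: bool = False
    eh_column: str = "e_h"
    interactions: tuple[str, ...] = ()  # parent terms interacted with eh_column
    fixed_effects: str | None = "province"
    subgroup: tuple[str, object] | None = None  # (column, value) filter

    def validate(self, table: pd.DataFrame) -> None:
        if self.interactions and not self.second_layer:
            raise ValueError("interactions are only allowed in the second layer")
        needed = [self.outcome, *self.main_terms]
        if self.second_layer:
            needed.append(self.eh_column)
        if self.fixed_effects:
            needed.append(self.fixed_effects)
        if self.subgroup:
            needed.append(self.subgroup[0])
        missing = [c for c in needed if c not in table.columns]
        if missing:
            raise KeyError(f"table lacks column(s): {missing}")
        for term in self.interactions:
            if term not in self.main_terms:
                raise ValueError(f"interaction parent {term!r} is not a main term")


@dataclass
class DesignInfo:
    """Built design with the metadata needed for marginal effects."""
    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]
    binary_terms: frozenset[str]
    interaction_of: dict[str, tuple[str, str]]  # column -> (parent, eh)
    n_dropped_missing: int
    fe_levels: int
    n_dropped_fe: int = 0  # rows in FE groups with constant outcome


@dataclass
class FitResult:
    coefficients: dict[str, tuple[float, float, float, float]]  # est, se, z, p
    log_likelihood: float
    n_obs: int
    converged: bool
    fe_absorbed: int
    columns: tuple[str, ...] = ()
    params: np.ndarray = field(default_factory=lambda: np.empty(0))
    cov: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    dropped_collinear: tuple[str, ...] = ()
    ll_null_fe: float = float("nan")


@dataclass
class MarginalEffects:
    dydx: dict[str, tuple[float, float, float]]  # est, se, z
    method: str
    discrete_terms: frozenset[str]


@dataclass
class WaldTestResult:
    statistic: float
    df: int
    p_value: float
    terms_tested: tuple[str, ...]


def _interaction_name(parent: str, eh: str) -> str:
    return f"{parent}_x_{eh}"


def build_design(table: pd.DataFrame, spec: RegressionSpec) -> DesignInfo:
    """Assemble outcome vector and design matrix (const, terms, interactions,
    reference-coded fixed-effect dummies); rows with missing values dropped."""
    spec.validate(table)
    data = table
    if spec.subgroup is not None:
        col, value = spec.subgroup
        data = data[data[col] == value]
        if len(data) == 0:
            raise ValueError(f"subgroup {col}=={value!r} is empty")

    use_cols = [spec.outcome, *spec.main_terms]
    if spec.second_layer:
        use_cols.append(spec.eh_column)
    if spec.fixed_effects:
        use_cols.append(spec.fixed_effects)
    sub = data[use_cols].dropna()
    n_dropped = len(data) - len(sub)
    if n_dropped:
        log.info("dropped %d rows with missing values", n_dropped)

    n_dropped_fe = 0
    if spec.fixed_effects and len(sub):
        # drop groups with no outcome variation: their dummy would perfectly
        # predict the outcome and separate the likelihood
        var_by_group = sub.groupby(spec.fixed_effects)[spec.outcome].nunique()
        degenerate = var_by_group[var_by_group < 2].index
        if len(degenerate):
            before = len(sub)
            sub = sub[~sub[spec.fixed_effects].isin(degenerate)]
            n_dropped_fe = before - len(sub)
            log.warning("dropped %d rows in %d fixed-effect group(s) with "
                        "constant outcome", n_dropped_fe, len(degenerate))

    y = sub[spec.outcome].to_numpy(float)
    if np.unique(y).size < 2:
        raise ValueError(f"outcome {spec.outcome!r} is constant")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} is not binary")

    columns: list[str] = ["const"]
    mats: list[np.ndarray] = [np.ones(len(sub))]
    binary: set[str] = set()
    interaction_of: dict[str, tuple[str, str]] = {}

    terms = list(spec.main_terms)
    if spec.second_layer and spec.eh_column not in terms:
        terms.append(spec.eh_column)
    for term in terms:
        v = sub[term].to_numpy(float)
        columns.append(term)
        mats.append(v)
        if np.isin(v, (0.0, 1.0)).all():
            binary.add(term)
    for parent in spec.interactions:
        name = _interaction_name(parent, spec.eh_column)
        columns.append(name)
        mats.append(sub[parent].to_numpy(float) * sub[spec.eh_column].to_numpy(float))
        interaction_of[name] = (parent, spec.eh_column)

    fe_levels = 0
    if spec.fixed_effects:
        dummies = pd.get_dummies(sub[spec.fixed_effects], prefix=spec.fixed_effects,
                                 drop_first=True, dtype=float)
        fe_levels = dummies.shape[1]
        for c in dummies.columns:
            columns.append(c)
            mats.append(dummies[c].to_numpy())

    X = np.column_stack(mats)
    return DesignInfo(X=X, y=y, columns=tuple(columns),
                      binary_terms=frozenset(binary),
                      interaction_of=interaction_of,
                      n_dropped_missing=n_dropped, fe_levels=fe_levels,
                      n_dropped_fe=n_dropped_fe)


def _drop_collinear(X: np.ndarray, columns: Sequence[str]):
    """Greedy rank-revealing QR column selection; returns (X', cols', dropped)."""
    from scipy.linalg import qr as scipy_qr
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    _, R, piv = scipy_qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = tuple(columns[i] for i in sorted(piv[rank:]))
    if dropped:
        log.warning("dropped collinear column(s): %s", list(dropped))
    return X[:, keep], tuple(columns[i] for i in keep), dropped


def _newton_logit(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 100, columns: Sequence[str] | None = None):
    n, p = X.shape
    beta = np.zeros(p)
    ll_prev = -np.inf
    for it in range(max_iter):
        eta = X @ beta
        pr = expit(eta)
        w = pr * (1.0 - pr)
        grad = X.T @ (y - pr)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix became singular (possible separation)"
            ) from exc
        # damped Newton: halve until the log-likelihood does not decrease
        ll = _loglik(X, y, beta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _loglik(X, y, cand) >= ll - 1e-10:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            big = np.abs(beta) > 30
            if big.any() and columns is not None:
                worst = int(np.argmax(np.abs(beta)))
                raise SeparationError(
                    f"coefficient for {columns[worst]!r} diverged "
                    f"(|beta| > 30); data are separated on that term")
            return beta, it + 1, True
        ll_prev = ll
    raise ConvergenceError(
        f"logit did not converge in {max_iter} iterations "
        f"(last max step {np.max(np.abs(scale * step)):.3g}, "
        f"log-likelihood {ll_prev:.6g})")


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # stable log(1 + exp(eta))
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logit(design: DesignInfo) -> FitResult:
    """Maximum-likelihood logit via damped Newton steps."""
    X, columns, dropped = _drop_collinear(design.X, design.columns)
    y = design.y
    beta, _, converged = _newton_logit(X, y, columns=columns)
    pr = expit(X @ beta)
    w = pr * (1.0 - pr)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    coefficients = {c: (float(b), float(s), float(zz), float(pp))
                    for c, b, s, zz, pp in zip(columns, beta, se, z, pvals)}

    # null model for the LR test: intercept + fixed effects only
    fe_cols = [i for i, c in enumerate(columns)
               if c == "const" or c.startswith("province_") or "_fe_" in c]
    try:
        beta0, _, _ = _newton_logit(X[:, fe_cols], y)
        ll_null = _loglik(X[:, fe_cols], y, beta0)
    except (SeparationError, ConvergenceError):
        ll_null = float("nan")

    return FitResult(coefficients=coefficients,
                     log_likelihood=_loglik(X, y, beta),
                     n_obs=len(y), converged=converged,
                     fe_absorbed=design.fe_levels, columns=columns,
                     params=beta, cov=cov, dropped_collinear=dropped,
                     ll_null_fe=ll_null)


def _predict(fit: FitResult, X: np.ndarray) -> np.ndarray:
    return expit(X @ fit.params)


def _fit_design_matrix(fit: FitResult, design: DesignInfo) -> np.ndarray:
    """Design restricted to the columns the fit kept (collinear ones removed)."""
    idx = [design.columns.index(c) for c in fit.columns]
    return design.X[:, idx]


def marginal_effects(fit: FitResult, design: DesignInfo,
                     terms: Sequence[str] | None = None) -> MarginalEffects:
    """Average marginal effects with delta-method standard errors."""
    if not fit.converged:
        raise RuntimeError("marginal effects require a converged fit")
    X = _fit_design_matrix(fit, design)
    columns = list(fit.columns)
    n = X.shape[0]
    if terms is None:
        # report every non-FE, non-interaction column
        terms = [c for c in columns if c != "const"
                 and c not in design.interaction_of
                 and not _is_fe_column(c)]
    dydx: dict[str, tuple[float, float, float]] = {}
    discrete = set()
    pr = _predict(fit, X)
    w = pr * (1.0 - pr)
    for term in terms:
        if term not in columns:
            raise KeyError(f"term {term!r} absent from fit")
        j = columns.index(term)
        children = [(columns.index(name), parent_eh)
                    for name, parent_eh in design.interaction_of.items()
                    if parent_eh[0] == term or parent_eh[1] == term]
        if term in design.binary_terms:
            est, grad = _discrete_ame(fit, X, columns, term, design)
            discrete.add(term)
        else:
            # chain rule: d eta / d term = beta_term + sum beta_child * other
            chain = np.full(n, fit.params[j])
            for cj, (parent, eh) in children:
                other = eh if parent == term else parent
                chain = chain + fit.params[cj] * X[:, columns.index(other)]
            est = float(np.mean(w * chain))
            grad = np.zeros(len(columns))
            # d/d beta_k of mean(w_i * chain_i)
            curv = w * (1.0 - 2.0 * pr) * chain
            for k in range(len(columns)):
                grad[k] = float(np.mean(curv * X[:, k]))
            grad[j] += float(np.mean(w))
            for cj, (parent, eh) in children:
                other = eh if parent == term else parent
                grad[cj] += float(np.mean(w * X[:, columns.index(other)]))
        se = float(np.sqrt(grad @ fit.cov @ grad))
        dydx[term] = (est, se, est / se if se > 0 else float("nan"))
    return MarginalEffects(dydx=dydx, method="average-marginal-effect",
                           discrete_terms=frozenset(discrete))


def _is_fe_column(name: str) -> bool:
    return name.startswith("province_")


def _discrete_ame(fit: FitResult, X: np.ndarray, columns: list[str],
                  term: str, design: DesignInfo):
    """Discrete-change AME p(term=1) - p(term=0), interactions updated too."""
    j = columns.index(term)
    children = [(columns.index(name), parent_eh)
                for name, parent_eh in design.interaction_of.items()
                if term in parent_eh]

    def counterfactual(value: float) -> np.ndarray:
        Xc = X.copy()
        Xc[:, j] = value
        for cj, (parent, eh) in children:
            other = eh if parent == term else parent
            Xc[:, cj] = value * Xc[:, columns.index(other)]
        return Xc

    X1, X0 = counterfactual(1.0), counterfactual(0.0)
    p1, p0 = _predict(fit, X1), _predict(fit, X0)
    est = float(np.mean(p1 - p0))
    g1 = (p1 * (1 - p1))[:, None] * X1
    g0 = (p0 * (1 - p0))[:, None] * X0
    grad = np.mean(g1 - g0, axis=0)
    return est, grad


def wald_joint(fit: FitResult, terms: Sequence[str]) -> WaldTestResult:
    """Joint Wald chi-square test that the named coefficients are all zero."""
    terms = tuple(terms)
    missing = [t for t in terms if t not in fit.columns]
    if missing:
        raise KeyError(f"term(s) absent from fit: {missing}")
    idx = [fit.columns.index(t) for t in terms]
    b = fit.params[idx]
    V = fit.cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance sub-block for {terms} is singular") from exc
    df = len(terms)
    return WaldTestResult(statistic=stat, df=df,
                          p_value=float(chi2.sf(stat, df)), terms_tested=terms)


# ---------------------------------------------------------------------------
# table-suite harness
# ---------------------------------------------------------------------------

def _lr_test(fit: FitResult) -> tuple[float, float]:
    """LR test of the full model against intercept + fixed effects.

    This is reported in place of the unspecified overall-model statistic:
    it is labelled 'lr_prob' in the output and is not a reproduction of any
    published summary statistic.
    """
    if np.isnan(fit.ll_null_fe):
        return float("nan"), float("nan")
    k = sum(1 for c in fit.columns if c != "const" and not _is_fe_column(c))
    stat = 2.0 * (fit.log_likelihood - fit.ll_null_fe)
    return stat, float(chi2.sf(stat, k))


def _stars(p: float) -> str:
    return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.10 else ""


def run_design(table: pd.DataFrame, spec: RegressionSpec,
               ame_terms: Sequence[str] | None = None) -> dict:
    design = build_design(table, spec)
    fit = fit_logit(design)
    ame = marginal_effects(fit, design, terms=ame_terms)
    lr_stat, lr_p = _lr_test(fit)
    rows = []
    for term, (est, se, z) in ame.dydx.items():
        coef = fit.coefficients.get(term)
        rows.append({"term": term,
                     "estimate": coef[0] if coef else float("nan"),
                     "se": coef[1] if coef else float("nan"),
                     "z": z, "p": 2.0 * norm.sf(abs(z)) if se > 0 else float("nan"),
                     "dydx": est, "dydx_pct": 100.0 * est, "dydx_se": se,
                     "stars": _stars(2.0 * norm.sf(abs(z)))})
    return {"n_obs": fit.n_obs, "n_dropped_fe": design.n_dropped_fe,
            "n_dropped_missing": design.n_dropped_missing,
            "fit": fit, "design": design, "ame": ame,
            "rows": rows, "lr_stat": lr_stat, "lr_prob": lr_p}


def _try_design(table: pd.DataFrame, spec: RegressionSpec) -> dict:
    """Run one subgroup design; a failure yields an error block, not an abort."""
    try:
        return run_design(table, spec)
    except (ValueError, KeyError, SeparationError, ConvergenceError,
            np.linalg.LinAlgError) as exc:
        log.error("subgroup design failed: %s", exc)
        return {"error": str(exc)}


def run_table_suite(table: pd.DataFrame,
                    covariates: Sequence[str] = DEFAULT_COVARIATES,
                    outcome: str = "vep", eh_column: str = "e_h",
                    fe_column: str | None = "province",
                    designs: Sequence[str] = ("table4", "table5", "table6",
                                              "table7", "table8")) -> dict:
    """Run the baseline, interaction-test, second-layer and subgroup designs.

    Returns a mapping design name -> result block (or an ``error`` entry when
    a subgroup fails; remaining designs still run).
    """
    covariates = tuple(covariates)
    first_terms = ("gs", "pm", *covariates, "urban")
    second_terms = ("gs", "pm", *covariates, "urban")
    results: dict[str, dict] = {}

    def second_spec(subgroup=None, drop_urban=False) -> RegressionSpec:
        terms = tuple(t for t in second_terms if not (drop_urban and t == "urban"))
        return RegressionSpec(outcome=outcome, main_terms=terms,
                              second_layer=True, eh_column=eh_column,
                              interactions=("gs", "pm"),
                              fixed_effects=fe_column, subgroup=subgroup)

    for name in designs:
        try:
            if name == "table4":
                spec = RegressionSpec(outcome=outcome, main_terms=first_terms,
                                      fixed_effects=fe_column)
                results[name] = run_design(table, spec)
            elif name == "table5":
                design = build_design(table, second_spec())
                fit = fit_logit(design)
                inter = [c for c in fit.columns if c in design.interaction_of]
                block = {"n_obs": fit.n_obs,
                         "joint": wald_joint(fit, inter),
                         "per_term": {t: wald_joint(fit, [t]) for t in inter}}
                results[name] = block
            elif name == "table6":
                results[name] = run_design(table, second_spec())
            elif name == "table7":
                results[name] = {
                    "urban": _try_design(table, second_spec(("urban", 1), drop_urban=True)),
                    "rural": _try_design(table, second_spec(("urban", 0), drop_urban=True)),
                }
            elif name == "table8":
                results[name] = {
                    r: _try_design(table, second_spec(("region", r)))
                    for r in ("east", "central", "west")
                }
            else:
                raise ValueError(f"unknown design {name!r}")
        except (ValueError, KeyError, SeparationError, ConvergenceError,
                np.linalg.LinAlgError) as exc:
            log.error("design %s failed: %s", name, exc)
            results[name] = {"error": str(exc)}
    return results


def results_to_frame(block: dict) -> pd.DataFrame:
    """Flatten one run_design block into the CSV output schema."""
    return pd.DataFrame(block["rows"],
                        columns=["term", "estimate", "se", "z", "p",
                                 "dydx", "dydx_pct", "dydx_se", "stars"])


def format_report(name: str, block: dict) -> str:
    """Plain-text report for one design block."""
    lines = [f"== {name} =="]
    if "error" in block:
        lines.append(f"  FAILED: {block['error']}")
        return "\n".join(lines) + "\n"
    if "joint" in block:  # interaction-test block
        j = block["joint"]
        lines.append(f"  n = {block['n_obs']}")
        lines.append(f"  joint Wald chi2({j.df}) = {j.statistic:.3f}, "
                     f"p = {j.p_value:.4f}  [{', '.join(j.terms_tested)}]")
        for t, w in block["per_term"].items():
            lines.append(f"  {t}: chi2(1) = {w.statistic:.3f}, p = {w.p_value:.4f}")
        return "\n".join(lines) + "\n"
    if "rows" in block:
        lines.append(f"  n = {block['n_obs']}, LR test vs intercept+FE: "
                     f"stat = {block['lr_stat']:.2f}, p = {block['lr_prob']:.4f}")
        lines.append(f"  {'term':<18}{'dydx':>10}{'dydx(%)':>10}{'z':>8}  sig")
        for r in block["rows"]:
            lines.append(f"  {r['term']:<18}{r['dydx']:>10.4f}"
                         f"{r['dydx_pct']:>10.2f}{r['z']:>8.2f}  {r['stars']}")
        return "\n".join(lines) + "\n"
    # nested subgroup block
    for sub, b in block.items():
        lines.append(format_report(f"{name}/{sub}", b).rstrip())
    return "\n".join(lines) + "\n"
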