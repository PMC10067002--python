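"""Synthetic survey microdata with known ground truth.

Every downstream stage (deprivation scoring, FGLS vulnerability, elasticity,
interaction logits, inequality indices) is exercised against populations drawn
here, where the generating parameters are known exactly:

* ``ln_welfare = X @ welfare_alpha + e`` with ``Var(e | X) = X @ welfare_beta``
  (heteroskedastic Gaussian), ``X`` the welfare design of
  :data:`healthvep.config.WELFARE_COLUMNS`;
* ``true_vulnerability = Phi((ln_poverty_line - X@alpha) / sqrt(X@beta))``;
* ``ln(health_expenditure) = a + slope_i * ln(income) + noise`` where
  ``slope_i`` is the person's true elasticity (base value plus optional
  urban and income-quintile shifts);
* binary health indicators drawn from latent propensities tied to welfare;
* subsidy receipt (``gs``) more likely for more-deprived, lower-income rows;
* the binary ``vep`` outcome drawn from a logistic model in ``logit_coefs``
  over gs, pm, true elasticity, the two interactions, covariates and small
  province effects.

One master seed; each stage draws from a named substream so adding a stage
never perturbs the others.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import WELFARE_COLUMNS, PopulationConfig

REGIONS = ("east", "central", "west")
#: province codes by region (11 east, 9 central, 10 west)
PROVINCES = {
    "east": tuple(f"P{i:02d}" for i in range(1, 12)),
    "central": tuple(f"P{i:02d}" for i in range(12, 21)),
    "west": tuple(f"P{i:02d}" for i in range(21, 31)),
}

PSYCH_ITEMS = ("depression", "struggle", "poor_sleep", "unpleasant",
               "lonely", "sad", "difficulty", "hopeless")

# name -> (kind, lo, hi); kind in {"str", "cat", "int", "float"}
_BIN = ("int", 0, 1)
SCHEMA: dict[str, tuple] = {
    "person_id": ("str", None, None),
    "urban": _BIN,
    "region": ("cat", REGIONS, None),
    "province": ("cat", tuple(p for ps in PROVINCES.values() for p in ps), None),
    "gender": _BIN,
    "age": ("int", 16, 96),
    "family_size": ("int", 1, 17),
    "marriage": _BIN,
    "education": ("int", 0, 22),
    "job_satisfaction": ("int", 1, 5),
    "social_status": ("int", 1, 5),
    "smoke": _BIN,
    "drink": _BIN,
    "exercise": ("int", 0, 50),
    "patient_trust": ("int", 0, 10),
    "income": ("float", 0.0, None),  # strictly positive, checked separately
    "health_expenditure": ("float", 0.0, None),
    "gs": _BIN,
    "pm": ("float", 0.0, 10.0),  # 1-10 scale or rescaled [0, 1] variant
    # raw physical-health indicator fields (deprivation rules in af_index)
    "health_insurance": _BIN,
    "chronic_illness": _BIN,
    "bronchitis": _BIN,
    "asthma": _BIN,
    "hospitalized": _BIN,
    "unwell": _BIN,
    "weekend_break": _BIN,
    # raw mental-health indicator fields
    **{item: ("int", 1, 4) for item in PSYCH_ITEMS},
    "social_relationship": _BIN,
}
#: generator-only columns, written but not required on ingest
OPTIONAL_COLUMNS: dict[str, tuple] = {
    "ln_welfare": ("float", None, None),
    "true_vulnerability": ("float", 0.0, 1.0),
    "e_h_true": ("float", 0.0, None),
    "vep": _BIN,
}
REQUIRED_COLUMNS = tuple(SCHEMA)
ALL_COLUMNS = tuple(SCHEMA) + tuple(OPTIONAL_COLUMNS)

_SUBSTREAMS = ("demographics", "income", "welfare", "indicators", "gs", "pm",
               "expenditure", "outcome")


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ValidationError(ValueError):
    """A value violates its documented range."""


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _trunc_int(rng, mean, sd, lo, hi, n):
    draw = np.round(rng.normal(mean, sd, size=n))
    return np.clip(draw, lo, hi).astype(int)


def welfare_design(table: pd.DataFrame) -> np.ndarray:
    """Welfare-equation design matrix (columns per WELFARE_COLUMNS)."""
    n = len(table)
    return np.column_stack([
        np.ones(n),
        table["urban"].to_numpy(float),
        table["age"].to_numpy(float) / 10.0,
        table["education"].to_numpy(float) / 10.0,
        table["family_size"].to_numpy(float) / 10.0,
    ])


def income_quintile(income: np.ndarray, urban: np.ndarray) -> np.ndarray:
    """Empirical income quintile 0..4 within each urban/rural group.

    Matches the default stratification of the elasticity module so the
    generator's per-stratum slopes are recoverable cell by cell.
    """
    s = pd.Series(np.asarray(income, float))
    out = np.zeros(len(s), dtype=int)
    for u in np.unique(urban):
        mask = np.asarray(urban) == u
        ranks = s[mask].rank(method="first").to_numpy()
        out[mask] = ((ranks - 1) * 5 // mask.sum()).astype(int)
    return out


def true_elasticity(urban: np.ndarray, quintile: np.ndarray,
                    config: PopulationConfig) -> np.ndarray:
    slope = (config.elasticity_true
             + config.elasticity_urban_delta * urban
             + config.elasticity_quintile_step * (quintile - 2))
    return np.maximum(slope, 0.0)


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw a full synthetic population; deterministic given ``config.seed``."""
    config.validate()
    n = config.n_individuals
    rng = _streams(config.seed)

    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=_pandas_dtype(c)) for c in ALL_COLUMNS})

    demo = rng["demographics"]
    urban = (demo.random(n) < config.urban_share).astype(int)
    region = demo.choice(REGIONS, size=n, p=np.asarray(config.region_shares))
    province = np.empty(n, dtype=object)
    for r in REGIONS:
        mask = region == r
        province[mask] = demo.choice(PROVINCES[r], size=int(mask.sum()))
    gender = (demo.random(n) < 0.602).astype(int)
    age = _trunc_int(demo, 39.1, 12.1, 16, 96, n)
    family_size = _trunc_int(demo, 3.9, 2.0, 1, 17, n)
    marriage = (demo.random(n) < 0.803).astype(int)
    education = _trunc_int(demo, 10.5, 4.1, 0, 22, n)
    job_satisfaction = _trunc_int(demo, 3.6, 0.86, 1, 5, n)
    social_status = _trunc_int(demo, 2.9, 0.98, 1, 5, n)
    smoke = (demo.random(n) < 0.360).astype(int)
    drink = (demo.random(n) < 0.174).astype(int)
    exercise = np.clip(np.round(demo.exponential(3.3, size=n)), 0, 50).astype(int)
    patient_trust = _trunc_int(demo, 6.5, 2.3, 0, 10, n)

    extra = dict(zip(REGIONS, config.income_urban_log_sd_extra))
    income_sd = config.income_log_sd + urban * np.array([extra[r] for r in region])
    income = np.exp(config.income_log_mean
                    + rng["income"].normal(size=n) * income_sd)

    table = pd.DataFrame({
        "person_id": [f"i{i:06d}" for i in range(n)],
        "urban": urban, "region": region, "province": province,
        "gender": gender, "age": age, "family_size": family_size,
        "marriage": marriage, "education": education,
        "job_satisfaction": job_satisfaction, "social_status": social_status,
        "smoke": smoke, "drink": drink, "exercise": exercise,
        "patient_trust": patient_trust, "income": income,
    })

    # welfare process
    X = welfare_design(table)
    alpha = np.asarray(config.welfare_alpha, float)
    beta = np.asarray(config.welfare_beta, float)
    var = X @ beta
    bad = np.nonzero(var <= 0)[0]
    if bad.size:
        raise ValueError(f"variance positivity violated at row {bad[0]}: "
                         f"X @ welfare_beta = {var[bad[0]]!r}")
    mean_w = X @ alpha
    ln_welfare = mean_w + rng["welfare"].normal(size=n) * np.sqrt(var)
    from scipy.stats import norm
    true_vul = norm.cdf((config.ln_poverty_line - mean_w) / np.sqrt(var))

    # health indicator propensities tied to welfare
    ind = rng["indicators"]
    z_w = (ln_welfare - ln_welfare.mean()) / max(ln_welfare.std(), 1e-12)
    k = config.deprivation_welfare_slope

    def dep(base_rate: float) -> np.ndarray:
        p = _sigmoid(_logit(base_rate) - k * z_w)
        return (ind.random(n) < p).astype(int)

    table["health_insurance"] = 1 - dep(0.08)
    table["chronic_illness"] = dep(0.20)
    table["bronchitis"] = dep(0.08)
    table["asthma"] = dep(0.05)
    table["hospitalized"] = dep(0.12)
    table["unwell"] = dep(0.25)
    table["weekend_break"] = 1 - dep(0.30)
    for item in PSYCH_ITEMS:
        d = dep(0.15)
        table[item] = np.where(d == 1, 3, 1) + (ind.random(n) < 0.5).astype(int)
    table["social_relationship"] = 1 - dep(0.20)

    # deprivation scores feed the subsidy-assignment propensity
    from . import af_index
    php_spec, mhp_spec = af_index.builtin_specs()
    php_score = af_index.weighted_scores(af_index.apply_deprivations(table, php_spec), php_spec)
    mhp_score = af_index.weighted_scores(af_index.apply_deprivations(table, mhp_spec), mhp_spec)
    combined = 0.5 * (php_score + mhp_score)

    quintile = income_quintile(income, urban)
    p_gs = _sigmoid(_logit(config.gs_rate)
                    + config.gs_score_slope * (combined - combined.mean())
                    + config.gs_quintile_slope * (quintile - 2))
    table["gs"] = (rng["gs"].random(n) < p_gs).astype(int)

    pm10 = np.clip(np.round(rng["pm"].normal(6.4, 1.8, size=n)), 1, 10)
    table["pm"] = pm10 if config.pm_scale == "1-10" else (pm10 - 1.0) / 9.0

    # health expenditure: log-log in income with per-person true slope
    e_h = true_elasticity(urban.astype(float), quintile, config)
    exp_rng = rng["expenditure"]
    # slope anchored at the income-distribution centre so that per-stratum
    # slope differences do not create level jumps at quantile boundaries
    ln_q = (config.expenditure_intercept
            + config.elasticity_true * config.income_log_mean
            + e_h * (np.log(income) - config.income_log_mean)
            + exp_rng.normal(0.0, config.expenditure_noise_sd, size=n))
    q = np.exp(ln_q)
    q[exp_rng.random(n) < config.zero_expenditure_rate] = 0.0
    table["health_expenditure"] = q

    # binary outcome from the logistic ground truth
    coefs = config.logit_coefs
    eta = np.full(n, coefs.get("const", 0.0))
    base_cols = {"gs": table["gs"], "pm": table["pm"], "e_h": e_h,
                 "gs_x_eh": table["gs"] * e_h, "pm_x_eh": table["pm"] * e_h,
                 "gender": gender, "age": age, "family_size": family_size,
                 "marriage": marriage, "education": education, "urban": urban}
    for name, coef in coefs.items():
        if name == "const":
            continue
        if name not in base_cols:
            raise ValueError(f"logit_coefs names unknown term {name!r}")
        eta += coef * np.asarray(base_cols[name], float)
    out_rng = rng["outcome"]
    all_provinces = [p for ps in PROVINCES.values() for p in ps]
    prov_effects = dict(zip(all_provinces,
                            out_rng.normal(0.0, config.province_effect_sd,
                                           size=len(all_provinces))))
    eta += np.array([prov_effects[p] for p in province])
    table["vep"] = (out_rng.random(n) < _sigmoid(eta)).astype(int)

    table["ln_welfare"] = ln_welfare
    table["true_vulnerability"] = true_vul
    table["e_h_true"] = e_h
    return table[list(ALL_COLUMNS)]


# ---------------------------------------------------------------------------
# table I/O with validation
# ---------------------------------------------------------------------------

def _pandas_dtype(col: str) -> str:
    kind = (SCHEMA.get(col) or OPTIONAL_COLUMNS[col])[0]
    return {"str": "object", "cat": "object", "int": "int64", "float": "float64"}[kind]


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a population table as UTF-8 comma-separated text."""
    table.to_csv(path, index=False)


def read_table(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a population table (round-trips :func:`write_table`).

    With ``validate=False`` only the column schema is checked, leaving range
    and missing-value screening to the caller (the pipeline excludes such
    rows explicitly and accounts for them in its ledger).
    """
    table = pd.read_csv(path, dtype={"person_id": str, "region": str, "province": str})
    if validate:
        validate_table(table)
        for col in table.columns:
            if col in SCHEMA or col in OPTIONAL_COLUMNS:
                table[col] = table[col].astype(_pandas_dtype(col))
    else:
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return table


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in table.columns:
        spec = SCHEMA.get(col) or OPTIONAL_COLUMNS.get(col)
        if spec is None:
            continue
        kind, lo, hi = spec
        series = table[col]
        if series.isna().any():
            row = int(series.isna().idxmax())
            raise ValidationError(f"column {col!r} has missing value at row {row}")
        if kind == "cat":
            bad = ~series.isin(lo)
            if bad.any():
                row = int(bad.idxmax())
                raise ValidationError(
                    f"column {col!r} value {series[row]!r} at row {row} "
                    f"not in allowed categories")
        elif kind in ("int", "float"):
            values = series.to_numpy()
            if lo is not None:
                bad = values < lo
                if bad.any():
                    row = int(np.argmax(bad))
                    raise ValidationError(
                        f"column {col!r} value {values[row]!r} at row {row} "
                        f"below allowed range {lo}-{hi}")
            if hi is not None:
                bad = values > hi
                if bad.any():
                    row = int(np.argmax(bad))
                    raise ValidationError(
                        f"column {col!r} value {values[row]!r} at row {row} "
                        f"above allowed range {lo}-{hi}")
    if len(table):
        nonpos = table["income"].to_numpy() <= 0
        if nonpos.any():
            row = int(np.argmax(nonpos))
            raise ValidationError(f"column 'income' must be strictly positive "
                                  f"(row {row})")
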