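"""Configuration objects for the generator and the pipeline.

All configs are flat dataclasses serialisable to/from YAML so that every run
is reproducible from a single text file plus a seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Ordered design columns of the welfare (mean + variance) equations.
WELFARE_COLUMNS = ("const", "urban", "age_dec", "edu_dec", "fam_dec")


def _default_logit_coefs() -> dict[str, float]:
    # Sign pattern: gs-, pm-, e_h-, gs_x_eh+, pm_x_eh-.  The intercept is
    # calibrated so the binary outcome mean is ~0.953 at large n under the
    # remaining defaults; re-calibrate if any other default changes.
    return {
        "const": 10.65,
        "gs": -2.4,
        "pm": -0.30,
        "e_h": -4.5,
        "gs_x_eh": 2.4,
        "pm_x_eh": -0.60,
        "gender": -0.15,
        "age": -0.008,
        "family_size": 0.22,
        "marriage": -0.25,
        "education": -0.03,
        "urban": -0.30,
    }


@dataclass
class PopulationConfig:
    """Ground-truth parameters of the synthetic survey population."""

    n_individuals: int = 8831
    urban_share: float = 0.570
    region_shares: tuple[float, float, float] = (0.482, 0.284, 0.234)
    seed: int = 0

    # -- welfare process: ln_welfare = X @ alpha + e,  Var(e|X) = X @ beta --
    welfare_alpha: tuple[float, ...] = (0.10, 0.30, 0.05, 0.40, -0.20)
    welfare_beta: tuple[float, ...] = (0.05, 0.02, 0.005, 0.01, 0.0)
    ln_poverty_line: float = 0.80

    # -- income and health expenditure (log-log link) --
    income_log_mean: float = 10.0
    income_log_sd: float = 0.8
    #: extra urban log-income dispersion per region (east, central, west);
    #: drives the urban-rural inequality-gap ordering across regions
    income_urban_log_sd_extra: tuple[float, float, float] = (0.30, 0.15, 0.0)
    elasticity_true: float = 0.35
    elasticity_urban_delta: float = 0.15
    elasticity_quintile_step: float = 0.12
    expenditure_intercept: float = 3.0
    expenditure_noise_sd: float = 0.12
    zero_expenditure_rate: float = 0.04

    # -- subsidy / public-mechanism processes --
    gs_rate: float = 0.335
    gs_score_slope: float = 1.2
    gs_quintile_slope: float = -0.35
    pm_scale: str = "1-10"  # or "unit": (pm - 1) / 9

    # -- deprivation propensities --
    deprivation_welfare_slope: float = 1.0

    # -- binary outcome process (logistic) --
    logit_coefs: dict[str, float] = field(default_factory=_default_logit_coefs)
    province_effect_sd: float = 0.10

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ValueError(f"n_individuals must be >= 0, got {self.n_individuals}")
        if not 0.0 <= self.urban_share <= 1.0:
            raise ValueError(f"urban_share must lie in [0, 1], got {self.urban_share}")
        shares = tuple(self.region_shares)
        if len(shares) != 3 or any(not 0.0 <= s <= 1.0 for s in shares):
            raise ValueError(f"region_shares must be three fractions in [0, 1], got {shares}")
        if abs(sum(shares) - 1.0) > 1e-12:
            raise ValueError(f"region_shares must sum to 1, got sum {sum(shares)!r}")
        if len(self.welfare_alpha) != len(WELFARE_COLUMNS):
            raise ValueError("welfare_alpha length must match the welfare design "
                             f"({len(WELFARE_COLUMNS)} columns)")
        if len(self.welfare_beta) != len(WELFARE_COLUMNS):
            raise ValueError("welfare_beta length must match the welfare design "
                             f"({len(WELFARE_COLUMNS)} columns)")
        if any(b < 0 for b in self.welfare_beta):
            raise ValueError("welfare_beta entries must be nonnegative")
        if self.welfare_beta[0] <= 0:
            raise ValueError("welfare_beta intercept must be positive for variance positivity")
        if self.elasticity_true < 0:
            raise ValueError("elasticity_true must be >= 0")
        extra = tuple(self.income_urban_log_sd_extra)
        if len(extra) != 3 or any(self.income_log_sd + e <= 0 for e in extra):
            raise ValueError("income_urban_log_sd_extra must be three values "
                             "keeping the log-income SD positive")
        if self.pm_scale not in ("1-10", "unit"):
            raise ValueError(f"pm_scale must be '1-10' or 'unit', got {self.pm_scale!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PopulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown PopulationConfig keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("region_shares", "welfare_alpha", "welfare_beta",
                     "income_urban_log_sd_extra"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.validate()
        return cfg


@dataclass
class PipelineConfig:
    """End-to-end run configuration (see ``healthvep.pipeline.run_pipeline``)."""

    out_dir: str = "results"
    input_csv: str | None = None  # None -> simulate with `population`
    population: PopulationConfig = field(default_factory=PopulationConfig)
    seed: int = 0

    # Alkire-Foster settings
    gamma: float = 0.30
    combine_rule: str = "either"  # either | both | score-union

    # VEP settings
    welfare_source: str = "af-score"  # "af-score" or "column:<name>"
    ln_poverty_line: float | None = None  # None -> ln(1 - gamma + eps) for af-score
    vep_cutoff: float = 0.5

    # elasticity settings
    elasticity_strategy: str = "stratified"
    elasticity_strata: tuple[str, ...] = ("urban", "income_quintile")
    min_stratum_n: int = 30

    # regression settings
    designs: tuple[str, ...] = ("table4", "table5", "table6", "table7", "table8")
    fe_column: str = "province"
    outcome_column: str = "vep"  # generated outcome; "vep_hat" = VEP-stage output

    # inequality settings
    inequality_value: str = "income"

    def validate(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")
        if not 0.0 < self.vep_cutoff < 1.0:
            raise ValueError(f"vep_cutoff must lie in (0, 1), got {self.vep_cutoff}")
        if self.combine_rule not in ("either", "both", "score-union"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")
        if not (self.welfare_source == "af-score"
                or self.welfare_source.startswith("column:")):
            raise ValueError(f"unknown welfare_source {self.welfare_source!r}")
        self.population.validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pop = raw.pop("population", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if pop is not None:
            cfg.population = PopulationConfig.from_dict(pop)
        for name in ("elasticity_strata", "designs"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.validate()
        return cfg


def _as_plain(obj: Any) -> Any:
    """Dataclass -> YAML-safe nested dict of plain python types."""
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    return obj
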